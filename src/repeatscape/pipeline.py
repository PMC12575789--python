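"""Stage orchestration: simulate -> sv-merge -> signatures -> coverage ->
methylation -> thor.

Each stage writes its tables under ``<outdir>/<stage>/`` plus a
``manifest.json`` recording the config hash, seed, package version and an
sha256 per output.  The manifest is written last, so a stage directory
without one is stale (an aborted run).  Reruns with an identical config are
byte-identical: nothing in the outputs depends on wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import allele, coverage, methylation, signatures, simulate, sv
from .config import PipelineConfig
from .io import (
    GenomicInterval,
    read_bed_annotation,
    read_bedmethyl,
    read_depth_bed,
    read_sample_sheet,
    read_signature_matrix,
    read_sv_vcf,
    write_bedmethyl,
    write_depth_bed,
    write_table,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "sv", "signatures", "coverage", "methylation", "thor")

#: planted THOR patterns cycled over tumor samples by the simulate stage
_THOR_PATTERNS = (
    ("biallelic_hyper", (0.85, 0.85)),
    ("monoallelic_hyper", (0.85, 0.10)),
    ("none", (0.10, 0.10)),
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _finish_stage(stage_dir: Path, stage: str, config: PipelineConfig) -> None:
    outputs = {
        p.name: _sha256(p)
        for p in sorted(stage_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": outputs,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _fresh_dir(outdir: Path, stage: str) -> Path:
    stage_dir = outdir / stage
    if stage_dir.exists():
        for p in stage_dir.iterdir():
            if p.is_file():
                p.unlink()
    stage_dir.mkdir(parents=True, exist_ok=True)
    return stage_dir


def _sim_config(config: PipelineConfig) -> simulate.SimulationConfig:
    s = config.simulate
    return simulate.SimulationConfig(
        seed=config.seed,
        n_pairs=s.n_pairs,
        depth_mean=s.depth_mean,
        tumor_variance_inflation=s.tumor_variance_inflation,
        breakpoint_jitter_sd=s.breakpoint_jitter_sd,
        n_sv=s.n_sv,
        catalog_size=s.catalog_size,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    inputs = _fresh_dir(outdir, "inputs")
    sim = _sim_config(config)
    ref = simulate.make_mini_reference(sim)
    ref.write(inputs)
    metas = simulate.make_cohort(sim)
    simulate.write_sample_sheet(metas, inputs / "sample_sheet.tsv")

    sigmat = simulate.make_signature_matrix(sim, n_signatures=config.simulate.n_signatures)
    from .io import write_signature_matrix
    write_signature_matrix(sigmat, inputs / "signature_matrix.tsv")

    catalogs, weight_rows = [], []
    for meta in metas:
        depth = simulate.simulate_depth_track(sim, ref, meta)
        write_depth_bed(depth, inputs / f"{meta.sample_id}.depth.bed")
        meth = simulate.simulate_methylome(sim, ref, meta)
        write_bedmethyl(meth, inputs / f"{meta.sample_id}.bedmethyl")
        if meta.group == "tumor":
            callsets, truth = simulate.simulate_sv_callsets(sim, ref, meta)
            simulate.write_sv_callsets(callsets, truth, ref, inputs, meta.sample_id)
            catalog, w = simulate.simulate_mutation_catalog(sim, meta, sigmat)
            catalogs.append(catalog)
            weight_rows.append({"sample_id": meta.sample_id,
                                **dict(zip(sigmat.names, w))})
    write_table(signatures.catalog_table(catalogs), inputs / "sbs_catalogs.tsv")
    write_table(pd.DataFrame(weight_rows), inputs / "exposure_truth.tsv")

    thor_rows = []
    tumors = [m for m in metas if m.group == "tumor"]
    for i, meta in enumerate(tumors):
        call_truth, hap_means = _THOR_PATTERNS[i % len(_THOR_PATTERNS)]
        locus = simulate.PhasedLocusSpec(hap_means_thor=hap_means)
        phased = simulate.simulate_phased_locus(sim, locus, sample=meta.sample_id)
        write_bedmethyl(phased, inputs / f"{meta.sample_id}.phased.bedmethyl",
                        write_haplotype=True)
        thor_rows.append({
            "sample_id": meta.sample_id, "planted_call": call_truth,
            "chrom": locus.chrom,
            "thor_start": locus.thor[0], "thor_end": locus.thor[1],
        })
    write_table(pd.DataFrame(thor_rows), inputs / "thor_truth.tsv")
    _finish_stage(inputs, "simulate", config)


def _tumor_ids(outdir: Path) -> list[str]:
    metas = read_sample_sheet(outdir / "inputs" / "sample_sheet.tsv")
    return [m.sample_id for m in metas if m.group == "tumor"]


def _contigs(outdir: Path) -> list[tuple[str, int]]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(outdir / "inputs" / "reference.fa"))
    return [(name, len(fa[name])) for name in fa.keys()]


def _stage_sv(config: PipelineConfig, outdir: Path) -> None:
    stage_dir = _fresh_dir(outdir, "sv")
    inputs = outdir / "inputs"
    contigs = _contigs(outdir)
    callers = sorted(
        {p.name.split(".")[1] for p in inputs.glob("*.vcf")}
    )
    summaries = []
    for sid in _tumor_ids(outdir):
        callsets = {}
        for caller in callers:
            path = inputs / f"{sid}.{caller}.vcf"
            records, _skipped = read_sv_vcf(path, caller, sample=sid)
            callsets[caller] = records
        consensus = sv.merge_callsets(
            callsets, tol=config.sv.tol,
            min_size=config.sv.min_size, min_support=config.sv.min_support,
        )
        sv.write_consensus_vcf(consensus, stage_dir / f"{sid}.consensus.vcf", contigs)
        summaries.append(sv.consensus_summary(consensus, sample=sid))
    write_table(pd.concat(summaries, ignore_index=True), stage_dir / "sv_summary.tsv")
    _finish_stage(stage_dir, "sv", config)


def _stage_signatures(config: PipelineConfig, outdir: Path) -> None:
    stage_dir = _fresh_dir(outdir, "signatures")
    inputs = outdir / "inputs"
    matrix_path = config.signatures.signature_matrix or inputs / "signature_matrix.tsv"
    sigmat = read_signature_matrix(matrix_path)
    catalogs = pd.read_csv(inputs / "sbs_catalogs.tsv", sep="\t", index_col="Type")
    exposures = []
    for sid in catalogs.columns:
        catalog = signatures.MutationCatalog(
            sid, tuple(catalogs.index), catalogs[sid].to_numpy()
        )
        exposures.append(signatures.nnls_fit(catalog, sigmat))
    write_table(signatures.exposures_table(exposures), stage_dir / "sbs_exposures.tsv")

    # SV32 catalogs from the consensus stage (no refit: needs an SV-class
    # reference matrix, which the caller may supply in a later run)
    sv_dir = outdir / "sv"
    if sv_dir.is_dir():
        sv32 = []
        for sid in _tumor_ids(outdir):
            records, _ = read_sv_vcf(sv_dir / f"{sid}.consensus.vcf", "consensus", sample=sid)
            consensus = [
                sv.ConsensusSV(r, 1, (r,)) for r in records
            ]
            sv32.append(signatures.build_sv32_catalog(consensus, sample_id=sid))
        write_table(signatures.catalog_table(sv32), stage_dir / "sv32_catalogs.tsv")
    _finish_stage(stage_dir, "signatures", config)


def _stage_coverage(config: PipelineConfig, outdir: Path) -> None:
    stage_dir = _fresh_dir(outdir, "coverage")
    inputs = outdir / "inputs"
    annotation = read_bed_annotation(inputs / "annotation.bed")
    metas = read_sample_sheet(inputs / "sample_sheet.tsv")
    sat = [iv for iv in annotation if iv.label in simulate.SATELLITE_CLASSES]
    bins = coverage.make_bins(sat, config.coverage.bin_width, config.coverage.partial)

    te_counts = [
        {"te_class": cls,
         "threshold_bp": coverage.TE_LENGTH_THRESHOLDS[cls],
         "n_full_length": len(coverage.filter_te_annotation(annotation, cls))}
        for cls in simulate.TE_CLASSES
        if any(iv.label == cls for iv in annotation)
    ]
    write_table(pd.DataFrame(te_counts), stage_dir / "te_full_length_counts.tsv")

    te_bins: dict[str, list[GenomicInterval]] = {}
    for cls in simulate.TE_CLASSES:
        full = [iv for iv in annotation if iv.label == cls]
        if not full:
            continue
        if cls == "AluY":
            te_bins[cls] = full  # per insertion
        else:
            te_bins[cls] = coverage.make_bins(full, config.coverage.bin_width,
                                              config.coverage.partial)

    rows = []
    te_values: dict[str, dict[str, np.ndarray]] = {cls: {} for cls in te_bins}
    for meta in metas:
        depth = read_depth_bed(inputs / f"{meta.sample_id}.depth.bed")
        gmed = coverage.genome_median_depth(depth)
        values = coverage.normalize_depth(coverage.bin_median_depth(depth, bins), gmed)
        for b, v in zip(bins, values):
            rows.append({"chrom": b.chrom, "start": b.start, "end": b.end,
                         "class": b.label, "sample": meta.sample_id, "value": v})
        for cls, cls_bins in te_bins.items():
            te_values[cls][meta.sample_id] = coverage.normalize_depth(
                coverage.bin_median_depth(depth, cls_bins), gmed
            )
    write_table(pd.DataFrame(rows), stage_dir / "satellite_coverage_bins.tsv")

    tumor_ids = {m.sample_id for m in metas if m.group == "tumor"}
    var_rows = []
    for cls, per_sample in te_values.items():
        tum = np.concatenate([v for s, v in per_sample.items() if s in tumor_ids])
        nor = np.concatenate([v for s, v in per_sample.items() if s not in tumor_ids])
        w, p = coverage.compare_variance(tum, nor, center=config.coverage.levene_center)
        var_rows.append({"te_class": cls, "levene_w": w, "p_value": p,
                         "var_tumor": float(np.nanvar(tum)),
                         "var_normal": float(np.nanvar(nor))})
    write_table(pd.DataFrame(var_rows), stage_dir / "te_coverage_variance.tsv")
    _finish_stage(stage_dir, "coverage", config)


def _stage_methylation(config: PipelineConfig, outdir: Path) -> None:
    stage_dir = _fresh_dir(outdir, "methylation")
    inputs = outdir / "inputs"
    annotation = read_bed_annotation(inputs / "annotation.bed")
    metas = read_sample_sheet(inputs / "sample_sheet.tsv")
    sat = [iv for iv in annotation if iv.label in simulate.SATELLITE_CLASSES]
    bins = coverage.make_bins(sat, config.coverage.bin_width, config.coverage.partial)

    per_sample: dict[str, np.ndarray] = {}
    summaries = []
    for meta in metas:
        records = read_bedmethyl(inputs / f"{meta.sample_id}.bedmethyl")
        per_sample[meta.sample_id] = methylation.bin_methylation(
            records, bins, method=config.methylation.method
        )
        summary = methylation.genome_cpg_summary(records)
        summaries.append(pd.Series(summary, name=meta.sample_id))
    write_table(pd.DataFrame(summaries).rename_axis("sample_id").reset_index(),
                stage_dir / "genome_cpg_summary.tsv")

    matrix = methylation.build_methylation_matrix(
        per_sample, bins, classes=config.methylation.classes
    )
    out = matrix.values.copy()
    out.insert(0, "class", matrix.classes)
    write_table(out.rename_axis("bin").reset_index(), stage_dir / "methylation_matrix.tsv")

    coords, ev = methylation.run_pca(matrix, config.methylation.n_components)
    coords = coords.rename_axis("sample_id").reset_index()
    write_table(coords, stage_dir / "pca_coordinates.tsv")
    write_table(pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(ev))],
                              "explained_variance_fraction": ev}),
                stage_dir / "pca_explained_variance.tsv")

    tumor_ids = [m.sample_id for m in metas if m.group == "tumor"]
    tumor_matrix = methylation.MethylationMatrix(matrix.bins, matrix.values[tumor_ids])
    clusters, linkage = methylation.ward_cluster(tumor_matrix, k=2)
    write_table(clusters.rename_axis("sample_id").reset_index(), stage_dir / "tumor_clusters.tsv")
    write_table(pd.DataFrame(linkage, columns=["left", "right", "height", "size"]),
                stage_dir / "tumor_linkage.tsv")

    groups = methylation.hrd_group(metas, cutoff=config.methylation.hrd_cutoff)
    write_table(pd.DataFrame([vars(g) if not hasattr(g, "__slots__")
                              else {k: getattr(g, k) for k in ("sample_id", "group", "score")}
                              for g in groups]),
                stage_dir / "hrd_groups.tsv")

    high = {g.sample_id for g in groups if g.group == "high"}
    low = {g.sample_id for g in groups if g.group == "low"}
    test_rows = []
    classes = sorted({b.label for b in bins})
    bin_class = np.array([b.label for b in matrix.bins])
    for cls in classes:
        mask = bin_class == cls
        if not mask.any():
            continue
        vals_high = matrix.values.loc[mask, sorted(high)].to_numpy().ravel()
        vals_low = matrix.values.loc[mask, sorted(low)].to_numpy().ravel()
        if len(vals_high) >= 2 and len(vals_low) >= 2:
            t, p = methylation.group_mean_test(vals_high, vals_low)
            test_rows.append({"class": cls, "t": t, "p_value": p,
                              "mean_high_hrd": float(np.nanmean(vals_high)),
                              "mean_low_hrd": float(np.nanmean(vals_low))})
    write_table(pd.DataFrame(test_rows), stage_dir / "hrd_group_tests.tsv")
    _finish_stage(stage_dir, "methylation", config)


def _stage_thor(config: PipelineConfig, outdir: Path) -> None:
    stage_dir = _fresh_dir(outdir, "thor")
    inputs = outdir / "inputs"
    truth = pd.read_csv(inputs / "thor_truth.tsv", sep="\t")
    call_rows = []
    profiles = []
    for row in truth.itertuples(index=False):
        sid = row.sample_id
        records = read_bedmethyl(inputs / f"{sid}.phased.bedmethyl",
                                 haplotype_column=18)
        if config.thor.thor_region:
            chrom, span = config.thor.thor_region.split(":")
            start, end = (int(x) for x in span.split("-"))
        else:
            chrom, start, end = row.chrom, int(row.thor_start), int(row.thor_end)
        region = GenomicInterval(chrom, 0, max(int(records["end"].max()), end), "locus")
        thor_region = GenomicInterval(chrom, start, end, "THOR")
        tracks = allele.site_methylation_by_haplotype(
            records, region, window=config.thor.window
        )
        call = allele.classify_thor(
            tracks, thor_region,
            hyper_threshold=config.thor.hyper_threshold,
            hypo_threshold=config.thor.hypo_threshold,
            sample_id=sid,
        )
        call_rows.append({
            "sample_id": sid, "call": call.call,
            "hap1_mean": call.hap_means[0], "hap2_mean": call.hap_means[1],
            "indeterminate": call.indeterminate,
            "hyper_threshold": call.hyper_threshold,
            "hypo_threshold": call.hypo_threshold,
        })
        prof = allele.tracks_table(tracks)
        prof.insert(0, "sample_id", sid)
        profiles.append(prof)
    write_table(pd.DataFrame(call_rows), stage_dir / "thor_calls.tsv")
    write_table(pd.concat(profiles, ignore_index=True), stage_dir / "thor_profiles.tsv")
    _finish_stage(stage_dir, "thor", config)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sv": _stage_sv,
    "signatures": _stage_signatures,
    "coverage": _stage_coverage,
    "methylation": _stage_methylation,
    "thor": _stage_thor,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the enabled stages in dependency order; returns a run manifest.

    A stage failure raises :class:`StageError` naming the stage; its partial
    outputs lack a manifest and are therefore flagged stale.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = stages if stages is not None else [
        s for s in STAGE_ORDER if getattr(config, s).enabled
    ]
    ran = []
    for stage in STAGE_ORDER:
        if stage not in selected:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
        ran.append(stage)
    return {"stages": ran, "config_hash": config.config_hash(), "outdir": str(outdir)}
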
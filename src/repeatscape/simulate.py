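"""Synthetic cohort generator for every pipeline input.

Emulates the statistical structure the downstream analyses assume, so each
stage can be tested against planted truth without controlled-access data:

* a mini reference genome with satellite/TE annotations whose lengths
  straddle the full-length TE filters,
* per-sample depth tracks from a gamma-Poisson (negative-binomial) model
  with tumor-specific dispersion inflation inside TE spans,
* CpG methylomes with beta-binomial site noise and planted group means
  (normal > high-HRD tumor > low-HRD tumor in satellite classes),
* four caller-attributed SV call sets derived from a truth table with
  controlled per-caller sensitivity, breakpoint jitter, and caller-private
  false positives,
* mutation catalogs drawn multinomially from known signature mixtures,
* a phased promoter locus with per-haplotype methylation for THOR calling.

Randomness: one master seed; every (operation, sample) pair gets its own
stream via stable hashing, so adding a sample never reshuffles another
sample's data, and every generator is byte-deterministic for a fixed seed.

Truth identifiability: truth SV breakpoints are placed on a coarse grid
(spacing well above the matching tolerance) and per-caller jitter is a
truncated normal bounded so that calls of the same event always match and
calls of different events never do; intra-chromosomal jitter shifts both
breakpoints by one offset so the caller-reported length equals the truth
length (long-read callers agree on length far more than on placement).
Consensus merging on these call sets is therefore exactly predictable from
the truth table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BEDMETHYL_COLUMNS,
    DEPTH_COLUMNS,
    GenomicInterval,
    SampleMeta,
    SignatureMatrix,
    SVRecord,
    write_bed,
    write_sv_vcf,
)
from .signatures import MutationCatalog, sbs96_channels

SATELLITE_CLASSES = (
    "active_hor", "inactive_hor", "divergent", "monomeric",
    "hsat1A", "hsat1B", "hsat2", "hsat3", "beta", "gamma",
)
TE_CLASSES = ("L1HS", "AluY", "SVA", "ERV")

#: planted per-class mean 5mC for (normal, tumor high-HRD, tumor low-HRD)
DEFAULT_METHYLATION_EFFECTS: dict[str, tuple[float, float, float]] = {
    **{c: (0.75, 0.55, 0.35) for c in SATELLITE_CLASSES},
    "L1HS": (0.85, 0.60, 0.45),
    "ERV": (0.85, 0.60, 0.45),
    "AluY": (0.85, 0.75, 0.70),
    "SVA": (0.85, 0.75, 0.70),
    "background": (0.75, 0.62, 0.58),
}

DEFAULT_CALLER_SENSITIVITIES = {
    "severus": 0.95, "savana": 0.90, "nanomonsv": 0.85, "delly": 0.80,
}


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    spans: tuple[tuple[int, int, str], ...] = ()  # (start, end, class)


@dataclass(frozen=True)
class PhasedLocusSpec:
    """Promoter locus layout and per-haplotype planted methylation."""

    chrom: str = "chr5_locus"
    promoter: tuple[int, int] = (0, 3000)
    thor: tuple[int, int] = (1000, 2000)
    hap_means_thor: tuple[float, float] = (0.1, 0.1)
    hap_means_background: tuple[float, float] = (0.15, 0.15)
    cpg_spacing: float = 15.0       # mean bp between CpG sites
    coverage_mean: float = 12.0     # reads per haplotype per site
    low_coverage_fraction: float = 0.1   # sites drawn from a sparse regime
    low_coverage_mean: float = 1.5
    beta_concentration: float = 25.0


def default_genome_spec() -> tuple[ChromSpec, ...]:
    """Two-chromosome 1.6-Mb mini genome.

    Satellite arrays sit on chr1, TE insertions on both; TE lengths straddle
    the full-length filters (L1HS: 4 of 10 above 6 kb, AluY: 40 of 60 above
    300 bp, SVA: 8 of 12 above 1 kb, ERV: 4 of 6 above 1 kb).
    """
    chr1_spans: list[tuple[int, int, str]] = [
        (100_000, 300_000, "active_hor"),
        (320_000, 370_000, "inactive_hor"),
        (380_000, 395_000, "divergent"),
        (400_000, 430_000, "hsat2"),
        (435_000, 450_000, "hsat3"),
        (455_000, 470_000, "monomeric"),
        (475_000, 490_000, "hsat1A"),
        (492_000, 498_000, "hsat1B"),
    ]
    pos = 520_000
    for i in range(10):
        length = 6_500 + 400 * i if i < 4 else 3_000 + 300 * i
        chr1_spans.append((pos, pos + length, "L1HS"))
        pos += length + 2_000
    for i in range(12):
        length = 1_200 + 100 * i if i < 8 else 800
        chr1_spans.append((pos, pos + length, "SVA"))
        pos += length + 1_500

    chr2_spans: list[tuple[int, int, str]] = [
        (20_000, 40_000, "beta"),
        (45_000, 60_000, "gamma"),
    ]
    pos = 80_000
    for i in range(60):
        length = 310 if i < 40 else 280
        chr2_spans.append((pos, pos + length, "AluY"))
        pos += length + 700
    for i in range(6):
        length = 1_500 + 500 * i if i < 4 else 700
        chr2_spans.append((pos, pos + length, "ERV"))
        pos += length + 2_000

    return (
        ChromSpec("chr1", 1_000_000, tuple(chr1_spans)),
        ChromSpec("chr2", 600_000, tuple(chr2_spans)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the synthetic cohort; defaults define the study-like
    conditions (six tumor/normal pairs, ~30x coverage, planted satellite
    hypomethylation ordering, four callers of mixed sensitivity)."""

    seed: int = 0
    n_pairs: int = 6
    genome_spec: tuple[ChromSpec, ...] = field(default_factory=default_genome_spec)
    depth_mean: float = 30.0
    depth_dispersion: float = 0.05          # NB: var = m + phi m^2
    depth_resolution: int = 100             # bp per depth interval
    tumor_variance_inflation: float = 4.0   # multiplies phi inside TE spans
    methylation_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METHYLATION_EFFECTS)
    )
    beta_concentration: float = 30.0        # site-to-site 5mC heterogeneity
    coverage_dropout: float = 0.01          # fraction of CpGs with no mapped reads
    caller_sensitivities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALLER_SENSITIVITIES)
    )
    n_sv: int = 200
    n_fp_per_caller: int = 10
    breakpoint_jitter_sd: float = 100.0
    sv_grid_spacing: int = 2_500            # >> 2 x matching tolerance
    sv_min_size: int = 30
    sv_max_size: int = 100_000
    exposure_truth: Mapping[str, Sequence[float]] | None = None
    catalog_size: int = 5_000
    hrd_cutoff: int = 63

    def __post_init__(self):
        for caller, p in self.caller_sensitivities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"sensitivity for {caller} outside [0,1]")
        for cls, means in self.methylation_effects.items():
            if any(not 0 <= m <= 1 for m in means):
                raise ValueError(f"methylation means for {cls} outside [0,1]")
        if self.exposure_truth is not None:
            for sid, w in self.exposure_truth.items():
                if abs(sum(w) - 1) > 1e-8:
                    raise ValueError(f"exposure weights for {sid} must sum to 1")
        for spec in self.genome_spec:
            if spec.length <= 0:
                raise ValueError(f"chromosome {spec.name} length must be positive")


def _rng(config: SimulationConfig, operation: str, sample: str = "") -> np.random.Generator:
    """Independent stream per (operation, sample), stable under cohort edits."""
    tag = zlib.crc32(f"{operation}|{sample}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


# ---------------------------------------------------------------------------
# cohort sheet
# ---------------------------------------------------------------------------

def make_cohort(config: SimulationConfig) -> list[SampleMeta]:
    """Tumor/normal pairs with planted HRD structure.

    The first half of the tumors (rounded up) gets scores above the cutoff,
    the rest below; scar components are drawn to sum to the score.
    """
    rng = _rng(config, "cohort")
    metas: list[SampleMeta] = []
    n_high = (config.n_pairs + 1) // 2
    for i in range(config.n_pairs):
        pair = f"P{i + 1}"
        if i < n_high:
            score = int(rng.integers(config.hrd_cutoff + 2, config.hrd_cutoff + 30))
        else:
            score = int(rng.integers(15, config.hrd_cutoff - 10))
        lst = int(rng.integers(score // 4, score // 2 + 1))
        loh = int(rng.integers((score - lst) // 3, (score - lst) // 2 + 1))
        tai = score - lst - loh
        metas.append(SampleMeta(
            sample_id=f"T{i + 1}", group="tumor", pair_id=pair,
            hrd_score=score, lst=lst, loh=loh, tai=tai,
            brca1_germline="present" if (i < n_high and i % 2 == 0) else "absent",
            ccne1_amp="present" if (i >= n_high and i % 2 == 1) else "absent",
            purity=float(np.round(rng.uniform(0.35, 0.95), 2)),
            ploidy=float(np.round(rng.uniform(1.8, 4.6), 2)),
        ))
        metas.append(SampleMeta(sample_id=f"N{i + 1}", group="normal", pair_id=pair))
    return metas


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [vars(m) if not hasattr(m, "__slots__") else
            {k: getattr(m, k) for k in m.__slots__} for m in metas]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _methylation_group(meta: SampleMeta, cutoff: int) -> int:
    """Column index into the (normal, tumor_highHRD, tumor_lowHRD) triples."""
    if meta.group == "normal":
        return 0
    if meta.hrd_score is None:
        raise ValueError(f"tumor {meta.sample_id} lacks an HRD score")
    return 1 if meta.hrd_score >= cutoff else 2


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiniReference:
    sequences: Mapping[str, str]
    annotation: tuple[GenomicInterval, ...]
    cpg_sites: Mapping[str, np.ndarray]  # CpG start positions per chromosome

    @property
    def contigs(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.sequences.items()]

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "reference.fa"
        bed = outdir / "annotation.bed"
        with open(fasta, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_bed(self.annotation, bed)
        return fasta, bed


def make_mini_reference(config: SimulationConfig) -> MiniReference:
    """Random-sequence reference plus annotation from the genome spec.

    Deterministic for a fixed seed; overlapping spans of the same class are
    rejected (they would double-count bins downstream).
    """
    total = sum(s.length for s in config.genome_spec)
    if total > 10_000_000:
        raise ValueError("genome spec exceeds 10 Mb")
    rng = _rng(config, "reference")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequences: dict[str, str] = {}
    annotation: list[GenomicInterval] = []
    cpg: dict[str, np.ndarray] = {}
    for spec in config.genome_spec:
        by_class: dict[str, list[tuple[int, int]]] = {}
        for start, end, label in spec.spans:
            if not (0 <= start < end <= spec.length):
                raise ValueError(f"span [{start},{end}) outside {spec.name}")
            for s, e in by_class.setdefault(label, []):
                if start < e and s < end:
                    raise ValueError(
                        f"overlapping {label} spans on {spec.name}: "
                        f"[{s},{e}) and [{start},{end})"
                    )
            by_class[label].append((start, end))
            annotation.append(GenomicInterval(spec.name, start, end, label))
        seq = rng.choice(bases, size=spec.length)
        arr = seq.view(np.uint8)
        is_cpg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        cpg[spec.name] = np.flatnonzero(is_cpg).astype(np.int64)
        sequences[spec.name] = seq.tobytes().decode("ascii")
    return MiniReference(sequences, tuple(annotation), cpg)


def _class_spans(reference: MiniReference, classes: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-chromosome sorted (start, end) arrays for the requested classes."""
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in reference.annotation:
        if iv.label in set(classes):
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {k: np.asarray(sorted(v), dtype=np.int64) for k, v in out.items()}


def _label_positions(reference: MiniReference, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Annotation class label per position ('background' outside all spans)."""
    labels = np.full(len(positions), "background", dtype=object)
    spans = [(iv.start, iv.end, iv.label) for iv in reference.annotation if iv.chrom == chrom]
    for start, end, label in spans:
        mask = (positions >= start) & (positions < end)
        labels[mask] = label
    return labels


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def simulate_depth_track(
    config: SimulationConfig,
    reference: MiniReference,
    meta: SampleMeta,
) -> pd.DataFrame:
    """Gamma-Poisson depth per ``depth_resolution``-bp interval.

    Var = m + phi m^2; tumors get phi multiplied by
    ``tumor_variance_inflation`` inside TE spans, emulating the elevated
    coverage dispersion of tumor genomes over mobile elements.
    """
    rng = _rng(config, "depth", meta.sample_id)
    te_spans = _class_spans(reference, TE_CLASSES)
    frames = []
    m = config.depth_mean
    for chrom, length in reference.contigs:
        starts = np.arange(0, length, config.depth_resolution, dtype=np.int64)
        ends = np.minimum(starts + config.depth_resolution, length)
        phi = np.full(len(starts), config.depth_dispersion)
        if meta.group == "tumor" and chrom in te_spans:
            spans = te_spans[chrom]
            idx = np.searchsorted(spans[:, 0], starts, side="right") - 1
            in_te = (idx >= 0) & (starts < spans[np.clip(idx, 0, None), 1])
            phi[in_te] *= config.tumor_variance_inflation
        lam = rng.gamma(shape=1.0 / phi, scale=m * phi)
        depth = rng.poisson(lam).astype(float)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "depth": depth,
        }))
    return pd.concat(frames, ignore_index=True)[DEPTH_COLUMNS]


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    config: SimulationConfig,
    reference: MiniReference,
    meta: SampleMeta,
) -> pd.DataFrame:
    """Per-CpG 5mC calls: n_valid ~ Poisson(depth), site mean beta-perturbed
    around the planted class/group mean, n_mod ~ Binomial(n_valid, site mean).

    Sites with drawn coverage 0 are retained with n_valid = 0.
    """
    rng = _rng(config, "methylome", meta.sample_id)
    col = _methylation_group(meta, config.hrd_cutoff)
    conc = config.beta_concentration
    frames = []
    for chrom, _length in reference.contigs:
        positions = reference.cpg_sites[chrom]
        if len(positions) == 0:
            continue
        labels = _label_positions(reference, chrom, positions)
        means = np.empty(len(positions))
        for cls in np.unique(labels):
            triple = config.methylation_effects.get(
                cls, config.methylation_effects["background"]
            )
            means[labels == cls] = triple[col]
        means = np.clip(means, 1e-4, 1 - 1e-4)
        p_site = rng.beta(means * conc, (1 - means) * conc)
        n_valid = rng.poisson(config.depth_mean, size=len(positions))
        # mapping dropout: a small fraction of CpGs receive no reads at all
        n_valid[rng.random(len(positions)) < config.coverage_dropout] = 0
        n_mod = rng.binomial(n_valid, p_site)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": positions,
            "end": positions + 2,
            "strand": "+",
            "n_valid": n_valid,
            "n_mod": n_mod,
            "haplotype": "unphased",
        }))
    return pd.concat(frames, ignore_index=True)[BEDMETHYL_COLUMNS]


# ---------------------------------------------------------------------------
# SV call sets
# ---------------------------------------------------------------------------

_SV_TYPE_PROBS = {"DEL": 0.35, "DUP": 0.20, "INV": 0.15, "INS": 0.20, "TRA": 0.10}


def _truncated_normal(rng: np.random.Generator, sd: float, size: int,
                      bound_sd: float = 2.4) -> np.ndarray:
    """Normal jitter truncated at +/- bound_sd standard deviations, so two
    independent draws can never differ by more than the matching tolerance."""
    draws = rng.normal(0.0, sd, size=size)
    limit = bound_sd * sd
    return np.clip(draws, -limit, limit)


def simulate_sv_callsets(
    config: SimulationConfig,
    reference: MiniReference,
    meta: SampleMeta,
) -> tuple[dict[str, list[SVRecord]], pd.DataFrame]:
    """Truth SV set plus four caller-attributed call sets.

    Returns (callsets keyed by caller, truth table).  The truth table has
    one row per event with columns chrom1/pos1/chrom2/pos2/svtype/svlen,
    one boolean column per caller, and n_detected.  See the module docstring
    for the identifiability guarantees.
    """
    rng = _rng(config, "sv", meta.sample_id)
    callers = list(config.caller_sensitivities)
    contigs = reference.contigs
    spacing = config.sv_grid_spacing
    jitter_sd = config.breakpoint_jitter_sd
    if spacing <= 2 * 2.4 * jitter_sd:
        raise ValueError("sv_grid_spacing must exceed twice the truncated jitter range")

    # one global pool of grid breakpoints per chromosome, consumed without
    # replacement by truth events and false positives alike
    pools: dict[str, list[int]] = {}
    for chrom, length in contigs:
        grid = np.arange(spacing, length - config.sv_min_size - spacing, spacing)
        pools[chrom] = list(rng.permutation(grid))

    def take_point(chrom: str) -> int:
        if not pools[chrom]:
            raise ValueError(f"breakpoint grid exhausted on {chrom}; enlarge genome")
        return int(pools[chrom].pop())

    chrom_names = [c for c, _ in contigs]
    chrom_lengths = dict(contigs)
    types = rng.choice(list(_SV_TYPE_PROBS), p=list(_SV_TYPE_PROBS.values()),
                       size=config.n_sv)

    truth_rows = []
    for svtype in types:
        if svtype == "TRA" and len(chrom_names) >= 2:
            c1, c2 = rng.choice(len(chrom_names), size=2, replace=False)
            chrom1, chrom2 = chrom_names[c1], chrom_names[c2]
            pos1, pos2 = take_point(chrom1), take_point(chrom2)
            if (chrom1, pos1) > (chrom2, pos2):
                chrom1, chrom2, pos1, pos2 = chrom2, chrom1, pos2, pos1
            svlen = 0
        else:
            if svtype == "TRA":
                svtype = "DEL"  # single-chromosome genome cannot host a TRA
            chrom1 = chrom_names[int(rng.integers(len(chrom_names)))]
            chrom2 = chrom1
            pos1 = take_point(chrom1)
            max_size = min(config.sv_max_size, chrom_lengths[chrom1] - pos1 - spacing)
            max_size = max(max_size, config.sv_min_size + 1)
            svlen = int(np.exp(rng.uniform(np.log(config.sv_min_size), np.log(max_size))))
            pos2 = pos1 if svtype == "INS" else pos1 + svlen
        truth_rows.append({
            "event_id": len(truth_rows), "chrom1": chrom1, "pos1": pos1,
            "chrom2": chrom2, "pos2": pos2, "svtype": svtype, "svlen": svlen,
        })
    truth = pd.DataFrame(truth_rows)

    detected = {}
    for caller in callers:
        detected[caller] = rng.random(len(truth)) < config.caller_sensitivities[caller]
        truth[caller] = detected[caller]
    truth["n_detected"] = sum(truth[c].astype(int) for c in callers)

    callsets: dict[str, list[SVRecord]] = {c: [] for c in callers}
    for row in truth.itertuples(index=False):
        for caller in callers:
            if not getattr(row, caller):
                continue
            if row.svtype == "TRA":
                j1 = _truncated_normal(rng, jitter_sd, 1)[0]
                j2 = _truncated_normal(rng, jitter_sd, 1)[0]
                pos1 = int(round(row.pos1 + j1))
                pos2 = int(round(row.pos2 + j2))
                rec = SVRecord(row.chrom1, max(pos1, 0), row.chrom2, max(pos2, 0),
                               "TRA", 0, caller, meta.sample_id)
            else:
                # shift, don't resize: callers agree on length, not placement
                sd = min(jitter_sd, max(row.svlen / 10.0, 1.0))
                shift = int(round(_truncated_normal(rng, sd, 1)[0]))
                pos1 = max(row.pos1 + shift, 0)
                pos2 = pos1 if row.svtype == "INS" else pos1 + row.svlen
                rec = SVRecord(row.chrom1, pos1, row.chrom2, pos2,
                               row.svtype, row.svlen, caller, meta.sample_id)
            callsets[caller].append(rec)

    # caller-private false positives from the same exclusive grid
    fp_types = [t for t in _SV_TYPE_PROBS if t != "TRA"]
    for caller in callers:
        for _ in range(config.n_fp_per_caller):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos1 = take_point(chrom)
            svtype = fp_types[int(rng.integers(len(fp_types)))]
            max_size = min(config.sv_max_size, chrom_lengths[chrom] - pos1 - spacing)
            max_size = max(max_size, config.sv_min_size + 1)
            svlen = int(np.exp(rng.uniform(np.log(config.sv_min_size), np.log(max_size))))
            pos2 = pos1 if svtype == "INS" else pos1 + svlen
            callsets[caller].append(
                SVRecord(chrom, pos1, chrom, pos2, svtype, svlen, caller, meta.sample_id)
            )
    return callsets, truth


def write_sv_callsets(
    callsets: Mapping[str, Sequence[SVRecord]],
    truth: pd.DataFrame,
    reference: MiniReference,
    outdir: str | Path,
    sample_id: str,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for caller, records in callsets.items():
        path = outdir / f"{sample_id}.{caller}.vcf"
        write_sv_vcf(records, path, reference.contigs)
        paths[caller] = path
    truth_path = outdir / f"{sample_id}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

def make_signature_matrix(
    config: SimulationConfig,
    n_signatures: int = 5,
    channels: Sequence[str] | None = None,
    concentration: float = 0.3,
) -> SignatureMatrix:
    """Random spiky reference signatures (Dirichlet columns) over the SBS96
    channel set by default; deterministic for a fixed seed."""
    rng = _rng(config, "signature_matrix")
    channels = list(channels) if channels is not None else sbs96_channels()
    cols = {}
    for k in range(n_signatures):
        cols[f"SIG{k + 1}"] = rng.dirichlet(np.full(len(channels), concentration))
    return SignatureMatrix(pd.DataFrame(cols, index=pd.Index(channels, name="Type")))


def simulate_mutation_catalog(
    config: SimulationConfig,
    meta: SampleMeta,
    signatures: SignatureMatrix,
    weights: Sequence[float] | None = None,
) -> tuple[MutationCatalog, np.ndarray]:
    """Catalog ~ Multinomial(catalog_size, S w) for truth weights w.

    Weights come from, in order: the explicit argument, the config's
    ``exposure_truth`` entry for the sample, or a Dirichlet(1) draw from the
    sample's stream.  Returns (catalog, weights used).
    """
    rng = _rng(config, "catalog", meta.sample_id)
    n_sig = len(signatures.names)
    if weights is None and config.exposure_truth is not None:
        weights = config.exposure_truth.get(meta.sample_id)
    if weights is None:
        w = rng.dirichlet(np.ones(n_sig))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n_sig:
            raise ValueError(f"need {n_sig} weights, got {len(w)}")
        if (w < 0).any() or abs(w.sum() - 1) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
    probs = signatures.table.to_numpy() @ w
    counts = rng.multinomial(config.catalog_size, probs)
    catalog = MutationCatalog(meta.sample_id, tuple(signatures.channels), counts)
    return catalog, w


# ---------------------------------------------------------------------------
# phased promoter locus
# ---------------------------------------------------------------------------

def simulate_phased_locus(
    config: SimulationConfig,
    locus: PhasedLocusSpec | None = None,
    sample: str = "",
) -> pd.DataFrame:
    """Haplotype-tagged CpG call table over a promoter locus.

    Site read support is variable: a ``low_coverage_fraction`` of sites per
    haplotype draws coverage from a sparse Poisson regime, so sites with
    fewer than three reads on one haplotype occur and exercise the
    read-support filter.
    """
    locus = locus or PhasedLocusSpec()
    rng = _rng(config, "phased_locus", sample)
    start, end = locus.promoter
    gaps = rng.exponential(locus.cpg_spacing, size=int(2 * (end - start) / locus.cpg_spacing))
    positions = start + np.cumsum(2 + gaps.astype(np.int64))
    positions = np.unique(positions[positions < end - 1])
    thor_lo, thor_hi = locus.thor
    in_thor = (positions >= thor_lo) & (positions < thor_hi)
    rows = []
    for hap_idx, hap in enumerate(("1", "2")):
        mean_thor = locus.hap_means_thor[hap_idx]
        mean_bg = locus.hap_means_background[hap_idx]
        means = np.where(in_thor, mean_thor, mean_bg)
        means = np.clip(means, 1e-4, 1 - 1e-4)
        conc = locus.beta_concentration
        p_site = rng.beta(means * conc, (1 - means) * conc)
        sparse = rng.random(len(positions)) < locus.low_coverage_fraction
        lam = np.where(sparse, locus.low_coverage_mean, locus.coverage_mean)
        n_valid = rng.poisson(lam)
        n_mod = rng.binomial(n_valid, p_site)
        for pos, v, m in zip(positions, n_valid, n_mod):
            rows.append((locus.chrom, int(pos), int(pos) + 2, "+", int(v), int(m), hap))
    df = pd.DataFrame(rows, columns=BEDMETHYL_COLUMNS)
    return df.sort_values(["start", "haplotype"], kind="stable").reset_index(drop=True)
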
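"""Mutation catalogs (SBS96, SV32) and NNLS signature refitting.

A sample's mutation catalog is a count vector over a fixed channel set:
96 pyrimidine-strand trinucleotide substitution classes for single base
substitutions, or 32 rearrangement classes ({clustered, non-clustered} x
{del, tds, inv} x five size bins, plus clustered/non-clustered
translocations).  Exposures to reference signatures are refit by
non-negative least squares: e = argmin ||c - S e||_2 s.t. e >= 0, and
reported both as counts and as percent contributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from pyfaidx import Fasta

from .io import FormatError, SignatureMatrix
from .sv import ConsensusSV

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

# clustered-SV density rule defaults (the breakpoint-density stand-in for
# full piecewise-constant-fit clustering)
CLUSTER_MIN_BREAKPOINTS = 10
CLUSTER_WINDOW = 5_000_000  # bp


def sbs96_channels() -> list[str]:
    """The 96 channel labels in COSMIC order, e.g. ``A[C>A]A``."""
    return [
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    ]


_SV32_SIZE_BINS = ("1-10Kb", "10-100Kb", "100Kb-1Mb", "1Mb-10Mb", ">10Mb")
_SV32_SIZE_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)


def sv32_channels() -> list[str]:
    """The 32 rearrangement channel labels in COSMIC order."""
    chans = []
    for clust in ("clustered", "non-clustered"):
        for kind in ("del", "tds", "inv"):
            for size in _SV32_SIZE_BINS:
                chans.append(f"{clust}_{kind}_{size}")
        chans.append(f"{clust}_trans")
    return chans


@dataclass(frozen=True)
class MutationCatalog:
    """Per-sample channel counts, aligned by label to a SignatureMatrix."""

    sample_id: str
    channels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.channels),):
            raise ValueError("counts length must equal channel count")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.isfinite(counts).all():
            raise ValueError("counts must be finite")
        # observed catalogs are integer tallies; exactly-constructed mixture
        # vectors (solver fixtures) may be real-valued
        if np.issubdtype(counts.dtype, np.integer) or np.all(counts == np.floor(counts)):
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.float64)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.channels), name=self.sample_id)


@dataclass(frozen=True)
class ExposureVector:
    """Fitted nonnegative exposures per signature and percent contributions."""

    sample_id: str
    signatures: tuple[str, ...]
    exposures: np.ndarray
    residual_norm: float

    @property
    def percent(self) -> np.ndarray:
        total = self.exposures.sum()
        if total == 0:
            return np.zeros_like(self.exposures)
        return 100.0 * self.exposures / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "signature": list(self.signatures),
                "exposure": self.exposures,
                "percent": self.percent,
            }
        )


# ---------------------------------------------------------------------------
# SBS96 catalog
# ---------------------------------------------------------------------------

def build_sbs96_catalog(
    snvs: Sequence[tuple[str, int, str, str]],
    reference: str | Fasta,
    sample_id: str = "",
) -> MutationCatalog:
    """Tally substitutions into the 96 trinucleotide channels.

    ``snvs`` holds (chrom, pos0, ref, alt) with 0-based positions.  The
    channel is keyed on the pyrimidine strand: substitutions with a purine
    reference are reverse-complemented together with their flanking context.
    A ref allele disagreeing with the reference sequence is a record-level
    error listing the offending positions.
    """
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    channels = sbs96_channels()
    index = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(len(channels), dtype=np.int64)
    mismatches: list[str] = []
    for chrom, pos, ref, alt in snvs:
        ref, alt = ref.upper(), alt.upper()
        tri = str(fasta[chrom][pos - 1 : pos + 2]).upper()
        if len(tri) < 3 or tri[1] != ref:
            mismatches.append(f"{chrom}:{pos} (ref {ref!r}, sequence {tri!r})")
            continue
        if ref in "AG":  # purine reference: flip to pyrimidine strand
            tri = tri.translate(_COMPLEMENT)[::-1]
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        counts[index[f"{tri[0]}[{ref}>{alt}]{tri[2]}"]] += 1
    if mismatches:
        raise FormatError(
            "reference allele mismatch at: " + "; ".join(mismatches[:10])
            + ("" if len(mismatches) <= 10 else f" (+{len(mismatches) - 10} more)")
        )
    return MutationCatalog(sample_id, tuple(channels), counts)


# ---------------------------------------------------------------------------
# SV32 catalog
# ---------------------------------------------------------------------------

def _size_bin(svlen: int) -> str:
    # sizes below 1 kb fall into the smallest bin
    for edge, label in zip(_SV32_SIZE_EDGES, _SV32_SIZE_BINS):
        if svlen < edge:
            return label
    return _SV32_SIZE_BINS[-1]


def assign_clustered(consensus: Sequence[ConsensusSV],
                     min_breakpoints: int = CLUSTER_MIN_BREAKPOINTS,
                     window: int = CLUSTER_WINDOW) -> list[bool]:
    """Density rule: an SV is clustered when >= ``min_breakpoints`` consensus
    breakpoints lie within ``window`` bp around one of its own breakpoints on
    the same chromosome (the SV's own breakpoints count)."""
    by_chrom: dict[str, list[int]] = {}
    for c in consensus:
        r = c.representative
        by_chrom.setdefault(r.chrom1, []).append(r.pos1)
        by_chrom.setdefault(r.chrom2, []).append(r.pos2)
    sorted_bp = {k: np.sort(np.asarray(v)) for k, v in by_chrom.items()}

    def density(chrom: str, pos: int) -> int:
        bp = sorted_bp[chrom]
        lo = np.searchsorted(bp, pos - window // 2, side="left")
        hi = np.searchsorted(bp, pos + window // 2, side="right")
        return int(hi - lo)

    flags = []
    for c in consensus:
        r = c.representative
        flags.append(
            density(r.chrom1, r.pos1) >= min_breakpoints
            or density(r.chrom2, r.pos2) >= min_breakpoints
        )
    return flags


def build_sv32_catalog(
    consensus: Sequence[ConsensusSV],
    sample_id: str = "",
    min_breakpoints: int = CLUSTER_MIN_BREAKPOINTS,
    window: int = CLUSTER_WINDOW,
) -> MutationCatalog:
    """Tally consensus SVs of one sample into the 32 rearrangement channels.

    Insertions have no channel in the scheme and are skipped with a warning.
    Translocations ignore size.
    """
    channels = sv32_channels()
    index = {c: i for i, c in enumerate(channels)}
    counts = np.zeros(len(channels), dtype=np.int64)
    clustered = assign_clustered(consensus, min_breakpoints, window)
    n_ins = 0
    kind_map = {"DEL": "del", "DUP": "tds", "INV": "inv"}
    for c, is_clustered in zip(consensus, clustered):
        r = c.representative
        clust = "clustered" if is_clustered else "non-clustered"
        if r.svtype == "INS":
            n_ins += 1
            continue
        if r.svtype == "TRA":
            counts[index[f"{clust}_trans"]] += 1
        else:
            counts[index[f"{clust}_{kind_map[r.svtype]}_{_size_bin(r.svlen)}"]] += 1
    if n_ins:
        logger.warning("sample %s: %d insertion(s) skipped (no SV32 channel)", sample_id, n_ins)
    return MutationCatalog(sample_id, tuple(channels), counts)


# ---------------------------------------------------------------------------
# NNLS refit
# ---------------------------------------------------------------------------

def nnls_fit(catalog: MutationCatalog, signatures: SignatureMatrix) -> ExposureVector:
    """Refit a catalog against reference signatures by non-negative least
    squares (Lawson–Hanson active set via :func:`scipy.optimize.nnls`).

    Channels are aligned by label before solving; a label mismatch is an
    error listing unmatched labels.  An all-zero catalog yields all-zero
    exposures (percent defined as 0).
    """
    S = signatures.values_for(list(catalog.channels))
    c = catalog.counts.astype(float)
    if catalog.total == 0:
        exposures = np.zeros(S.shape[1])
        return ExposureVector(catalog.sample_id, tuple(signatures.names), exposures, 0.0)
    exposures, residual = scipy.optimize.nnls(S, c)
    return ExposureVector(catalog.sample_id, tuple(signatures.names), exposures, float(residual))


def exposures_table(exposures: Iterable[ExposureVector]) -> pd.DataFrame:
    """Samples x signatures table with exposure and percent columns."""
    frames = [e.to_frame() for e in exposures]
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot(index="sample_id", columns="signature", values=["exposure", "percent"])
    wide.columns = [f"{sig} (%)" if kind == "percent" else f"{sig}"
                    for kind, sig in wide.columns]
    return wide.reset_index()


def catalog_table(catalogs: Iterable[MutationCatalog]) -> pd.DataFrame:
    """Channels x samples catalog table (COSMIC layout)."""
    series = [c.to_series() for c in catalogs]
    out = pd.concat(series, axis=1)
    out.index.name = "Type"
    return out.reset_index()
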
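"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based half-open, the BED convention.  BED input
is never shifted; VCF positions are converted exactly once on input
(``pos_internal = pos_vcf - 1``) and back on output.  No other module
performs coordinate arithmetic across conventions.

Bulk per-site tables (bedMethyl CpG calls, depth tracks) are represented as
:class:`pandas.DataFrame` with fixed column schemas (see
:data:`BEDMETHYL_COLUMNS`, :data:`DEPTH_COLUMNS`); single-record dataclasses
are provided for row-level validation and round-trip tests.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "INS", "TRA")

#: column schema for bedMethyl site tables
BEDMETHYL_COLUMNS = ["chrom", "start", "end", "strand", "n_valid", "n_mod", "haplotype"]
#: column schema for depth tracks (mosdepth-style intervals)
DEPTH_COLUMNS = ["chrom", "start", "end", "depth"]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A labeled interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class BedMethylRecord:
    """One CpG site's 5mC call: modified / valid read counts, optionally phased."""

    site: GenomicInterval
    strand: str
    n_valid: int
    n_mod: int
    haplotype: str = "unphased"  # {"1", "2", "unphased"}

    def __post_init__(self):
        if not (0 <= self.n_mod <= self.n_valid):
            raise ValueError(f"require 0 <= n_mod <= n_valid, got {self.n_mod}/{self.n_valid}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def ratio(self) -> float | None:
        """5mC ratio = methylated reads / total reads; None when uncovered."""
        if self.n_valid == 0:
            return None
        return self.n_mod / self.n_valid


@dataclass(frozen=True, slots=True)
class DepthRecord:
    interval: GenomicInterval
    depth: float

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True, slots=True)
class SVRecord:
    """One breakpoint-pair somatic SV call attributed to a caller.

    Positions are internal 0-based.  ``svlen`` is 0 for translocations.
    """

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str
    svlen: int
    caller: str
    sample: str = ""

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svlen < 0:
            raise ValueError("svlen must be >= 0")
        if (self.svtype == "TRA") != (self.chrom1 != self.chrom2):
            raise ValueError("TRA iff chrom1 != chrom2")
        if self.svtype in {"DEL", "DUP", "INV"} and self.pos2 < self.pos1:
            raise ValueError("pos2 must be >= pos1 for intrachromosomal SVs")


class SignatureMatrix:
    """Reference mutational-signature matrix: channels x signatures.

    Each column is a probability distribution over the channel set (COSMIC
    layout: first TSV column holds channel labels, header holds signature
    names).
    """

    def __init__(self, table: pd.DataFrame, *, tol: float = 1e-3):
        if table.index.has_duplicates or table.columns.has_duplicates:
            raise FormatError("duplicate channel or signature labels")
        values = table.to_numpy(dtype=float)
        if (values < 0).any():
            raise FormatError("signature probabilities must be non-negative")
        sums = values.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
        if bad.size:
            names = ", ".join(f"{table.columns[i]} (sum {sums[i]:.4g})" for i in bad)
            raise FormatError(f"signature column(s) not normalized: {names}")
        self._table = table.astype(float)

    @property
    def channels(self) -> list[str]:
        return list(self._table.index)

    @property
    def names(self) -> list[str]:
        return list(self._table.columns)

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    def values_for(self, channels: Sequence[str]) -> np.ndarray:
        """Matrix reordered to the given channel labels (error on mismatch)."""
        missing = [c for c in channels if c not in self._table.index]
        extra = [c for c in self._table.index if c not in set(channels)]
        if missing or extra:
            raise FormatError(
                "channel label mismatch: "
                f"missing from matrix {missing[:5]}, unmatched in matrix {extra[:5]}"
            )
        return self._table.loc[list(channels)].to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SignatureMatrix({len(self.channels)} channels x {len(self.names)} signatures)"


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Per-sample metadata; scar scores are given inputs, never computed here."""

    sample_id: str
    group: str  # {"tumor", "normal"}
    pair_id: str
    hrd_score: int | None = None
    lst: int | None = None
    loh: int | None = None
    tai: int | None = None
    brca1_germline: str | None = None  # {"present", "absent"}
    ccne1_amp: str | None = None
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self):
        if self.group not in {"tumor", "normal"}:
            raise ValueError(f"group must be tumor/normal, got {self.group!r}")


# ---------------------------------------------------------------------------
# BED annotations
# ---------------------------------------------------------------------------

def read_bed_annotation(path: str | Path, class_column: int = 3) -> list[GenomicInterval]:
    """Read a BED file into labeled intervals, preserving input order.

    ``class_column`` is the 0-based column index carrying the class label
    (default: BED name field).  Coordinates are taken as-is (0-based
    half-open).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"expected >= 3 tab-separated columns, got {len(fields)}", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-integer coordinates: {exc}", lineno) from None
            label = fields[class_column] if class_column < len(fields) else ""
            try:
                intervals.append(GenomicInterval(fields[0], start, end, label))
            except ValueError as exc:
                raise FormatError(str(exc), lineno) from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

def read_depth_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4 depth track (mosdepth per-interval dialect) into a frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=DEPTH_COLUMNS, usecols=range(4),
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": float},
    )
    if (df["depth"] < 0).any():
        bad = int(df.index[df["depth"] < 0][0]) + 1
        raise FormatError("negative depth", bad)
    if (df["start"] >= df["end"]).any():
        bad = int(df.index[df["start"] >= df["end"]][0]) + 1
        raise FormatError("start >= end", bad)
    return df


def write_depth_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=DEPTH_COLUMNS, float_format="%.6g")


# ---------------------------------------------------------------------------
# bedMethyl (modkit dialect)
# ---------------------------------------------------------------------------

_HAPLOTYPE_PATTERNS = [
    (re.compile(r"(?:^|[._-])(?:hap(?:lotype)?)?1(?:[._-]|$)"), "1"),
    (re.compile(r"(?:^|[._-])(?:hap(?:lotype)?)?2(?:[._-]|$)"), "2"),
    (re.compile(r"ungrouped|unphased|untagged"), "unphased"),
]


def _haplotype_from_filename(path: Path) -> str | None:
    stem = path.name
    for ext in (".gz", ".bed", ".bedmethyl", ".bedMethyl", ".txt", ".tsv"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    for pattern, tag in _HAPLOTYPE_PATTERNS:
        if pattern.search(stem):
            return tag
    return None


def read_bedmethyl(
    path: str | Path,
    haplotype: str | None = None,
    haplotype_column: int | None = None,
) -> pd.DataFrame:
    """Read a modkit-style bedMethyl file (BED9+) into a site table.

    Both the traditional per-strand output and ``--cpg``-aggregated output
    share the column layout: N_valid at column 10 and N_mod at column 12
    (1-based).  Haplotype may come from an explicit ``haplotype`` tag, from a
    trailing column (``haplotype_column``, 0-based), or be inferred from
    modkit ``--partition-tag`` style file naming; precedence in that order.
    Records with ``n_valid == 0`` are retained (their ratio is undefined).
    """
    path = Path(path)
    if haplotype is None and haplotype_column is None:
        haplotype = _haplotype_from_filename(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"expected modkit bedMethyl (>= 10 columns), got {len(f)}", lineno)
            try:
                start, end = int(f[1]), int(f[2])
                n_valid = int(f[9])
                # full modkit layout carries N_mod at column 12; a minimal
                # BED9+2 dialect puts it right after N_valid
                n_mod = int(f[11]) if len(f) >= 12 else int(f[10])
            except ValueError as exc:
                raise FormatError(f"non-integer count field: {exc}", lineno) from None
            if n_mod > n_valid:
                raise FormatError(f"n_mod {n_mod} > n_valid {n_valid}", lineno)
            if haplotype_column is not None:
                if haplotype_column >= len(f):
                    raise FormatError(f"haplotype column {haplotype_column} absent", lineno)
                hap = f[haplotype_column]
            else:
                hap = haplotype or "unphased"
            if hap not in {"1", "2", "unphased"}:
                raise FormatError(f"bad haplotype tag {hap!r}", lineno)
            rows.append((f[0], start, end, f[5] if len(f) > 5 else ".", n_valid, n_mod, hap))
    df = pd.DataFrame(rows, columns=BEDMETHYL_COLUMNS)
    return df.astype({"start": np.int64, "end": np.int64, "n_valid": np.int64, "n_mod": np.int64})


def write_bedmethyl(df: pd.DataFrame, path: str | Path, *, write_haplotype: bool = False) -> None:
    """Write a site table in the 18-column modkit bedMethyl layout.

    With ``write_haplotype`` the tag is appended as a 19th column (read back
    via ``haplotype_column=18``).
    """
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            n_valid, n_mod = int(row.n_valid), int(row.n_mod)
            pct = 100.0 * n_mod / n_valid if n_valid else 0.0
            cols = [
                row.chrom, row.start, row.end, "m", n_valid, row.strand,
                row.start, row.end, "255,0,0", n_valid, f"{pct:.2f}",
                n_mod, n_valid - n_mod, 0, 0, 0, 0, 0,
            ]
            if write_haplotype:
                cols.append(row.haplotype)
            fh.write("\t".join(str(c) for c in cols) + "\n")


def bedmethyl_records(df: pd.DataFrame) -> list[BedMethylRecord]:
    """Materialize a site table as validated record objects (small inputs)."""
    return [
        BedMethylRecord(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            r.strand, int(r.n_valid), int(r.n_mod), r.haplotype,
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

_BND_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")

_SYMBOLIC_MAP = {
    "DEL": "DEL", "DUP": "DUP", "DUP:TANDEM": "DUP", "INV": "INV",
    "INS": "INS", "INS:ME": "INS", "TRA": "TRA", "CNV": "DUP",
}


def _parse_bnd_mate(alt: str) -> tuple[str, int] | None:
    m = _BND_RE.search(alt)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def read_sv_vcf(path: str | Path, caller: str, sample: str = "") -> tuple[list[SVRecord], int]:
    """Read somatic SV calls from one caller's VCF.

    Handles symbolic ALTs (``<DEL>`` etc., END/SVLEN info) and BND breakend
    notation; BND mate pairs are collapsed to a single record keyed on the
    lexicographically smaller breakpoint.  Unparseable records are skipped
    with a logged warning; the skip count is returned alongside the records.
    VCF 1-based positions are converted to internal 0-based here and nowhere
    else.
    """
    records: list[SVRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                parsed = _parse_sv_record(rec, caller, sample)
            except (ValueError, KeyError, TypeError):
                parsed = None
            if parsed is None:
                n_skipped += 1
                continue
            if parsed == "mate":  # second half of a BND pair
                continue
            records.append(parsed)
    if n_skipped:
        logger.warning("%s: skipped %d unparseable SV record(s) from caller %s",
                       path, n_skipped, caller)
    return records, n_skipped


def _parse_sv_record(rec, caller: str, sample: str):
    alt = rec.alts[0] if rec.alts else None
    if alt is None:
        return None
    info = dict(rec.info)
    svtype = info.get("SVTYPE")
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    chrom1, pos1 = rec.chrom, rec.start  # pysam .start is 0-based

    if alt.startswith("<") and alt.endswith(">"):
        symbol = alt[1:-1]
        svtype = _SYMBOLIC_MAP.get(symbol, _SYMBOLIC_MAP.get(symbol.split(":")[0]))
        if svtype is None or svtype == "TRA":
            return None
        svlen = info.get("SVLEN")
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        end0 = rec.stop - 1  # INFO END is 1-based inclusive; internal 0-based
        if svtype == "INS":
            pos2 = pos1
            svlen = abs(int(svlen)) if svlen is not None else max(end0 - pos1, 0)
        else:
            pos2 = max(end0, pos1)
            svlen = abs(int(svlen)) if svlen is not None else abs(pos2 - pos1)
        return SVRecord(chrom1, pos1, chrom1, pos2, svtype, int(svlen), caller, sample)

    mate = _parse_bnd_mate(alt)
    if mate is not None:
        chrom2, pos2_vcf = mate
        pos2 = pos2_vcf - 1
        if chrom2 == chrom1:
            # intrachromosomal breakend with no declared simple type: not
            # interpretable as DEL/DUP/INV here
            if svtype in {"DEL", "DUP", "INV"}:
                lo, hi = sorted((pos1, pos2))
                return SVRecord(chrom1, lo, chrom1, hi, svtype, hi - lo, caller, sample)
            return None
        if (chrom1, pos1) > (chrom2, pos2):
            return "mate"
        return SVRecord(chrom1, pos1, chrom2, pos2, "TRA", 0, caller, sample)

    # sequence-resolved ALT
    ref = rec.ref or ""
    if len(ref) == 1 and len(alt) > 1 and alt[0].upper() in "ACGTN":
        return SVRecord(chrom1, pos1, chrom1, pos1, "INS", len(alt) - 1, caller, sample)
    if len(ref) > 1 and len(alt) == 1 and alt[0].upper() in "ACGTN":
        return SVRecord(chrom1, pos1, chrom1, pos1 + len(ref) - 1, "DEL", len(ref) - 1, caller, sample)
    return None


_VCF_HEADER_INFO = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of supporting callers">
##INFO=<ID=SUPP_CALLERS,Number=1,Type=String,Description="Comma-separated supporting caller ids">
##INFO=<ID=MEMBERS,Number=1,Type=String,Description="Member breakpoints caller:chrom1:pos1:chrom2:pos2">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=INS,Description="Insertion">
"""


def write_sv_vcf(
    records: Sequence[SVRecord],
    path: str | Path,
    contigs: Sequence[tuple[str, int]],
    extra_info: dict[int, str] | None = None,
) -> None:
    """Write SV records as VCF 4.2 (symbolic ALTs; TRA as BND mate pairs)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(_VCF_HEADER_INFO)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(records):
            extra = extra_info.get(i, "") if extra_info else ""
            extra = ";" + extra if extra else ""
            if r.svtype == "TRA":
                a = f"{r.chrom1}\t{r.pos1 + 1}\tbnd_{i}_1\tN\tN[{r.chrom2}:{r.pos2 + 1}[\t.\tPASS\tSVTYPE=BND;MATEID=bnd_{i}_2{extra}\n"
                b = f"{r.chrom2}\t{r.pos2 + 1}\tbnd_{i}_2\tN\tN]{r.chrom1}:{r.pos1 + 1}]\t.\tPASS\tSVTYPE=BND;MATEID=bnd_{i}_1{extra}\n"
                fh.write(a + b)
            else:
                end = r.pos2 + 1 if r.svtype != "INS" else r.pos1 + 1
                fh.write(
                    f"{r.chrom1}\t{r.pos1 + 1}\tsv_{i}\tN\t<{r.svtype}>\t.\tPASS\t"
                    f"SVTYPE={r.svtype};END={end};SVLEN={r.svlen}{extra}\n"
                )


# ---------------------------------------------------------------------------
# signature matrix / sample sheet
# ---------------------------------------------------------------------------

def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a COSMIC-style signature TSV (channel labels in first column)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[1] == 0:
        raise FormatError("no signature columns found")
    return SignatureMatrix(table)


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    matrix.table.to_csv(path, sep="\t", index_label="Type")


_META_INT = ("hrd_score", "lst", "loh", "tai")
_META_FLOAT = ("purity", "ploidy")
_META_STR = ("brca1_germline", "ccne1_amp")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the cohort sample sheet; validate pairing and scar-score sums.

    Each pair_id must carry exactly one tumor and one normal, or a single
    normal.  A stated HRD score that is not LST + LOH + TAI raises a logged
    warning, not an error (the scores are given values).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing required column(s): {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s): {dupes}")

    metas: list[SampleMeta] = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for col in _META_INT:
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip():
                kwargs[col] = int(float(row[col]))  # tolerate float-formatted ints
        for col in _META_FLOAT:
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip():
                kwargs[col] = float(row[col])
        for col in _META_STR:
            if col in df.columns and pd.notna(row[col]) and str(row[col]).strip():
                kwargs[col] = str(row[col])
        meta = SampleMeta(row["sample_id"], row["group"], row["pair_id"], **kwargs)
        if all(getattr(meta, c) is not None for c in _META_INT):
            if meta.hrd_score != meta.lst + meta.loh + meta.tai:
                logger.warning(
                    "sample %s: hrd_score %d != lst+loh+tai = %d",
                    meta.sample_id, meta.hrd_score, meta.lst + meta.loh + meta.tai,
                )
        metas.append(meta)

    for pair_id, members in pd.DataFrame(
        [(m.pair_id, m.group) for m in metas], columns=["pair_id", "group"]
    ).groupby("pair_id"):
        counts = members["group"].value_counts().to_dict()
        ok = (counts.get("tumor", 0) == 1 and counts.get("normal", 0) == 1) or (
            counts.get("tumor", 0) == 0 and counts.get("normal", 0) == 1
        )
        if not ok:
            raise FormatError(
                f"pair {pair_id!r}: expected one tumor + one normal (or normal only), got {counts}"
            )
    return metas


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    """Write any output table as TSV (the pipeline's single table dialect)."""
    df.to_csv(path, sep="\t", index=index)
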
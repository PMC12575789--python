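"""Multi-caller somatic SV consensus merging.

Calls from several callers are matched by breakpoint proximity (same type,
same chromosome pair, both ends within a tolerance), the match graph is
reduced to connected components (single-linkage), and a component is
retained as a consensus simple SV when it is supported by at least
``min_support`` distinct callers and its representative length is at least
``min_size`` (translocations carry no meaningful length and are exempt from
the size filter).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SVRecord, write_sv_vcf

DEFAULT_TOL = 500          # bp per breakpoint; typical long-read caller jitter
DEFAULT_MIN_SIZE = 50      # bp; variants shorter than this are excluded
DEFAULT_MIN_SUPPORT = 2    # distinct callers


@dataclass(frozen=True)
class ConsensusSV:
    """A merged multi-caller SV: representative call plus its members."""

    representative: SVRecord
    support: int
    members: tuple[SVRecord, ...]

    def __post_init__(self):
        assert self.support == len({m.caller for m in self.members})
        assert len({m.svtype for m in self.members}) == 1


def _lower_median(values: Sequence[int]) -> int:
    """Median with the lower value taken on even counts."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def match_sv_pair(a: SVRecord, b: SVRecord, tol: int = DEFAULT_TOL) -> bool:
    """True iff two calls describe the same event within breakpoint tolerance.

    Requires equal svtype and chromosome pair, both breakpoints within
    ``tol`` bp, and for insertions a length ratio of at least 0.5 (insertion
    breakpoints are a single locus, so length is the discriminating field).
    Symmetric in its arguments.
    """
    if a.svtype != b.svtype:
        return False
    if (a.chrom1, a.chrom2) != (b.chrom1, b.chrom2):
        return False
    if abs(a.pos1 - b.pos1) > tol or abs(a.pos2 - b.pos2) > tol:
        return False
    if a.svtype == "INS":
        lo, hi = sorted((a.svlen, b.svlen))
        if hi > 0 and lo / hi < 0.5:
            return False
    return True


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_callsets(
    callsets: Mapping[str, Sequence[SVRecord]] | Sequence[Sequence[SVRecord]],
    tol: int = DEFAULT_TOL,
    min_size: int = DEFAULT_MIN_SIZE,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[ConsensusSV]:
    """Merge per-caller call sets into consensus SVs.

    The match graph uses :func:`match_sv_pair` edges; connected components
    become candidate events.  Support counts distinct callers per component.
    Retention requires ``support >= min_support`` and representative
    ``svlen >= min_size`` (TRA exempt).  Representative breakpoints and
    length are per-field lower medians over members.  Output is sorted by
    (chrom1, pos1, chrom2, pos2); the result is invariant to caller input
    order.
    """
    if isinstance(callsets, Mapping):
        all_records = [r for recs in callsets.values() for r in recs]
    else:
        all_records = [r for recs in callsets for r in recs]

    # canonical record order makes components independent of input order
    all_records = sorted(
        all_records,
        key=lambda r: (r.chrom1, r.pos1, r.chrom2, r.pos2, r.svtype, r.svlen, r.caller),
    )
    # bucket by (svtype, chrom pair): only these can ever match
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, r in enumerate(all_records):
        buckets[(r.svtype, r.chrom1, r.chrom2)].append(i)

    uf = _UnionFind(len(all_records))
    for idxs in buckets.values():
        # records sorted by pos1; a sliding window bounds the pair scan
        for ai in range(len(idxs)):
            a = all_records[idxs[ai]]
            for bi in range(ai + 1, len(idxs)):
                b = all_records[idxs[bi]]
                if b.pos1 - a.pos1 > tol:
                    break
                if match_sv_pair(a, b, tol):
                    uf.union(idxs[ai], idxs[bi])

    components: dict[int, list[SVRecord]] = defaultdict(list)
    for i, r in enumerate(all_records):
        components[uf.find(i)].append(r)

    out: list[ConsensusSV] = []
    for members in components.values():
        support = len({m.caller for m in members})
        if support < min_support:
            continue
        rep = SVRecord(
            chrom1=members[0].chrom1,
            pos1=_lower_median([m.pos1 for m in members]),
            chrom2=members[0].chrom2,
            pos2=_lower_median([m.pos2 for m in members]),
            svtype=members[0].svtype,
            svlen=_lower_median([m.svlen for m in members]),
            caller="consensus",
            sample=members[0].sample,
        )
        if rep.svtype != "TRA" and rep.svlen < min_size:
            continue
        out.append(ConsensusSV(rep, support, tuple(members)))
    out.sort(key=lambda c: (c.representative.chrom1, c.representative.pos1,
                            c.representative.chrom2, c.representative.pos2))
    return out


def consensus_summary(consensus: Iterable[ConsensusSV], sample: str = "") -> pd.DataFrame:
    """Per-svtype retained counts, one row per type (Deletion/Duplication/...)."""
    label = {"DEL": "Deletion", "DUP": "Duplication", "TRA": "Translocation",
             "INS": "Insertion", "INV": "Inversion"}
    counts = {name: 0 for name in label.values()}
    for c in consensus:
        counts[label[c.representative.svtype]] += 1
    rows = [{"sample": sample, "svtype": k, "count": v} for k, v in counts.items()]
    return pd.DataFrame(rows)


def write_consensus_vcf(
    consensus: Sequence[ConsensusSV],
    path: str | Path,
    contigs: Sequence[tuple[str, int]],
) -> None:
    """Write consensus calls with SUPP / SUPP_CALLERS / MEMBERS annotations."""
    reps = [c.representative for c in consensus]
    extra = {}
    for i, c in enumerate(consensus):
        callers = ",".join(sorted({m.caller for m in c.members}))
        members = ",".join(
            f"{m.caller}:{m.chrom1}:{m.pos1 + 1}:{m.chrom2}:{m.pos2 + 1}" for m in c.members
        )
        extra[i] = f"SUPP={c.support};SUPP_CALLERS={callers};MEMBERS={members}"
    write_sv_vcf(reps, path, contigs, extra_info=extra)
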
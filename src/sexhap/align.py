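"""Pairwise alignment kernel shared by read filtering, classification and consensus.

Wraps edlib (Myers bit-vector edit distance with traceback). Two modes are
exposed: *infix* (the whole query must align inside the target, used to place
a read on a haplotype or a diagnostic window inside a read) and *global*
(end-to-end, used for variant-vs-original gene comparisons). Gap costs are
unit costs; a long structural deletion still surfaces as one contiguous gap
run in the path, which is all the downstream indel measurement needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: cigar ops that consume the query sequence
QUERY_OPS = {"=", "X", "I", "M"}
#: cigar ops that consume the target sequence
TARGET_OPS = {"=", "X", "D", "M"}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Extended cigar string -> list of (length, op)."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass
class Alignment:
    """One pairwise alignment, cigar ops are query-relative.

    ``I`` consumes query only (extra bases in the query), ``D`` consumes
    target only (target bases missing from the query). ``target_start`` /
    ``target_end`` are 0-based half-open on the target.
    """

    query_len: int
    target_start: int
    target_end: int
    edit_distance: int
    cigar: list[tuple[int, str]] = field(repr=False)
    strand: str = "+"

    @property
    def columns(self) -> int:
        return sum(n for n, _ in self.cigar)

    @property
    def identity(self) -> float:
        cols = self.columns
        return 1.0 - self.edit_distance / cols if cols else 0.0

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    def walk(self):
        """Yield (op, length, query_offset, target_offset) per cigar run.

        Offsets are 0-based positions at the start of the run; the query
        offset is relative to the query, the target offset relative to
        ``target_start``.
        """
        q = t = 0
        for n, op in self.cigar:
            yield op, n, q, t
            if op in QUERY_OPS:
                q += n
            if op in TARGET_OPS:
                t += n


def align_infix(
    query: str,
    target: str,
    max_distance: int = -1,
    min_identity: float = 0.0,
    try_revcomp: bool = False,
) -> Alignment | None:
    """Best placement of the full query inside the target, or None.

    Returns None when edlib finds no alignment within ``max_distance`` or the
    resulting identity falls below ``min_identity``. With ``try_revcomp`` the
    reverse complement of the query is also tried and the better hit kept.
    """
    if not query or not target:
        return None
    best: Alignment | None = None
    candidates = [("+", query)]
    if try_revcomp:
        candidates.append(("-", revcomp(query)))
    for strand, q in candidates:
        res = edlib.align(q, target, mode="HW", task="path", k=max_distance)
        if res["editDistance"] < 0:
            continue
        start, end = res["locations"][0]
        aln = Alignment(
            query_len=len(q),
            target_start=start,
            target_end=end + 1,
            edit_distance=res["editDistance"],
            cigar=parse_cigar(res["cigar"]),
            strand=strand,
        )
        if best is None or aln.edit_distance < best.edit_distance:
            best = aln
    if best is None or best.identity < min_identity:
        return None
    return best


def align_global(query: str, target: str) -> Alignment:
    """End-to-end alignment of two sequences."""
    res = edlib.align(query, target, mode="NW", task="path")
    return Alignment(
        query_len=len(query),
        target_start=0,
        target_end=len(target),
        edit_distance=res["editDistance"],
        cigar=parse_cigar(res["cigar"]),
    )


def gap_runs_in_query(aln: Alignment, merge_matched: int = 0) -> list[tuple[int, int]]:
    """Runs of query bases absent from the target ('I' runs).

    Returns 0-based half-open intervals in query coordinates. Runs separated
    by at most ``merge_matched`` query-consuming non-gap columns are merged,
    which re-joins a long deletion that a noisy read split into pieces.
    """
    runs = [(q, q + n) for op, n, q, _ in aln.walk() if op == "I"]
    return _merge_runs(runs, merge_matched)


def gap_runs_in_target(aln: Alignment, merge_matched: int = 0) -> list[tuple[int, int]]:
    """Runs of target bases absent from the query ('D' runs), target coords
    relative to ``target_start``, 0-based half-open."""
    runs = [(t, t + n) for op, n, _, t in aln.walk() if op == "D"]
    return _merge_runs(runs, merge_matched)


def insertion_points_in_target(aln: Alignment) -> list[tuple[int, int]]:
    """(target_offset, length) of each query-only run, i.e. where extra query
    sequence sits between two target positions."""
    return [(t, n) for op, n, _, t in aln.walk() if op == "I"]


def net_indel_in_target(aln: Alignment, t_lo: int, t_hi: int) -> int:
    """Net inserted-minus-deleted length within a target interval.

    ``t_lo``/``t_hi`` are 0-based half-open coordinates relative to
    ``target_start``. Insertions ('I') are attributed to the target position
    they precede; deletions ('D') to the target bases they span. The *net*
    imbalance is invariant to how an optimal path distributes tied edits, so
    it is the right readout for structural indel sizes; positive means the
    query carries extra sequence there, negative that it lacks sequence.
    """
    net = 0
    for op, n, _, t in aln.walk():
        if op == "I" and t_lo <= t < t_hi:
            net += n
        elif op == "D":
            net -= max(0, min(t + n, t_hi) - max(t, t_lo))
    return net


def _merge_runs(runs: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= merge_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def overlap_length(runs: list[tuple[int, int]], start: int, end: int) -> int:
    """Total length of run pieces overlapping [start, end) (same coords)."""
    total = 0
    for s, e in runs:
        total += max(0, min(e, end) - max(s, start))
    return total
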
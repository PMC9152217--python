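"""Backbone-anchored consensus over a read subset, with IUPAC ambiguity.

Rather than a de-novo multiple alignment, every read is aligned individually
to a fixed backbone (the expected Y), and a consensus is called column by
column over the backbone positions the reads cover — a star alignment, which
is well-posed here because a backbone exists by construction. Columns below
``min_depth`` become N; columns where the majority base falls short of the
agreement threshold get the IUPAC code of every base with at least 25%
support; columns where most reads show a gap are removed. Insertions
relative to the backbone are emitted only when at least half of the covering
reads agree one is there.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import align_infix, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}
GAP = 4

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


@dataclass
class ColumnMatrix:
    """Per-backbone-position base/gap tallies plus insertion side lists."""

    backbone_len: int
    counts: np.ndarray = field(repr=False)        # (L, 5): A,C,G,T,gap
    insertions: dict[int, list[str]] = field(default_factory=dict, repr=False)
    n_aligned: int = 0
    n_unaligned: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def stack_alignments(
    reads: list[tuple[str, str]],
    backbone: str,
    max_divergence: float = 0.35,
) -> ColumnMatrix:
    """Align each read to the backbone and pile its bases into columns.

    Insertions relative to the backbone are recorded in a side list keyed by
    the backbone position they follow. Reads that fail to align are skipped
    with a warning tally.
    """
    L = len(backbone)
    mat = ColumnMatrix(backbone_len=L, counts=np.zeros((L, 5), dtype=np.int64))
    for rid, seq in reads:
        s = seq.upper()
        k = max(50, int(max_divergence * len(s)))
        aln = align_infix(s, backbone, max_distance=k)
        if aln is None:
            aln = align_infix(revcomp(s), backbone, max_distance=k)
            if aln is None:
                mat.n_unaligned += 1
                logger.warning("read %s does not align to the backbone", rid)
                continue
            s = revcomp(s)
        mat.n_aligned += 1
        for op, n, q, t in aln.walk():
            col = aln.target_start + t
            if op in "=XM":
                for j in range(n):
                    base = s[q + j]
                    mat.counts[col + j, _B2I.get(base, 0)] += 1
            elif op == "D":
                mat.counts[col : col + n, GAP] += 1
            elif op == "I":
                # keyed by the backbone column the insertion follows, matching
                # the emission order in call_consensus; an insertion before
                # the first aligned column (col 0) has no anchor and is dropped
                if col > 0:
                    mat.insertions.setdefault(col - 1, []).append(s[q : q + n])
    return mat


@dataclass
class ConsensusResult:
    sequence: str
    column_calls: list[str] = field(default_factory=list, repr=False)  # per backbone column: base/code/N/'-'
    depth: np.ndarray = field(default=None, repr=False)       # per backbone column in span
    agreement: np.ndarray = field(default=None, repr=False)   # per backbone column in span
    n_ambiguous: int = 0
    span: tuple[int, int] | None = None          # covered backbone span, 1-based incl


def call_consensus(
    columns: ColumnMatrix,
    min_depth: int = 2,
    agreement_threshold: float = 0.6,
    minor_support: float = 0.25,
    insertion_presence: float = 0.5,
) -> ConsensusResult:
    """Column-wise consensus over the covered backbone span.

    ``column_calls`` holds one symbol per backbone column of the span
    ('-' for a deleted, gap-majority column); ``sequence`` is the calls with
    deletions removed and agreed insertions spliced in.
    """
    depth_all = columns.depth
    covered = np.nonzero(depth_all)[0]
    if covered.size == 0:
        logger.warning("no column has coverage; empty consensus")
        return ConsensusResult(sequence="", depth=np.array([], dtype=int),
                               agreement=np.array([]), n_ambiguous=0)
    lo, hi = int(covered[0]), int(covered[-1])

    calls: list[str] = []
    out: list[str] = []
    depths: list[int] = []
    agreements: list[float] = []
    n_amb = 0

    def emit_insertion(col: int, depth_here: int):
        ins = columns.insertions.get(col, [])
        if not ins or depth_here == 0:
            return
        if len(ins) >= insertion_presence * depth_here:
            seq, _ = Counter(ins).most_common(1)[0]
            out.extend(seq)

    for col in range(lo, hi + 1):
        row = columns.counts[col]
        depth = int(row.sum())
        base_depth = depth - int(row[GAP])
        depths.append(depth)
        if depth < min_depth:
            call = "N"
            agreements.append(0.0)
            n_amb += 1
        elif row[GAP] > depth / 2:
            call = "-"  # gap-majority column: deleted from the consensus
            agreements.append(float(row[GAP] / depth))
        else:
            freqs = row[:4] / base_depth
            top = int(np.argmax(row[:4]))
            agreement = float(freqs[top])
            agreements.append(agreement)
            if agreement >= agreement_threshold:
                call = _BASES[top]
            else:
                alts = frozenset(
                    _BASES[i] for i in range(4) if freqs[i] >= minor_support
                ) or frozenset(_BASES[top])
                call = IUPAC[alts]
                if call not in _BASES:
                    n_amb += 1
        calls.append(call)
        if call != "-":
            out.append(call)
        emit_insertion(col, depth)

    return ConsensusResult(
        sequence="".join(out),
        column_calls=calls,
        depth=np.array(depths, dtype=int),
        agreement=np.array(agreements),
        n_ambiguous=n_amb,
        span=(lo + 1, hi + 1),
    )
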
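"""Long-read bait filtering, trimming, alignment and Y/non-Y classification.

The workflow mirrors a targeted capture done in software: reads are kept
when they share sequence with any of the focal genes (bait filter), trimmed
at both ends to drop low-quality tails, and then interrogated at the
diagnostic locus — the deletion in the truncated oaz1 copy that only the Y
carries. A read that spans the locus with anchored flanks and shows a gap of
the expected length is Y-specific; one that spans it without the gap is
non-Y; anything else is unassigned.

Diagnostic detection anchors the two X-side flanks bordering the deletion
independently into each read and compares their separation on the X with
their separation on the read: a Y read collapses the 275 bp to (near) zero,
an X read keeps it. The separation difference is the observed deletion
length; being anchor-based it is immune to how an edit-distance aligner
chooses to thread a long gap.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .align import Alignment, align_infix, revcomp
from .sim import GeneModel, YVariantSpec
from .yhap import HaplotypeModel

logger = logging.getLogger(__name__)

LABEL_Y = "Y-specific"
LABEL_NON_Y = "non-Y"
LABEL_UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# bait filter
# ---------------------------------------------------------------------------

@dataclass
class BaitSet:
    """Gene-derived bait segments and the k-mer index built over them."""

    segments: list[tuple[str, str]]          # (gene name, sequence)
    min_hit_score: int = 3
    k: int = 15
    _index: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for gene, seq in self.segments:
            kmers = self._index.setdefault(gene, set())
            s = seq.upper()
            for strand_seq in (s, revcomp(s)):
                for i in range(len(strand_seq) - self.k + 1):
                    kmers.add(strand_seq[i : i + self.k])

    def hit_scores(self, read: str) -> Counter:
        """Shared-k-mer count per gene for one read."""
        r = read.upper()
        read_kmers = {r[i : i + self.k] for i in range(len(r) - self.k + 1)}
        return Counter(
            {gene: len(read_kmers & kmers) for gene, kmers in self._index.items()}
        )

    def best_hit(self, read: str, margin: int = 0) -> str | None:
        """Best-scoring gene at/above min_hit_score, or None.

        With ``margin`` > 0 the best gene must beat the runner-up by that many
        shared k-mers — a guard against paralog-only matches.
        """
        scores = self.hit_scores(read)
        ranked = scores.most_common(2)
        if not ranked or ranked[0][1] < self.min_hit_score:
            return None
        if margin and len(ranked) > 1 and ranked[0][1] - ranked[1][1] < margin:
            return None
        return ranked[0][0]


def prepare_baits(
    genes: list[GeneModel],
    reference: str,
    min_hit_score: int = 3,
    k: int = 15,
) -> BaitSet:
    """One bait segment per maximal unmasked run of each gene's span.

    A gene with one internal masked intron yields exactly two segments; a
    fully masked gene contributes nothing (logged).
    """
    segments: list[tuple[str, str]] = []
    for gene in genes:
        gs, ge = gene.span
        masked = sorted(gene.masked_intervals)
        cursor = gs
        runs: list[tuple[int, int]] = []
        for ms, me in masked:
            if ms > cursor:
                runs.append((cursor, ms - 1))
            cursor = max(cursor, me + 1)
        if cursor <= ge:
            runs.append((cursor, ge))
        runs = [(s, e) for s, e in runs if e - s + 1 >= k]
        if not runs:
            logger.warning("gene %s fully masked; no bait segments", gene.name)
            continue
        for s, e in runs:
            segments.append((gene.name, reference[s - 1 : e]))
    return BaitSet(segments=segments, min_hit_score=min_hit_score, k=k)


def bait_filter(
    reads: list[tuple[str, str]],
    baits: BaitSet,
    margin: int = 0,
) -> list[tuple[str, str, str]]:
    """Retain reads with a bait hit; returns (read_id, sequence, gene)."""
    if not baits.segments:
        raise ValueError("bait set is empty")
    out = []
    for rid, seq in reads:
        gene = baits.best_hit(seq, margin=margin)
        if gene is not None:
            out.append((rid, seq, gene))
    return out


# ---------------------------------------------------------------------------
# trimming and alignment
# ---------------------------------------------------------------------------

def trim_ends(seq: str, n: int = 23) -> str | None:
    """Remove n bases from each end; None when nothing is left."""
    if n == 0:
        return seq
    if len(seq) <= 2 * n:
        return None
    return seq[n:-n]


def align_to_target(
    read: str,
    target: str,
    min_identity: float = 0.75,
    max_divergence: float = 0.35,
) -> Alignment | None:
    """Place a (possibly noisy) read on a haplotype; None when unaligned."""
    if not read:
        return None
    k = max(50, int(max_divergence * len(read)))
    return align_infix(read, target, max_distance=k, min_identity=min_identity,
                       try_revcomp=True)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class Diagnostic:
    spans_locus: bool
    deletion_detected: bool
    observed_length: int | None


@dataclass
class ReadCall:
    read_id: str
    bait_hit: str | None
    trimmed: bool
    alignment: Alignment | None
    diagnostic: Diagnostic
    label: str


def classify_read(
    read_id: str,
    read_seq: str,
    x_sequence: str,
    diagnostic_x_interval: tuple[int, int],
    expected_length: int,
    flank: int = 200,
    tol: int = 30,
    min_flank_identity: float = 0.7,
    bait_hit: str | None = None,
    alignment: Alignment | None = None,
) -> ReadCall:
    """Label one read by evidence at the diagnostic deletion.

    The two X flanks immediately bordering the diagnostic interval are
    anchored independently into the read; the read spans the locus when both
    flanks place with at least ``min_flank_identity`` in consistent order and
    orientation. The observed deletion is then the X separation of the
    anchors (the diagnostic interval itself) minus their separation on the
    read -- a path-independent readout that a noisy alignment cannot smear.
    """
    ds, de = diagnostic_x_interval
    if ds - flank < 1 or de + flank > len(x_sequence):
        raise ValueError("diagnostic interval too close to the X boundary for flank")
    left_q = x_sequence[ds - 1 - flank : ds - 1]
    right_q = x_sequence[de : de + flank]
    budget = int((1 - min_flank_identity) * flank)

    left = align_infix(left_q, read_seq, max_distance=budget,
                       min_identity=min_flank_identity, try_revcomp=True)
    right = align_infix(right_q, read_seq, max_distance=budget,
                        min_identity=min_flank_identity, try_revcomp=True)

    observed = None
    detected = False
    spans = False
    if left is not None and right is not None and left.strand == right.strand:
        if left.strand == "+":
            read_gap = right.target_start - left.target_end
        else:
            read_gap = left.target_start - right.target_end
        x_gap = de - ds + 1  # the flanks border the interval exactly
        # ordered, nearby placements only; a wildly separated pair means the
        # flanks hit unrelated parts of the read
        if -tol <= read_gap <= x_gap + tol:
            spans = True
            net = x_gap - read_gap
            if net > 0:
                observed = net
            detected = net > 0 and abs(net - expected_length) <= tol
    label = (
        LABEL_Y if detected
        else LABEL_NON_Y if spans
        else LABEL_UNASSIGNED
    )
    return ReadCall(
        read_id=read_id,
        bait_hit=bait_hit,
        trimmed=True,
        alignment=alignment,
        diagnostic=Diagnostic(spans_locus=spans, deletion_detected=detected,
                              observed_length=observed),
        label=label,
    )


@dataclass
class ClassificationResult:
    calls: list[ReadCall]
    n_input: int = 0
    n_bait_pass: int = 0
    n_trim_dropped: int = 0

    def label_counts(self) -> Counter:
        return Counter(c.label for c in self.calls)

    def subset(self, label: str) -> list[str]:
        return [c.read_id for c in self.calls if c.label == label]


def classify_reads(
    reads: list[tuple[str, str]],
    model: HaplotypeModel,
    baits: BaitSet,
    trim_n: int = 23,
    flank: int = 200,
    tol: int = 30,
    margin: int = 0,
    align_expected_y: bool = False,
) -> ClassificationResult:
    """The full per-read workflow: bait filter (on raw reads), end trim, and
    diagnostic classification against the X haplotype. Each read is handled
    independently of the rest of the batch."""
    spec: YVariantSpec = model.spec
    diag_x = spec.diagnostic_x_interval()
    expected = spec.diagnostic_expected_length

    retained = bait_filter(reads, baits, margin=margin)
    calls: list[ReadCall] = []
    n_dropped = 0
    for rid, seq, gene in retained:
        trimmed = trim_ends(seq, trim_n)
        if trimmed is None:
            n_dropped += 1
            continue
        aln = (
            align_to_target(trimmed, model.y_sequence) if align_expected_y else None
        )
        calls.append(
            classify_read(
                rid, trimmed, model.x_sequence, diag_x, expected,
                flank=flank, tol=tol, bait_hit=gene, alignment=aln,
            )
        )
    if n_dropped:
        logger.info("%d reads shorter than 2x trim length dropped", n_dropped)
    return ClassificationResult(
        calls=calls,
        n_input=len(reads),
        n_bait_pass=len(retained),
        n_trim_dropped=n_dropped,
    )
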
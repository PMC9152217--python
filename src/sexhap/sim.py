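"""Synthetic data generation with full ground truth.

Everything the downstream stages consume can be produced here: a reference
X haplotype with gene annotations, a true Y haplotype built from a
structural-variant description (tandem duplication + indels + SNVs), pooled
male/female allele counts under an XY or no-GSD scenario, and error-modeled
long reads. Ground truth (which sites are sex-linked, which reads came from
which haplotype) is kept separately from the emitted records so nothing in a
read id or a sync line leaks the answer.

All randomness flows through explicit integer seeds; identical configuration
plus seed reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene on the reference: name, exons and optional masked intervals.

    Coordinates are 1-based inclusive on the reference. ``masked_intervals``
    mark sub-sequences excluded from bait construction (e.g. an intron that
    resembles an unrelated gene and would poison similarity search).
    """

    name: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.name}: at least one exon required")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be + or -")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.name}: overlapping exons")
        for s, e in ex:
            if s < 1 or e < s:
                raise ValueError(f"gene {self.name}: bad exon ({s},{e})")
        self.exons = ex
        lo, hi = self.span
        for s, e in self.masked_intervals:
            if s < lo or e > hi or e < s:
                raise ValueError(
                    f"gene {self.name}: masked interval ({s},{e}) outside gene span"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Deletion:
    """A deletion on the duplicated copy, 1-based inclusive copy coordinates.

    ``override`` resolves deletions whose size falls between the keep-below
    and apply-at-or-above thresholds of the expected-Y builder: "apply" or
    "keep"; None leaves the size rule in charge.
    """

    start: int
    end: int
    override: str | None = None

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad deletion interval ({self.start},{self.end})")
        if self.override not in (None, "apply", "keep"):
            raise ValueError(f"deletion override must be apply/keep, got {self.override}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class YVariantSpec:
    """Structural description of the Y relative to the X reference.

    ``dup_source`` is the X interval copied in tandem; the copy is inserted
    immediately before X position ``dup_insert_at``. All small edits
    (``deletions``, ``insertions`` after a copy position, ``snvs``) live in
    1-based coordinates *on the duplicated copy*. ``diagnostic_deletion`` is
    the deletion whose presence in a read marks it as Y-derived; it is always
    applied, whatever its size.
    """

    dup_source: tuple[int, int]
    dup_insert_at: int
    deletions: list[Deletion] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    snvs: list[tuple[int, str]] = field(default_factory=list)
    diagnostic_deletion: Deletion | None = None
    diagnostic_expected_length: int = 275

    def __post_init__(self):
        s, e = self.dup_source
        if s < 1 or e < s:
            raise ValueError(f"bad dup_source ({s},{e})")
        dup_len = e - s + 1
        all_dels = list(self.deletions)
        if self.diagnostic_deletion is not None:
            d = self.diagnostic_deletion
            if d.start < 1 or d.end > dup_len:
                raise ValueError("diagnostic deletion outside the duplicated copy")
            if d.length != self.diagnostic_expected_length:
                raise ValueError(
                    f"diagnostic deletion length {d.length} != expected "
                    f"{self.diagnostic_expected_length}"
                )
            all_dels.append(d)
        spans = sorted((d.start, d.end) for d in all_dels)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("deletion intervals overlap")
        for d in self.deletions:
            if d.end > dup_len:
                raise ValueError(f"deletion ({d.start},{d.end}) outside the copy")
        for pos, seq in self.insertions:
            if not 0 <= pos <= dup_len:
                raise ValueError(f"insertion position {pos} outside the copy")
            if not seq or any(b not in _BASE_IDX for b in seq.upper()):
                raise ValueError(f"bad insertion sequence at {pos}")
        for pos, alt in self.snvs:
            if not 1 <= pos <= dup_len:
                raise ValueError(f"SNV position {pos} outside the copy")
            if alt.upper() not in _BASE_IDX:
                raise ValueError(f"bad SNV base {alt!r}")

    @property
    def dup_length(self) -> int:
        return self.dup_source[1] - self.dup_source[0] + 1

    def diagnostic_x_interval(self) -> tuple[int, int]:
        """The diagnostic deletion mapped back to X coordinates (1-based incl)."""
        if self.diagnostic_deletion is None:
            raise ValueError("spec has no diagnostic deletion")
        off = self.dup_source[0] - 1
        return self.diagnostic_deletion.start + off, self.diagnostic_deletion.end + off

    def validate_against(self, reference: str) -> None:
        if self.dup_source[1] > len(reference):
            raise ValueError("dup_source extends past the reference")
        if not 1 <= self.dup_insert_at <= len(reference) + 1:
            raise ValueError("dup_insert_at outside the reference")


@dataclass
class PoolSimConfig:
    """Pooled short-read sampling model for one male and one female pool."""

    n_per_sex: int = 10
    depth_mean: float = 170.0
    seq_error: float = 0.002
    snp_density: float = 2.0       # polymorphic sites per kb
    sex_system: str = "XY"         # "XY" or "none"
    subsample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("seq_error", "subsample_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.sex_system not in ("XY", "none"):
            raise ValueError("sex_system must be 'XY' or 'none'")
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be >= 1")


@dataclass
class LongReadErrorModel:
    """Nanopore-like read error model: one total error rate split across
    substitutions, insertions and deletions; lognormal read lengths."""

    error_rate: float = 0.0644
    mix: tuple[float, float, float] = (0.4, 0.3, 0.3)   # sub, ins, del
    length_mean: float = 10_000.0    # median of the lognormal, bp
    length_sigma: float = 0.35       # sigma of log length
    min_length: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0,1)")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mix must sum to 1")


@dataclass
class SimTruth:
    """Generator ground truth, used only by tests and reports."""

    sex_linked_sites: set[int] = field(default_factory=set)
    read_origins: dict[str, str] = field(default_factory=dict)
    read_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    y_sequence: str | None = None


# ---------------------------------------------------------------------------
# reference + true Y
# ---------------------------------------------------------------------------

def generate_reference(
    length: int,
    genes: list[GeneModel] | None = None,
    gc: float = 0.42,
    seed: int = 0,
) -> tuple[str, list[GeneModel]]:
    """Random reference haplotype of ``length`` bp at the given GC content.

    Gene models are positional annotations only (the sequence under them is
    random like everything else); they must fit inside the sequence and not
    overlap each other.
    """
    genes = list(genes or [])
    spans = sorted(g.span for g in genes)
    total_span = 0
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("overlapping genes are not supported")
    for s, e in spans:
        if e > length:
            raise ValueError(f"gene span ({s},{e}) extends past length {length}")
        total_span += e - s + 1
    if total_span > length:
        raise ValueError("gene spans exceed the sequence length")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(BASES)[rng.choice(4, size=length, p=p)])
    return seq, genes


# coordinate-map tags
TAG_ORIGINAL = 0
TAG_DUPLICATE = 1
TAG_GAP = 2
TAG_NAMES = {TAG_ORIGINAL: "original", TAG_DUPLICATE: "duplicate", TAG_GAP: "gap"}


def apply_variant_spec(reference, spec, apply_deletion):
    """Build a Y haplotype from the X plus a variant spec.

    ``apply_deletion(d)`` decides per deletion whether its sequence is removed
    (the diagnostic deletion is the caller's responsibility to include). Used
    by both the truth builder (everything applied) and the expected-Y builder
    (size-class rules).

    Returns (y_sequence, x_origin, tag, copy_to_y, x_to_y, applied_deletions)
    where x_origin is a 1-based X position per Y base (0 for novel insertions),
    tag the provenance tag per Y base, copy_to_y / x_to_y map 1-based copy /
    X positions to 1-based Y positions (0 when deleted/absent).
    """
    spec.validate_against(reference)
    s, e = spec.dup_source
    dup_len = spec.dup_length
    copy = list(reference[s - 1 : e])

    snv_at = {}
    for pos, alt in spec.snvs:
        alt = alt.upper()
        if copy[pos - 1].upper() == alt:
            raise ValueError(f"SNV at copy position {pos} equals the reference base")
        snv_at[pos] = alt
    ins_at: dict[int, str] = {}
    for pos, seq_ in spec.insertions:
        if pos in ins_at:
            raise ValueError(f"two insertions at copy position {pos}")
        ins_at[pos] = seq_.upper()

    deleted = np.zeros(dup_len + 1, dtype=bool)
    applied: list[Deletion] = []
    for d in list(spec.deletions) + (
        [spec.diagnostic_deletion] if spec.diagnostic_deletion else []
    ):
        if apply_deletion(d):
            deleted[d.start : d.end + 1] = True
            applied.append(d)

    y_chars: list[str] = []
    x_origin: list[int] = []
    tag: list[int] = []
    copy_to_y = np.zeros(dup_len + 1, dtype=np.int64)
    x_to_y = np.zeros(len(reference) + 1, dtype=np.int64)

    def emit(char, origin, t):
        y_chars.append(char)
        x_origin.append(origin)
        tag.append(t)
        return len(y_chars)  # 1-based Y position just written

    def emit_copy():
        if 0 in ins_at:
            for b in ins_at[0]:
                emit(b, 0, TAG_GAP)
        for cp in range(1, dup_len + 1):
            if not deleted[cp]:
                base = snv_at.get(cp, copy[cp - 1])
                copy_to_y[cp] = emit(base, s + cp - 1, TAG_DUPLICATE)
            if cp in ins_at:
                for b in ins_at[cp]:
                    emit(b, 0, TAG_GAP)

    for xp in range(1, len(reference) + 1):
        if xp == spec.dup_insert_at:
            emit_copy()
        x_to_y[xp] = emit(reference[xp - 1], xp, TAG_ORIGINAL)
    if spec.dup_insert_at == len(reference) + 1:
        emit_copy()

    return (
        "".join(y_chars),
        np.array(x_origin, dtype=np.int64),
        np.array(tag, dtype=np.uint8),
        copy_to_y,
        x_to_y,
        applied,
    )


def make_true_y(reference: str, spec: YVariantSpec):
    """The *actual* Y sequence: every edit in the spec applied.

    Returns (y_sequence, coord_map) where coord_map is a dict with the arrays
    described in :func:`apply_variant_spec`.
    """
    y, x_origin, tag, copy_to_y, x_to_y, applied = apply_variant_spec(
        reference, spec, lambda d: True
    )
    coord_map = {
        "x_origin": x_origin,
        "tag": tag,
        "copy_to_y": copy_to_y,
        "x_to_y": x_to_y,
        "applied_deletions": applied,
    }
    return y, coord_map


# ---------------------------------------------------------------------------
# pooled counts
# ---------------------------------------------------------------------------

def _other_base(rng, base_idx):
    return (base_idx + rng.integers(1, 4)) % 4


def _sample_pool_reads(rng, allele_idx, allele_freq, depth_mean, seq_error, frac):
    """One pool at one site -> counts over A/C/G/T."""
    depth = rng.poisson(depth_mean)
    if frac < 1.0:
        depth = rng.binomial(depth, frac)
    counts = np.zeros(4, dtype=np.int64)
    if depth == 0:
        return counts
    draws = rng.multinomial(depth, allele_freq)
    for idx, n in zip(allele_idx, draws):
        if n == 0:
            continue
        n_err = rng.binomial(n, seq_error) if seq_error > 0 else 0
        counts[idx] += n - n_err
        for _ in range(n_err):
            counts[_other_base(rng, idx)] += 1
    return counts


def simulate_pool_counts(
    reference: str,
    spec: YVariantSpec | None,
    cfg: PoolSimConfig,
    chrom: str = "chr1",
):
    """Pooled per-site allele counts for a female pool and a male pool.

    Polymorphic sites are placed uniformly at ``snp_density`` per kb. Under
    an XY system, sites inside ``spec.dup_source`` are sex-linked: the X
    allele (the reference base) is fixed in females while males carry one X
    and one Y (alternate) allele per individual, so the male pool sits at
    allele frequency 0.5. All other sites share a population frequency drawn
    once and sampled independently into each pool's 2n chromosomes. Read
    counts are multinomial at Poisson depth with per-base error flips;
    ``subsample_fraction`` thins each pool's reads independently.

    Returns (sites, truth): a list of
    :class:`sexhap.poolscan.PooledSiteCounts` and a :class:`SimTruth`.
    """
    from .poolscan import PooledSiteCounts

    if cfg.sex_system == "XY" and spec is None:
        raise ValueError("sex_system='XY' requires a Y variant spec")
    rng = np.random.default_rng(cfg.seed)
    n_sites = int(round(cfg.snp_density * len(reference) / 1000.0))
    n_sites = min(n_sites, len(reference))
    positions = np.sort(rng.choice(len(reference), size=n_sites, replace=False)) + 1

    region = spec.dup_source if spec is not None else None
    two_n = 2 * cfg.n_per_sex
    truth = SimTruth()
    sites: list[PooledSiteCounts] = []
    for pos in positions:
        ref = reference[pos - 1].upper()
        if ref not in _BASE_IDX:
            continue
        ref_i = _BASE_IDX[ref]
        alt_i = _other_base(rng, ref_i)
        sex_linked = (
            cfg.sex_system == "XY"
            and region is not None
            and region[0] <= pos <= region[1]
        )
        if sex_linked:
            f_freq = 1.0          # females: 2n X chromosomes, all ref
            m_freq = 0.5          # males: n X (ref) + n Y (alt)
            truth.sex_linked_sites.add(int(pos))
        else:
            p = rng.uniform(0.05, 0.95)
            f_freq = rng.binomial(two_n, p) / two_n
            m_freq = rng.binomial(two_n, p) / two_n
        fem = _sample_pool_reads(
            rng, (ref_i, alt_i), (f_freq, 1 - f_freq),
            cfg.depth_mean, cfg.seq_error, cfg.subsample_fraction,
        )
        mal = _sample_pool_reads(
            rng, (ref_i, alt_i), (m_freq, 1 - m_freq),
            cfg.depth_mean, cfg.seq_error, cfg.subsample_fraction,
        )
        sites.append(
            PooledSiteCounts(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                pool1_counts={b: int(c) for b, c in zip(BASES, fem)},
                pool2_counts={b: int(c) for b, c in zip(BASES, mal)},
            )
        )
    return sites, truth


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def _inject_errors(rng, template: str, model: LongReadErrorModel) -> str:
    """Walk the template once; at each base an error event fires with
    probability ``error_rate`` and is a substitution, an insertion before the
    base, or a deletion of the base, per ``mix``."""
    if model.error_rate == 0:
        return template
    out: list[str] = []
    sub_p, ins_p, _ = model.mix
    events = rng.random(len(template))
    kinds = rng.random(len(template))
    for i, base in enumerate(template):
        if events[i] >= model.error_rate:
            out.append(base)
            continue
        k = kinds[i]
        if k < sub_p:
            out.append(BASES[_other_base(rng, _BASE_IDX.get(base, 0))])
        elif k < sub_p + ins_p:
            out.append(BASES[rng.integers(4)])
            out.append(base)
        # else: deletion, emit nothing
    return "".join(out)


def simulate_long_reads(
    haplotype: str,
    n: int,
    model: LongReadErrorModel,
    origin: str = "X",
    id_prefix: str = "read",
    id_start: int = 0,
):
    """``n`` noisy long reads from uniform start positions on one haplotype.

    Read ids carry only a running number; the haplotype of origin and the
    template span live in the returned :class:`SimTruth`. Returns
    (records, truth) with records as (read_id, sequence) tuples.
    """
    rng = np.random.default_rng(model.seed)
    truth = SimTruth()
    records: list[tuple[str, str]] = []
    L = len(haplotype)
    if model.min_length > L:
        raise ValueError("min_length exceeds the haplotype length")
    for i in range(n):
        rl = int(model.length_mean * math.exp(rng.normal(0.0, model.length_sigma)))
        rl = max(model.min_length, min(rl, L))
        start = int(rng.integers(0, L - rl + 1))  # 0-based
        template = haplotype[start : start + rl]
        seq = _inject_errors(rng, template, model)
        rid = f"{id_prefix}_{id_start + i:05d}"
        records.append((rid, seq))
        truth.read_origins[rid] = origin
        truth.read_spans[rid] = (start + 1, start + rl)
    return records, truth


def simulate_read_set(
    x_sequence: str,
    y_sequence: str | None,
    n_reads: int,
    y_fraction: float,
    model: LongReadErrorModel,
):
    """A shuffled mixed read set from the X and (optionally) Y haplotypes.

    Mimics sequencing one individual: an XY male contributes reads from both
    haplotypes (``y_fraction`` ~ 0.5), an XX individual only from X
    (``y_fraction`` = 0). Ids are assigned after shuffling so they encode
    nothing about origin.
    """
    rng = np.random.default_rng(model.seed)
    n_y = int(round(n_reads * y_fraction)) if y_sequence else 0
    x_model = LongReadErrorModel(**{**model.__dict__, "seed": int(rng.integers(2**31))})
    reads, truth = simulate_long_reads(x_sequence, n_reads - n_y, x_model, origin="X",
                                       id_prefix="tmpx")
    if n_y:
        y_model = LongReadErrorModel(**{**model.__dict__, "seed": int(rng.integers(2**31))})
        y_reads, y_truth = simulate_long_reads(y_sequence, n_y, y_model, origin="Y",
                                               id_prefix="tmpy")
        reads += y_reads
        truth.read_origins.update(y_truth.read_origins)
        truth.read_spans.update(y_truth.read_spans)
    order = rng.permutation(len(reads))
    final_reads: list[tuple[str, str]] = []
    final_truth = SimTruth(y_sequence=y_sequence)
    for new_i, old_i in enumerate(order):
        old_id, seq = reads[old_i]
        rid = f"read_{new_i:05d}"
        final_reads.append((rid, seq))
        final_truth.read_origins[rid] = truth.read_origins[old_id]
        final_truth.read_spans[rid] = truth.read_spans[old_id]
    return final_reads, final_truth


def constant_quality(seq: str, error_rate: float) -> str:
    """A flat FASTQ quality string consistent with the error model."""
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    return chr(q + 33) * len(seq)
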
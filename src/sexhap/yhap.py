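"""Expected-Y haplotype construction, annotation liftover and coordinates.

The expected Y is a reference-guided model: the X haplotype with a tandem
duplicated segment inserted, edited according to a structural-variant spec.
Deletions reported from short-read evidence are applied by size class —
small ones (< 500 bp by default) are *kept* in the model because long reads
cross them anyway, large ones (>= 5 kb) are removed; the diagnostic deletion
that defines Y-origin reads is always applied. Deletions falling between the
two thresholds are refused unless the spec marks them with an explicit
override, since no general rule covers that range.

Every Y base carries provenance (original X copy, duplicated copy, or novel
insertion) in a coordinate map, which also supports the inverse edit script:
dropping all duplicate/insertion bases reproduces the X exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .sim import (
    TAG_DUPLICATE,
    TAG_GAP,
    TAG_NAMES,
    TAG_ORIGINAL,
    Deletion,
    GeneModel,
    YVariantSpec,
    apply_variant_spec,
)

logger = logging.getLogger(__name__)


@dataclass
class RegionSpec:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad region {self.chrom}:{self.start}-{self.end}")


@dataclass
class Feature:
    """A lifted annotation on the Y (gene copy, truncated copy or chimera)."""

    name: str
    start: int          # 1-based inclusive on Y
    end: int
    strand: str = "+"
    copy: str = "original"   # original | duplicate | chimera
    truncated: bool = False


@dataclass
class HaplotypeModel:
    x_sequence: str
    annotations: list[GeneModel]
    spec: YVariantSpec
    y_sequence: str
    x_origin: np.ndarray = field(repr=False)   # per Y base, 1-based X pos or 0
    tag: np.ndarray = field(repr=False)        # per Y base, provenance tag
    copy_to_y: np.ndarray = field(repr=False)  # copy pos -> Y pos (0 = deleted)
    x_to_y: np.ndarray = field(repr=False)     # X pos -> Y pos (original copy)
    applied_deletions: list[Deletion] = field(default_factory=list)

    @property
    def applied_deletion_total(self) -> int:
        return sum(d.length for d in self.applied_deletions)

    @property
    def insertion_total(self) -> int:
        return int((self.tag == TAG_GAP).sum())

    def duplicated_span(self) -> int:
        """Length of the duplicated X segment, recovered from the coordinate
        map: duplicate-tagged Y bases plus copy bases removed by applied
        deletions."""
        return int((self.tag == TAG_DUPLICATE).sum()) + self.applied_deletion_total

    def invert_to_x(self) -> str:
        """Apply the inverse edit script: keep only original-copy bases."""
        keep = self.tag == TAG_ORIGINAL
        return "".join(np.frombuffer(self.y_sequence.encode(), dtype="S1")[keep]
                       .tobytes().decode())


def build_expected_y(
    x_sequence: str,
    annotations: list[GeneModel],
    spec: YVariantSpec,
    small_del_keep_below: int = 500,
    large_del_apply_at_or_above: int = 5_000,
) -> HaplotypeModel:
    """Construct the expected Y model from the X plus a variant spec."""

    def apply(d: Deletion) -> bool:
        if spec.diagnostic_deletion is not None and d is spec.diagnostic_deletion:
            return True
        if d.override == "apply":
            return True
        if d.override == "keep":
            return False
        if d.length < small_del_keep_below:
            return False
        if d.length >= large_del_apply_at_or_above:
            return True
        raise ValueError(
            f"deletion ({d.start},{d.end}) of {d.length} bp falls between the "
            f"keep-below ({small_del_keep_below}) and apply-at-or-above "
            f"({large_del_apply_at_or_above}) thresholds; set an explicit "
            "override ('apply' or 'keep') on this deletion"
        )

    y, x_origin, tag, copy_to_y, x_to_y, applied = apply_variant_spec(
        x_sequence, spec, apply
    )
    return HaplotypeModel(
        x_sequence=x_sequence,
        annotations=list(annotations),
        spec=spec,
        y_sequence=y,
        x_origin=x_origin,
        tag=tag,
        copy_to_y=copy_to_y,
        x_to_y=x_to_y,
        applied_deletions=applied,
    )


def _copy_interval(gene: GeneModel, spec: YVariantSpec) -> tuple[int, int] | None:
    """Gene span intersected with dup_source, in copy coordinates."""
    s, e = spec.dup_source
    gs, ge = gene.span
    lo, hi = max(gs, s), min(ge, e)
    if lo > hi:
        return None
    return lo - s + 1, hi - s + 1


def _surviving_ends(model: HaplotypeModel, c_lo: int, c_hi: int):
    """First/last copy position in [c_lo, c_hi] still present on Y, or None."""
    present = model.copy_to_y[c_lo : c_hi + 1]
    idx = np.nonzero(present)[0]
    if idx.size == 0:
        return None
    return int(present[idx[0]]), int(present[idx[-1]])


def liftover_annotations(model: HaplotypeModel) -> list[Feature]:
    """Project X gene annotations onto the constructed Y.

    Original-copy genes lift unchanged (shifted past the insertion). Genes
    overlapping the duplicated segment appear a second time with a ``_dup``
    suffix; duplicate copies hit by an applied deletion are flagged
    truncated, and when one deletion truncates the tail of one gene copy and
    the head of the next, the two remnants are fused into a single
    ``geneA-geneB_chimera`` feature (upstream gene first).
    """
    spec = model.spec
    features: list[Feature] = []
    for gene in model.annotations:
        gs, ge = gene.span
        features.append(
            Feature(
                name=gene.name,
                start=int(model.x_to_y[gs]),
                end=int(model.x_to_y[ge]),
                strand=gene.strand,
                copy="original",
            )
        )

    # duplicate copies, ordered along the copy
    dup_genes = []
    for gene in model.annotations:
        ci = _copy_interval(gene, spec)
        if ci is not None:
            dup_genes.append((gene, ci))
    dup_genes.sort(key=lambda t: t[1][0])

    # chimera pairs: one applied deletion cutting the tail of A and head of B
    fused: dict[str, tuple] = {}
    consumed: set[str] = set()
    for d in model.applied_deletions:
        a = b = None
        for gene, (lo, hi) in dup_genes:
            if lo < d.start <= hi:
                a = (gene, lo, hi)
            if lo <= d.end < hi:
                b = (gene, lo, hi)
        if a and b and a[0].name != b[0].name:
            up, down = (a, b) if a[1] <= b[1] else (b, a)
            name = f"{up[0].name}-{down[0].name}_chimera"
            ends_up = _surviving_ends(model, up[1], up[2])
            ends_down = _surviving_ends(model, down[1], down[2])
            if ends_up and ends_down:
                fused[name] = (ends_up[0], ends_down[1], up[0].strand)
                consumed.update({up[0].name, down[0].name})

    for gene, (lo, hi) in dup_genes:
        if gene.name in consumed:
            continue
        ends = _surviving_ends(model, lo, hi)
        if ends is None:
            logger.warning("duplicate copy of %s fully removed by deletions", gene.name)
            continue
        lost = int((model.copy_to_y[lo : hi + 1] == 0).sum())
        features.append(
            Feature(
                name=f"{gene.name}_dup",
                start=ends[0],
                end=ends[1],
                strand=gene.strand,
                copy="duplicate",
                truncated=lost > 0,
            )
        )
    for name, (start, end, strand) in fused.items():
        features.append(
            Feature(name=name, start=start, end=end, strand=strand,
                    copy="chimera", truncated=True)
        )
    features.sort(key=lambda f: (f.start, f.name))
    return features


def extract_region(sequence: str, region: RegionSpec) -> str:
    """1-based inclusive slice of a sequence."""
    if region.end > len(sequence):
        raise ValueError(
            f"region {region.start}-{region.end} outside sequence of "
            f"length {len(sequence)}"
        )
    return sequence[region.start - 1 : region.end]


def y_to_x(model: HaplotypeModel, y_pos: int) -> tuple[int | None, str]:
    """Map a 1-based Y position to its X origin: (x_pos, tag) or (None, 'gap')."""
    if not 1 <= y_pos <= len(model.y_sequence):
        raise ValueError(f"Y position {y_pos} out of range")
    tag = TAG_NAMES[int(model.tag[y_pos - 1])]
    if tag == "gap":
        return None, "gap"
    return int(model.x_origin[y_pos - 1]), tag
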
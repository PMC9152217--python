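"""Default study models: the full-scale synthetic sex region and presets
mirroring the three sequenced males.

The full-scale model is a 200 kb X region carrying four genes in their
duplicated order (dot1l, oaz1, LOC100707471, amh) and a 51 kb tandem
duplication whose copy carries: two large (>5 kb) deletions, the first of
which fuses the truncated dot1l and oaz1 copies into a chimera; the 275 bp
diagnostic deletion in the truncated oaz1 copy; a 233 bp deletion in the
last exon (7) of the amh copy plus a 5 bp insertion in its exon 6 (the
truncating amhΔY-style edits); one additional small intergenic deletion; and
a few marker SNVs. The first intron of dot1l is masked for bait use (it
resembles an unrelated gene).

Three presets mimic the sequenced males: "kpandu-like" and "koka-like" carry
the duplication (koka without the exon-6 insertion, as its amhΔY is not
truncated), "hora-like" has no Y-specific structure at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sim import (
    Deletion,
    GeneModel,
    LongReadErrorModel,
    PoolSimConfig,
    YVariantSpec,
    generate_reference,
)

X_LENGTH = 200_000

#: X interval copied in tandem (51 kb, the short-read estimate of the
#: duplicated span) and the copy insertion point (immediately after it).
DUP_SOURCE = (3_001, 54_000)
DUP_INSERT_AT = 54_001

_DUP_OFF = DUP_SOURCE[0] - 1   # X position -> copy position: x - _DUP_OFF


def _cp(x_pos: int) -> int:
    """X coordinate -> coordinate on the duplicated copy."""
    return x_pos - _DUP_OFF


def default_genes() -> list[GeneModel]:
    return [
        GeneModel(
            name="dot1l",
            exons=[(2_001, 2_600), (5_001, 5_600), (8_001, 8_600), (11_001, 13_000)],
            strand="+",
            masked_intervals=[(2_601, 5_000)],   # vasa-like intron 1
        ),
        GeneModel(
            name="oaz1",
            exons=[(15_001, 15_800), (17_601, 18_200), (18_901, 19_500)],
            strand="-",
        ),
        GeneModel(
            name="LOC100707471",
            exons=[(23_001, 23_800), (26_501, 27_500)],
            strand="+",
        ),
        GeneModel(
            name="amh",
            exons=[(30_001, 30_300), (31_001, 31_300), (32_001, 32_300),
                   (33_001, 33_300), (34_001, 34_300), (35_001, 35_400),
                   (36_501, 37_400)],
            strand="+",
        ),
    ]


#: amh coordinates used by the variant edits (X coordinates)
AMH_SPAN = (30_001, 37_800)
AMH_EXON6 = (35_001, 35_400)
AMH_EXON7 = (36_501, 37_400)
AMH_EXON6_INS_AFTER = 35_200          # 5 bp insertion site (X coordinate)
AMH_EXON6_INS_SEQ = "TTAAG"
AMH_EXON7_DEL = (36_800, 37_032)      # 233 bp

DIAGNOSTIC_DEL_X = (17_001, 17_275)   # 275 bp in the truncated oaz1 copy

LARGE_DEL_1_X = (9_000, 16_500)       # fuses dot1l and oaz1 copies (7,501 bp)
LARGE_DEL_2_X = (20_500, 26_000)      # truncates the LOC copy head (5,501 bp)
SMALL_DEL_X = (40_000, 40_119)        # 120 bp, intergenic

_SNV_X_POSITIONS = (4_000, 30_500, 50_000)
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def default_yspec(
    x_sequence: str, with_exon6_insertion: bool = True
) -> YVariantSpec:
    """The full-scale Y variant spec; SNV alternates derive from the
    reference so they always differ from it."""
    insertions = (
        [(_cp(AMH_EXON6_INS_AFTER), AMH_EXON6_INS_SEQ)]
        if with_exon6_insertion else []
    )
    return YVariantSpec(
        dup_source=DUP_SOURCE,
        dup_insert_at=DUP_INSERT_AT,
        deletions=[
            Deletion(_cp(LARGE_DEL_1_X[0]), _cp(LARGE_DEL_1_X[1])),
            Deletion(_cp(LARGE_DEL_2_X[0]), _cp(LARGE_DEL_2_X[1])),
            Deletion(_cp(AMH_EXON7_DEL[0]), _cp(AMH_EXON7_DEL[1])),
            Deletion(_cp(SMALL_DEL_X[0]), _cp(SMALL_DEL_X[1])),
        ],
        insertions=insertions,
        snvs=[(_cp(x), _NEXT_BASE[x_sequence[x - 1].upper()])
              for x in _SNV_X_POSITIONS],
        diagnostic_deletion=Deletion(_cp(DIAGNOSTIC_DEL_X[0]),
                                     _cp(DIAGNOSTIC_DEL_X[1])),
        diagnostic_expected_length=275,
    )


@dataclass
class Preset:
    """One simulated individual/population scenario."""

    name: str
    has_duplication: bool
    with_exon6_insertion: bool = True
    sex_system: str = "XY"
    y_read_fraction: float = 0.5
    n_long_reads: int = 300
    pool: PoolSimConfig = field(default_factory=lambda: PoolSimConfig(
        n_per_sex=10, depth_mean=170.0, seq_error=0.002, snp_density=2.0,
        sex_system="XY", subsample_fraction=0.2,
    ))
    error_model: LongReadErrorModel = field(default_factory=LongReadErrorModel)


def get_preset(name: str) -> Preset:
    presets = {
        "kpandu-like": Preset(
            name="kpandu-like", has_duplication=True, with_exon6_insertion=True,
        ),
        "koka-like": Preset(
            name="koka-like", has_duplication=True, with_exon6_insertion=False,
        ),
        "hora-like": Preset(
            name="hora-like", has_duplication=False, sex_system="none",
            y_read_fraction=0.0,
            pool=PoolSimConfig(
                n_per_sex=10, depth_mean=170.0, seq_error=0.002, snp_density=2.0,
                sex_system="none", subsample_fraction=0.2,
            ),
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    p = presets[name]
    p.pool.sex_system = p.sex_system
    return p


def build_study_region(seed: int = 0):
    """Generate the full-scale X region with its gene annotations."""
    return generate_reference(X_LENGTH, default_genes(), gc=0.42, seed=seed)
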
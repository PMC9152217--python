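"""Pooled male/female SNP scan: frequencies, pool-Fst, the sex filter,
windowed summaries and the Manhattan table.

The scan looks for the signature of an XY system in pooled sequencing: sites
where one sex pool is fixed (or nearly fixed) for an allele that sits at
intermediate frequency in the other pool. Per-site differentiation is
summarised with the classical pi-based pool-Fst, Fst = (pi_T - pi_S)/pi_T,
with pi = 1 - sum(p_i^2) within each pool and pi_T computed from the summed
retained counts; identical pools give exactly 0, fixed different alleles
give 1. Alleles seen fewer than ``min_read_count`` times in a pool are
treated as sequencing error and dropped before anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

REASON_PASS = "pass"
REASON_DEPTH = "depth"
REASON_BOTH_FIXED = "both_fixed"
REASON_NO_PATTERN = "no_sex_pattern"
REASON_UNUSABLE = "unusable"


@dataclass
class PooledSiteCounts:
    """Per-site allele counts for the two sex pools (pool1 = females by
    convention). N/del columns may be present in the dicts but never enter a
    frequency."""

    chrom: str
    pos: int
    ref: str
    pool1_counts: dict[str, int]
    pool2_counts: dict[str, int]

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        for counts in (self.pool1_counts, self.pool2_counts):
            for b, c in counts.items():
                if c < 0:
                    raise ValueError(f"negative count for {b}")


@dataclass
class ScanConfig:
    fixed_threshold: float = 0.9
    min_polymorphic_freq: float = 0.3
    max_polymorphic_freq: float = 0.7
    min_depth: int = 10
    max_depth: int = 100
    min_read_count: int = 2
    window_size: int = 10_000

    def __post_init__(self):
        if not 0.5 < self.fixed_threshold <= 1.0:
            raise ValueError("fixed_threshold must be in (0.5, 1]")
        if not self.min_polymorphic_freq < self.max_polymorphic_freq:
            raise ValueError("polymorphic frequency bounds out of order")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth > max_depth")


def allele_frequencies(
    counts: dict[str, int], min_read_count: int = 2
) -> tuple[dict[str, float], int]:
    """Frequencies over alleles with count >= min_read_count.

    Returns ({} , 0) when no allele survives — the site is unusable for this
    pool, not an error. Only A/C/G/T are considered.
    """
    kept = {b: counts.get(b, 0) for b in BASES if counts.get(b, 0) >= min_read_count}
    depth = sum(kept.values())
    if depth == 0:
        return {}, 0
    return {b: c / depth for b, c in kept.items()}, depth


def _pi(freqs: dict[str, float]) -> float:
    return 1.0 - sum(f * f for f in freqs.values())


def site_fst(
    counts1: dict[str, int], counts2: dict[str, int], min_read_count: int = 2
) -> float | None:
    """Pool-Fst between two count vectors; None when either pool is unusable."""
    f1, d1 = allele_frequencies(counts1, min_read_count)
    f2, d2 = allele_frequencies(counts2, min_read_count)
    if not f1 or not f2:
        return None
    pooled = {
        b: counts1.get(b, 0) * (counts1.get(b, 0) >= min_read_count)
        + counts2.get(b, 0) * (counts2.get(b, 0) >= min_read_count)
        for b in BASES
    }
    total = sum(pooled.values())
    pi_t = _pi({b: c / total for b, c in pooled.items() if c})
    if pi_t == 0.0:
        return 0.0
    pi_w = 0.5 * (_pi(f1) + _pi(f2))
    return (pi_t - pi_w) / pi_t


def sex_snp_filter(
    freq1: dict[str, float],
    depth1: int,
    freq2: dict[str, float],
    depth2: int,
    cfg: ScanConfig,
) -> tuple[bool, str]:
    """Fixed-in-one-sex / intermediate-in-the-other verdict.

    Candidate iff both depths lie in [min_depth, max_depth] and one pool's
    major allele reaches ``fixed_threshold`` while *that same allele* sits in
    the polymorphic band in the other pool.
    """
    if not freq1 or not freq2:
        return False, REASON_UNUSABLE
    if not (cfg.min_depth <= depth1 <= cfg.max_depth
            and cfg.min_depth <= depth2 <= cfg.max_depth):
        return False, REASON_DEPTH

    def fixed_allele(freqs):
        allele = max(sorted(freqs), key=lambda b: freqs[b])
        return (allele, freqs[allele]) if freqs[allele] >= cfg.fixed_threshold else None

    fix1, fix2 = fixed_allele(freq1), fixed_allele(freq2)
    for fixed, other in ((fix1, freq2), (fix2, freq1)):
        if fixed is None:
            continue
        f_other = other.get(fixed[0], 0.0)
        if cfg.min_polymorphic_freq <= f_other <= cfg.max_polymorphic_freq:
            return True, REASON_PASS
    if fix1 and fix2:
        return False, REASON_BOTH_FIXED
    return False, REASON_NO_PATTERN


@dataclass
class ScanResult:
    records: pd.DataFrame
    windows: pd.DataFrame
    rejects: dict[str, int] = field(default_factory=dict)


def scan(sites, cfg: ScanConfig | None = None) -> ScanResult:
    """Run the full per-site scan over an iterable of PooledSiteCounts.

    One record per usable site (both pools usable after min-count filtering);
    unusable sites are tallied in ``rejects``. ``freq1``/``freq2`` report the
    frequency, in each pool, of pool1's major allele (ties broken
    alphabetically), so the XY expectation reads freq1≈1.0, freq2≈0.5.
    """
    cfg = cfg or ScanConfig()
    rows = []
    rejects: dict[str, int] = {}
    for site in sites:
        f1, d1 = allele_frequencies(site.pool1_counts, cfg.min_read_count)
        f2, d2 = allele_frequencies(site.pool2_counts, cfg.min_read_count)
        if not f1 or not f2:
            rejects[REASON_UNUSABLE] = rejects.get(REASON_UNUSABLE, 0) + 1
            continue
        fst = site_fst(site.pool1_counts, site.pool2_counts, cfg.min_read_count)
        candidate, reason = sex_snp_filter(f1, d1, f2, d2, cfg)
        major = max(sorted(f1), key=lambda b: f1[b])
        rows.append(
            dict(
                chrom=site.chrom, pos=site.pos, ref=site.ref, major_allele=major,
                freq1=f1[major], freq2=f2.get(major, 0.0),
                depth1=d1, depth2=d2, fst=fst, candidate=candidate, reason=reason,
            )
        )
    columns = ["chrom", "pos", "ref", "major_allele", "freq1", "freq2",
               "depth1", "depth2", "fst", "candidate", "reason"]
    records = pd.DataFrame(rows, columns=columns)
    windows = window_summary(records, cfg.window_size)
    return ScanResult(records=records, windows=windows, rejects=rejects)


def window_summary(records: pd.DataFrame, window_size: int = 10_000) -> pd.DataFrame:
    """Non-overlapping windows [k*w+1, (k+1)*w] anchored at position 1."""
    columns = ["chrom", "window_start", "window_end", "n_sites", "n_candidates",
               "mean_fst"]
    if records.empty:
        return pd.DataFrame(columns=columns)
    df = records.copy()
    df["_win"] = (df["pos"] - 1) // window_size
    out = (
        df.groupby(["chrom", "_win"], sort=True)
        .agg(n_sites=("pos", "size"), n_candidates=("candidate", "sum"),
             mean_fst=("fst", "mean"))
        .reset_index()
    )
    out["window_start"] = out["_win"] * window_size + 1
    out["window_end"] = (out["_win"] + 1) * window_size
    out["n_candidates"] = out["n_candidates"].astype(int)
    return out[columns]


def enriched_windows(
    windows: pd.DataFrame, quantile: float = 0.95, min_candidates: int = 5
) -> pd.DataFrame:
    """Windows whose candidate count exceeds the empirical null.

    A window is called enriched when its candidate count reaches both the
    genome-wide ``quantile`` of per-window candidate counts and the absolute
    floor ``min_candidates`` — the floor keeps isolated false positives from
    flagging windows in a sex-signal-free genome, while the quantile keeps
    the call relative to the genome at hand.
    """
    if windows.empty:
        return windows
    thr = max(windows["n_candidates"].quantile(quantile), min_candidates)
    return windows[windows["n_candidates"] >= thr]


def manhattan_plot(records: pd.DataFrame, path: str) -> None:
    """Single-panel Manhattan plot of per-site Fst."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    if not records.empty:
        colors = records["candidate"].map({True: "crimson", False: "steelblue"})
        ax.scatter(records["pos"], records["fst"], s=6, c=colors)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("pool Fst")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
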
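"""Scan semantics: frequencies after min-count filtering, the pi-based
pool-Fst closed forms, the fixed-vs-intermediate filter, window bookkeeping,
and equality with an independent brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexhap import sim
from sexhap.poolscan import (
    PooledSiteCounts,
    ScanConfig,
    allele_frequencies,
    enriched_windows,
    scan,
    sex_snp_filter,
    site_fst,
    window_summary,
)


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "counts,expect_freqs,expect_depth",
        [
            ({"A": 18, "G": 1, "T": 1}, {"A": 1.0}, 18),   # singletons dropped
            ({"A": 10, "T": 10}, {"A": 0.5, "T": 0.5}, 20),
            ({"A": 1, "T": 1}, {}, 0),                      # unusable
        ],
    )
    def test_min_count_filtering(self, counts, expect_freqs, expect_depth):
        freqs, depth = allele_frequencies(counts, min_read_count=2)
        assert depth == expect_depth
        assert freqs == pytest.approx(expect_freqs)

    def test_frequencies_sum_to_one(self):
        freqs, _ = allele_frequencies({"A": 5, "C": 7, "G": 3, "T": 2}, 2)
        assert sum(freqs.values()) == pytest.approx(1.0)


class TestSiteFst:
    def test_fixed_different_alleles_is_one(self):
        assert site_fst({"A": 20}, {"T": 20}) == pytest.approx(1.0)

    def test_identical_pools_is_zero(self):
        assert site_fst({"A": 10, "T": 10}, {"A": 10, "T": 10}) == pytest.approx(0.0)

    def test_fixed_vs_balanced_is_one_third(self):
        # pi1=0, pi2=0.5, pi_within=0.25, pooled p(A)=0.75 -> pi_total=0.375
        assert site_fst({"A": 20}, {"A": 10, "T": 10}) == pytest.approx(1 / 3)

    def test_unusable_pool_returns_none(self):
        assert site_fst({"A": 1}, {"A": 10, "T": 10}) is None

    @given(
        c1=st.lists(st.integers(0, 60), min_size=4, max_size=4),
        c2=st.lists(st.integers(0, 60), min_size=4, max_size=4),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_fst_bounded(self, c1, c2):
        bases = ("A", "C", "G", "T")
        fst = site_fst(dict(zip(bases, c1)), dict(zip(bases, c2)))
        if fst is not None:
            assert -1e-9 <= fst <= 1 + 1e-9


class TestSexSnpFilter:
    CFG = ScanConfig()

    def test_xy_pattern_is_candidate(self):
        ok, reason = sex_snp_filter({"A": 1.0}, 20, {"A": 0.5, "T": 0.5}, 20, self.CFG)
        assert ok and reason == "pass"

    def test_both_fixed_rejected(self):
        ok, reason = sex_snp_filter(
            {"A": 0.95, "T": 0.05}, 20, {"A": 0.95, "T": 0.05}, 20, self.CFG
        )
        assert not ok and reason == "both_fixed"

    def test_depth_bounds_enforced(self):
        ok, reason = sex_snp_filter({"A": 1.0}, 8, {"A": 0.5, "T": 0.5}, 50, self.CFG)
        assert not ok and reason == "depth"

    def test_checks_fixed_allele_in_other_pool(self):
        """The polymorphic-band test applies to the allele fixed in the
        first pool, not the other pool's own major allele."""
        # pool2 major is T (0.6) but freq of pool1's fixed A is 0.4 -> pass
        ok, _ = sex_snp_filter({"A": 1.0}, 20, {"A": 0.4, "T": 0.6}, 20, self.CFG)
        assert ok
        # freq of the fixed allele outside the band -> fail
        ok, _ = sex_snp_filter({"A": 1.0}, 20, {"A": 0.2, "T": 0.8}, 20, self.CFG)
        assert not ok

    @given(
        f2a=st.floats(0.0, 1.0),
        d=st.integers(10, 100),
        thr2=st.floats(0.9, 1.0),
        widen=st.floats(0.0, 0.3),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_filter_monotonicity(self, f2a, d, thr2, widen):
        """Raising fixed_threshold never adds candidates; widening the
        polymorphic band never removes them."""
        base = ScanConfig()
        f1 = {"A": 1.0}
        f2 = {"A": f2a, "T": 1.0 - f2a}
        ok_base, _ = sex_snp_filter(f1, d, f2, d, base)
        stricter = ScanConfig(fixed_threshold=max(thr2, base.fixed_threshold))
        ok_strict, _ = sex_snp_filter(f1, d, f2, d, stricter)
        assert ok_base or not ok_strict
        wider = ScanConfig(
            min_polymorphic_freq=max(0.0, base.min_polymorphic_freq - widen),
            max_polymorphic_freq=min(1.0, base.max_polymorphic_freq + widen),
        )
        ok_wide, _ = sex_snp_filter(f1, d, f2, d, wider)
        assert ok_wide or not ok_base


class TestWindows:
    def _records(self, positions, candidates):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "fst": [0.5] * len(positions),
                "candidate": candidates,
            }
        )

    def test_window_counting_convention(self):
        rec = self._records([1_000, 5_000, 12_000], [True, True, True])
        win = window_summary(rec, 10_000)
        assert list(win["n_candidates"]) == [2, 1]
        assert list(win["window_start"]) == [1, 10_001]

    def test_no_candidates(self):
        rec = self._records([100, 15_000], [False, False])
        win = window_summary(rec, 10_000)
        assert (win["n_candidates"] == 0).all()

    def test_empty_input(self):
        win = window_summary(pd.DataFrame(columns=["chrom", "pos", "fst", "candidate"]))
        assert win.empty


def brute_force_scan(sites, cfg):
    """Independent per-site recomputation used as the oracle: plain Python,
    no shared code path with the scan implementation."""
    out = []
    for s in sites:
        kept1 = {b: c for b, c in s.pool1_counts.items()
                 if b in "ACGT" and c >= cfg.min_read_count}
        kept2 = {b: c for b, c in s.pool2_counts.items()
                 if b in "ACGT" and c >= cfg.min_read_count}
        d1, d2 = sum(kept1.values()), sum(kept2.values())
        if d1 == 0 or d2 == 0:
            continue
        f1 = {b: c / d1 for b, c in kept1.items()}
        f2 = {b: c / d2 for b, c in kept2.items()}
        pooled = {b: kept1.get(b, 0) + kept2.get(b, 0) for b in set(kept1) | set(kept2)}
        tot = sum(pooled.values())
        pi_t = 1 - sum((c / tot) ** 2 for c in pooled.values())
        pi_w = 0.5 * ((1 - sum(v * v for v in f1.values()))
                      + (1 - sum(v * v for v in f2.values())))
        fst = 0.0 if pi_t == 0 else (pi_t - pi_w) / pi_t
        cand = False
        if cfg.min_depth <= d1 <= cfg.max_depth and cfg.min_depth <= d2 <= cfg.max_depth:
            for fa, fb in ((f1, f2), (f2, f1)):
                major = max(sorted(fa), key=lambda b: fa[b])
                if fa[major] >= cfg.fixed_threshold and (
                    cfg.min_polymorphic_freq
                    <= fb.get(major, 0.0)
                    <= cfg.max_polymorphic_freq
                ):
                    cand = True
        out.append((s.pos, round(fst, 12), cand))
    return out


class TestScanOracle:
    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(42)
        sites = []
        for i in range(50):
            c1 = {b: int(rng.integers(0, 40)) for b in "ACGT"}
            c2 = {b: int(rng.integers(0, 40)) for b in "ACGT"}
            sites.append(PooledSiteCounts("chr1", 100 * (i + 1), "A", c1, c2))
        cfg = ScanConfig()
        res = scan(sites, cfg)
        expected = brute_force_scan(sites, cfg)
        got = [
            (int(r.pos), round(float(r.fst), 12), bool(r.candidate))
            for r in res.records.itertuples()
        ]
        assert got == expected


class TestScanEndToEnd:
    def test_planted_region_is_top_window_and_power_high(self, study):
        """With no sequencing error the sex-linked region dominates."""
        # depth 50 keeps nearly every site inside the scan's [10,100] depth
        # window, so the measurement is about the filter, not depth losses
        cfg = sim.PoolSimConfig(depth_mean=50, seq_error=0.0, snp_density=3.0,
                                seed=21)
        sites, truth = sim.simulate_pool_counts(study["x"], study["spec"], cfg)
        # ~600 sites genome-wide, ~25% of the genome is duplicated
        assert len(truth.sex_linked_sites) >= 120
        res = scan(sites)
        top = res.windows.sort_values(
            ["n_candidates", "window_start"], ascending=[False, True]
        ).iloc[0]
        lo, hi = study["spec"].dup_source
        # the top window overlaps the planted sex-linked region
        assert top.window_end >= lo and top.window_start <= hi
        linked = res.records[res.records.pos.isin(truth.sex_linked_sites)]
        usable = linked[linked.reason != "depth"]
        assert len(usable) >= 100
        assert usable.candidate.mean() >= 0.99

    def test_null_simulation_has_no_enriched_window(self, study):
        cfg = sim.PoolSimConfig(depth_mean=34, seq_error=0.002, snp_density=2.0,
                                sex_system="none", seed=22)
        sites, _ = sim.simulate_pool_counts(study["x"], None, cfg)
        res = scan(sites)
        assert len(enriched_windows(res.windows)) == 0

    def test_empty_input_gives_empty_tables(self):
        res = scan([])
        assert res.records.empty and res.windows.empty
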
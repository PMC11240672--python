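"""Adaptive calling parameters and the sliding-window ROH scanner."""

import math
from dataclasses import replace
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import rohscape as rs
from rohscape.datatypes import MISSING
from rohscape.roh import ROHCallingParams, detect_roh_single_pass, run_class_scheme

from conftest import brute_force_single_pass, make_dataset


class TestWindowSizeFormula:
    def test_numerator_equals_denominator(self):
        assert rs.compute_min_window_snps(0.5, 1, 1, 0.5) == 1

    @pytest.mark.parametrize(
        "alpha,n_snps,n_samples,het,expected",
        [(0.05, 33965, 1047, 0.335, 50), (0.05, 33965, 2323, 0.3567, 48)],
    )
    def test_study_scale_values(self, alpha, n_snps, n_samples, het, expected):
        """Direct evaluation of ln(a/(ns*ni))/ln(1-het) at 50K-chip scale,
        cross-checked with 50-digit decimal arithmetic."""
        assert rs.compute_min_window_snps(alpha, n_snps, n_samples, het) == expected
        from decimal import Decimal, getcontext

        getcontext().prec = 50
        num = (Decimal(str(alpha)) / (Decimal(n_snps) * Decimal(n_samples))).ln()
        den = (Decimal(1) - Decimal(str(het))).ln()
        assert int((num / den).to_integral_value(rounding="ROUND_HALF_EVEN")) == expected

    def test_monomorphic_het_fatal(self):
        with pytest.raises(ValueError, match="mean_het"):
            rs.compute_min_window_snps(0.05, 100, 10, 0.0)


class TestScanThreshold:
    @pytest.mark.parametrize(
        "n_out,L,expected", [(2, 50, 0.06), (0, 10, 0.1), (2, 48, 0.062)]
    )
    def test_floor_three_decimals(self, n_out, L, expected):
        t = rs.compute_scan_threshold(n_out, L)
        assert t == expected
        # truncation, never rounding up: t <= (n_out+1)/L exactly
        assert Fraction(t).limit_denominator(1000) <= Fraction(n_out + 1, L)

    def test_zero_window_fatal(self):
        with pytest.raises(ValueError):
            rs.compute_scan_threshold(2, 0)

    def test_floor_property_over_parameter_space(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=200, derandomize=True)
        @given(n_out=st.integers(0, 10), L=st.integers(1, 500))
        def check(n_out, L):
            t = rs.compute_scan_threshold(n_out, L)
            exact = Fraction(n_out + 1, L)
            # truncated to 3 decimals: within 1/1000 below the exact ratio
            assert Fraction(round(t * 1000), 1000) <= exact
            assert exact - Fraction(round(t * 1000), 1000) < Fraction(1, 1000)

        check()


def _params(**kw) -> ROHCallingParams:
    base = dict(window_snps=50, scan_threshold=0.06)
    base.update(kw)
    return ROHCallingParams(**base)


class TestSinglePass:
    def test_fully_homozygous_sample(self):
        """100 SNPs at 50 kb spacing, all homozygous -> one 100-SNP segment."""
        pos = [50_000 * (j + 1) for j in range(100)]
        ds = make_dataset([[0] * 100], positions=pos)
        seg = detect_roh_single_pass(ds, _params())
        assert len(seg) == 1
        row = seg.iloc[0]
        assert row.n_snps == 100
        assert row.start_bp == 50_000 and row.end_bp == 5_000_000
        assert row.length_bp == 5_000_000 - 50_000 + 1  # spans 4.95 Mb

    def test_central_heterozygote_breaks_run(self):
        """One het at SNP 50 (0 allowed): no segment contains it; 49-SNP
        flanks fail the 50-SNP minimum, so nothing is called — exactly as the
        explicit window enumeration predicts."""
        g = [0] * 100
        g[49] = 1
        pos = [50_000 * (j + 1) for j in range(100)]
        ds = make_dataset([g], positions=pos)
        p = _params()
        seg = detect_roh_single_pass(ds, p)
        oracle = brute_force_single_pass(np.array(g), np.array(pos), p)
        assert oracle == []
        assert seg.empty

    def test_all_heterozygous_empty(self):
        ds = make_dataset([[1] * 100])
        assert detect_roh_single_pass(ds, _params()).empty

    def test_chromosome_shorter_than_window_skipped(self, caplog):
        ds = make_dataset([[0] * 10])
        with caplog.at_level("WARNING"):
            seg = detect_roh_single_pass(ds, _params())
        assert seg.empty
        assert "no calls" in caplog.text

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Vectorized scanner equals the loop-by-loop oracle on random
        instances with scattered heterozygotes, missing calls and gaps."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(60, 200))
        g = np.zeros(m, dtype=np.int8)
        g[rng.random(m) < 0.04] = 1
        g[rng.random(m) < 0.04] = MISSING
        steps = rng.integers(10_000, 120_000, size=m)
        if seed % 2:  # occasionally inject an over-gap
            steps[m // 2] = 2_000_000
        pos = np.cumsum(steps)
        p = ROHCallingParams(
            window_snps=int(rng.integers(10, 40)),
            scan_threshold=float(rng.choice([0.05, 0.1, 0.3])),
            het_allowed=int(rng.integers(0, 2)),
            missing_allowed=int(rng.integers(0, 3)),
            min_length_bp=500_000,
            min_segment_snps=int(rng.integers(5, 25)),
        )
        ds = make_dataset([g], positions=pos)
        got = detect_roh_single_pass(ds, p)
        expected = brute_force_single_pass(g, pos, p)
        got_pairs = [
            (int(np.searchsorted(pos, r.start_bp)), int(np.searchsorted(pos, r.end_bp)))
            for r in got.itertuples(index=False)
        ]
        assert got_pairs == expected

    def test_relaxing_allowances_grows_in_roh_state(self):
        """More tolerated het/missing calls never shrink the set of SNPs in
        ROH state (the window hit-rate stage is monotone; the final
        segment-content filter is deliberately strict and can drop merged
        candidates, so end-to-end coverage is not asserted here)."""
        from rohscape.roh import _roh_state

        rng = np.random.default_rng(42)
        for _ in range(5):
            m = 150
            g = np.zeros((1, m), dtype=np.int8)
            g[0, rng.random(m) < 0.05] = 1
            g[0, rng.random(m) < 0.05] = MISSING
            prev = None
            for het_a, mis_a in [(0, 0), (0, 2), (1, 2), (2, 4)]:
                state = _roh_state(g, 20, 0.06, het_a, mis_a)
                if prev is not None:
                    assert (state | prev == state).all()
                prev = state

    def test_deterministic_and_ordered(self, inbred_population):
        _, (ds, _) = inbred_population
        sub = ds.subset(sample_idx=np.arange(12))
        p = _params(window_snps=30, scan_threshold=0.1)
        a = detect_roh_single_pass(sub, p)
        b = detect_roh_single_pass(sub, p)
        pd.testing.assert_frame_equal(a, b)
        order = a[["sample_id", "chromosome", "start_bp"]].apply(tuple, axis=1).tolist()
        assert order == sorted(order)


class TestClassScheme:
    def _one_sample(self, g, pos):
        return make_dataset([g], positions=pos)

    def test_clean_6mb_run_lands_in_4_8(self):
        """A clean 6-Mb autozygous run is retained by the 4-8 Mb pass only."""
        pos = np.arange(1, 301) * 50_000  # 15 Mb chromosome
        g = np.full(300, 1, dtype=np.int8)
        g[100:221] = 0  # positions 5.05 -> 11.05 Mb: 6.0 Mb + 1 bp run
        ds = self._one_sample(g, pos)
        base = _params(window_snps=25, scan_threshold=0.06, min_segment_snps=25)
        seg = run_class_scheme(ds, base)
        assert len(seg) == 1
        assert seg.iloc[0].class_label == "4-8"
        # cross-check against running every pass and filtering by length
        for label, lo, hi, n_mis, n_het in rs.CLASS_SCHEME:
            p = replace(base, missing_allowed=n_mis, het_allowed=n_het)
            sp = detect_roh_single_pass(ds, p)
            in_class = sp[(sp.length_bp >= lo) & (sp.length_bp < hi)]
            assert len(in_class) == (1 if label == "4-8" else 0)

    def test_10mb_run_with_het_yields_no_8_16_call(self):
        """A 10-Mb run containing one heterozygote cannot be called in the
        8-16 Mb class (that pass allows 0 het); only the clean flank long
        enough for its own class survives."""
        pos = np.arange(1, 401) * 50_000  # 20 Mb
        g = np.full(400, 1, dtype=np.int8)
        g[100:301] = 0  # 10 Mb run
        g[150] = 1  # one het inside
        ds = self._one_sample(g, pos)
        base = _params(window_snps=25, scan_threshold=0.06, min_segment_snps=25)
        seg = run_class_scheme(ds, base)
        assert not (seg.class_label == "8-16").any()
        # the right-hand clean flank (~7.5 Mb) is a legitimate 4-8 call
        assert (seg.class_label == "4-8").any()

    def test_no_autozygosity_empty(self):
        ds = self._one_sample(np.ones(200, dtype=np.int8), np.arange(1, 201) * 50_000)
        base = _params(window_snps=25, min_segment_snps=25)
        assert run_class_scheme(ds, base).empty

    def test_clean_planted_segment_endpoints(self):
        """With no missing calls or het errors, every planted 5-Mb segment is
        recovered, with endpoints within a few inter-SNP gaps of truth (N_out
        flank SNPs are excluded by design, marker gaps are exponential, and a
        chance-homozygous background SNP can extend a run slightly)."""
        from rohscape import SimulationConfig, simulate_population

        cfg = SimulationConfig(
            n_samples=10, n_chromosomes=4, chrom_length_bp=50_000_000,
            n_snps=4 * 2000, segment_lengths_bp=(5_000_000,),
            missing_rate=0.0, seed=5,
        )
        ds, truth = simulate_population(cfg)
        det = rs.ROHDetector().fit(ds)
        seg = det.segments_
        tol = 250_000  # 5% of the planted length
        hit = 0
        for t in truth.segments.itertuples(index=False):
            cand = seg[(seg.sample_id == t.sample_id)
                       & (seg.chromosome == t.chromosome)
                       & (seg.end_bp > t.start_bp) & (seg.start_bp < t.end_bp)]
            assert len(cand), f"planted segment not recovered for {t.sample_id}"
            s = cand.iloc[0]
            if (abs(int(s.start_bp) - t.start_bp) <= tol
                    and abs(int(s.end_bp) - t.end_bp) <= tol):
                hit += 1
        assert hit >= 0.9 * len(truth.segments)

    def test_planted_segment_recovered_near_truth(self, inbred_population):
        """On the realistic fixture (missing calls, many segments per sample)
        planted >=4-Mb segments are each covered >=90% by detected ROH."""
        _, (ds, truth) = inbred_population
        det = rs.ROHDetector().fit(ds)
        seg = det.segments_
        planted = truth.segments
        big = planted[planted.length_bp >= 4_000_000].head(50)
        good = 0
        for t in big.itertuples(index=False):
            cand = seg[(seg.sample_id == t.sample_id)
                       & (seg.chromosome == t.chromosome)
                       & (seg.end_bp > t.start_bp) & (seg.start_bp < t.end_bp)]
            ivals = sorted(zip(cand["start_bp"], cand["end_bp"]))
            cov, last = 0, -1
            for s, e in ivals:
                s, e = max(s, t.start_bp, last + 1), min(e, t.end_bp)
                if e >= s:
                    cov += e - s + 1
                    last = max(last, e)
            if cov >= 0.9 * t.length_bp:
                good += 1
        assert good >= 0.9 * len(big)


def test_class_summary_counts():
    seg = pd.DataFrame({"class_label": ["2-4"] * 3 + ["4-8"] * 5 + [">16"] * 2})
    summary = rs.segment_class_summary(seg)
    assert summary.loc[summary.class_label == "4-8", "proportion"].item() == 0.5
    assert summary["n_segments"].sum() == 10
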
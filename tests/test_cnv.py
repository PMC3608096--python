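import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from famphase.cnv import (
    ExonCoverageMatrix,
    call_exon_cnv,
    cnv_coseg_scan,
    coseg_contingency,
    fisher_exact_3x2,
    normalize_coverage,
)
from famphase.simulate import default_family

from oracles import fisher_3x2_oracle


def make_cov(depth, n_exons=None, samples=None):
    depth = np.asarray(depth, dtype=float)
    n, s = depth.shape
    exons = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 150,
            "name": [f"e{i}" for i in range(n)],
        }
    )
    return ExonCoverageMatrix(exons, depth, samples or [f"s{j}" for j in range(s)])


class TestNormalize:
    def test_global_library_size_factor_cancels(self, rng):
        base = rng.uniform(20, 100, size=(50, 1))
        depth = np.hstack([base, 2.0 * base])
        lr, baseline, mask = normalize_coverage(make_cov(depth))
        assert np.nanmax(np.abs(lr)) < 1e-12

    def test_half_depth_gives_minus_one(self):
        depth = np.full((40, 4), 50.0)
        depth[7, 0] = 25.0
        lr, _, _ = normalize_coverage(make_cov(depth))
        # library sizes differ slightly; the implanted exon is still ~ -1
        assert lr[7, 0] == pytest.approx(-1.0, abs=0.02)

    def test_low_baseline_masked_not_infinite(self):
        depth = np.full((10, 3), 50.0)
        depth[2] = 5.0
        depth[3] = 0.0
        lr, baseline, mask = normalize_coverage(make_cov(depth), min_baseline_depth=10)
        assert mask[2] and mask[3]
        assert np.isnan(lr[2]).all() and np.isnan(lr[3]).all()
        assert np.isfinite(lr[~mask]).all()

    def test_idempotence(self, rng):
        depth = rng.uniform(15, 120, size=(60, 6))
        _, _, _ = normalize_coverage(make_cov(depth))
        totals = depth.sum(axis=0)
        prenorm = depth / (totals / totals.mean())[None, :]
        lr1, _, _ = normalize_coverage(make_cov(depth))
        lr2, _, _ = normalize_coverage(make_cov(prenorm))
        assert np.nanmax(np.abs(lr1 - lr2)) < 1e-12


class TestCalls:
    def test_identical_samples_called_normal(self, rng):
        depth = np.tile(rng.uniform(20, 80, size=(100, 1)), (1, 8))
        calls = call_exon_cnv(make_cov(depth))
        assert (calls.state == 0).all()
        assert np.nanmin(calls.p_value) == pytest.approx(1.0)

    def test_state_matches_significance_and_sign(self, rng):
        depth = rng.poisson(50, size=(300, 8)).astype(float)
        depth[10, 0] *= 4.0
        depth[20, 3] *= 0.25
        calls = call_exon_cnv(make_cov(depth))
        ok = ~calls.mask
        sig = calls.p_value[ok] < calls.alpha
        state = calls.state[ok]
        lr = calls.log2_ratio[ok]
        assert ((state != 0) == sig).all()
        hit = state != 0
        assert (np.sign(state[hit]) == np.sign(lr[hit])).all()
        assert calls.state[10, 0] == 1 and calls.state[20, 3] == -1


class TestFisher:
    def test_perfect_four_vs_four(self):
        assert fisher_exact_3x2(np.array([[4, 0], [0, 4], [0, 0]])) == pytest.approx(2 / 70)

    def test_single_occupied_row_is_one(self):
        assert fisher_exact_3x2(np.array([[0, 0], [4, 4], [0, 0]])) == 1.0

    def test_zero_total_is_one_by_convention(self):
        assert fisher_exact_3x2(np.zeros((3, 2), dtype=int)) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_enumeration_exactly(self, seed):
        rng = np.random.default_rng(3000 + seed)
        for _ in range(50):
            n = int(rng.integers(1, 13))
            tab = rng.multinomial(n, np.ones(6) / 6).reshape(3, 2)
            assert fisher_exact_3x2(tab, as_fraction=True) == fisher_3x2_oracle(tab)

    def test_zero_row_collapse_equals_2x2_test(self, rng):
        """With an empty row the 3×2 test must reduce to the classical
        2×2 two-sided Fisher test (checked against scipy)."""
        for _ in range(40):
            tab2 = rng.integers(0, 6, size=(2, 2))
            tab3 = np.vstack([tab2, [0, 0]])
            expected = stats.fisher_exact(tab2, alternative="two-sided")[1]
            assert fisher_exact_3x2(tab3) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    @given(st.lists(st.integers(0, 6), min_size=6, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_probability_bounds_and_column_swap(self, cells):
        tab = np.array(cells).reshape(3, 2)
        p = fisher_exact_3x2(tab)
        assert 0.0 <= p <= 1.0
        assert p == fisher_exact_3x2(tab[:, ::-1].copy())
        assert p == fisher_exact_3x2(tab[::-1].copy())

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_agrees_with_r_fisher_test(self, rng):
        tables = [rng.multinomial(8, np.ones(6) / 6).reshape(3, 2) for _ in range(12)]
        script = "\n".join(
            "cat(fisher.test(matrix(c(%s), nrow=3, byrow=TRUE))$p.value, '\\n')"
            % ",".join(str(int(x)) for x in t.ravel())
            for t in tables
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        for t, r_p in zip(tables, out):
            assert fisher_exact_3x2(t) == pytest.approx(float(r_p), rel=1e-6, abs=1e-9)


class TestCosegScan:
    def test_contingency_counts_by_affection(self):
        ped = default_family()
        samples = [i.id for i in ped.members(sequenced=True)]
        aff = {i.id for i in ped.members(affection="affected", sequenced=True)}
        states = np.array([1 if s in aff else 0 for s in samples])
        tab = coseg_contingency(states, samples, ped)
        assert tab.tolist() == [[4, 0], [0, 4], [0, 0]]
        assert coseg_contingency(np.zeros(8, int), samples, ped).tolist() == [[0, 0], [4, 4], [0, 0]]

    def test_unknown_affection_excluded_with_warning(self, caplog):
        ped = default_family()
        samples = [i.id for i in ped.members(sequenced=True)] + ["II-6"]
        states = np.zeros(9, dtype=int)
        with caplog.at_level("WARNING"):
            tab = coseg_contingency(states, samples, ped)
        assert tab.sum() == 8
        assert "unknown affection" in caplog.text

    def test_custom_groups_supported(self):
        ped = default_family()
        samples = [i.id for i in ped.members(sequenced=True)]
        groups = {s: ("affected" if j < 2 else "unaffected") for j, s in enumerate(samples)}
        tab = coseg_contingency(np.ones(8, int), samples, ped, groups)
        assert tab.tolist() == [[2, 6], [0, 0], [0, 0]]

    def test_deletion_in_affected_only_attains_min_p(self, rng):
        ped = default_family()
        samples = [i.id for i in ped.members(sequenced=True)]
        aff_cols = [j for j, s in enumerate(samples) if ped[s].affection == "affected"]
        depth = rng.poisson(60, size=(200, 8)).astype(float)
        depth[50, aff_cols] *= 0.5
        calls = call_exon_cnv(make_cov(depth, samples=samples))
        scan = cnv_coseg_scan(calls, ped)
        assert scan["p"].min() == pytest.approx(2 / 70)
        assert scan.loc[scan["p"].idxmin(), "exon"] == "e50"

    def test_fully_normal_matrix_all_p_one(self):
        ped = default_family()
        samples = [i.id for i in ped.members(sequenced=True)]
        depth = np.tile(np.linspace(30, 90, 50)[:, None], (1, 8))
        calls = call_exon_cnv(make_cov(depth, samples=samples))
        scan = cnv_coseg_scan(calls, ped)
        assert (scan["p"] == 1.0).all()

    def test_masked_exons_absent_from_scan(self):
        ped = default_family()
        samples = [i.id for i in ped.members(sequenced=True)]
        depth = np.full((30, 8), 50.0)
        depth[4] = 3.0
        calls = call_exon_cnv(make_cov(depth, samples=samples))
        scan = cnv_coseg_scan(calls, ped)
        assert "e4" not in set(scan["exon"])
        assert len(scan) == 29
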
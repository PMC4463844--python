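"""Null-model simulation of Delta(SNP-index) and its confidence machinery."""

import numpy as np
import pandas as pd
import pytest

from qtlseq.null_ci import CiTable, NullDesign, attach_ci, build_ci_table, simulate_null_delta
from qtlseq.stats import sliding_windows
from conftest import enumerate_null_delta_pmf


class TestSimulateNullDelta:
    def test_ril_k1_depth1_matches_enumeration(self):
        """Single RIL individual, one read per bulk: Delta is -1/0/+1 with
        probabilities 1/4, 1/2, 1/4 by exhaustive enumeration."""
        design = NullDesign("RIL", k=1, error_rate=0.0)
        pmf = enumerate_null_delta_pmf(design, 1, 1)
        assert pmf == pytest.approx({-1.0: 0.25, 0.0: 0.5, 1.0: 0.25})
        sample = simulate_null_delta(design, 1, 1, 40_000, seed=1)
        for value, p in pmf.items():
            freq = (sample == value).mean()
            assert abs(freq - p) <= 4 * np.sqrt(p * (1 - p) / len(sample))

    @pytest.mark.parametrize("generation,depth", [("F2", 2), ("F4", 2), ("RIL", 2)])
    def test_k1_depth2_matches_enumeration(self, generation, depth):
        """Every outcome tree is enumerable at k=1, depth <= 2; Monte-Carlo
        atom frequencies must match the exact pmf."""
        design = NullDesign(generation, k=1, error_rate=0.0)
        pmf = enumerate_null_delta_pmf(design, depth, depth)
        assert sum(pmf.values()) == pytest.approx(1.0)
        sample = np.round(simulate_null_delta(design, depth, depth, 40_000, seed=2), 10)
        for value, p in pmf.items():
            freq = (sample == value).mean()
            assert abs(freq - p) <= 4 * np.sqrt(p * (1 - p) / len(sample)) + 1e-9

    @pytest.mark.parametrize("generation", ["F2", "F4", "RIL"])
    def test_null_symmetry(self, generation):
        design = NullDesign(generation, k=10, error_rate=0.0)
        sample = simulate_null_delta(design, 30, 30, 10_000, seed=3)
        se = sample.std(ddof=1) / np.sqrt(len(sample))
        assert abs(sample.mean()) <= 3 * se
        from scipy.stats import skew

        assert abs(skew(sample)) < 0.1

    def test_f4_bulk_frequency_law(self):
        """The mean bulk high-allele frequency is 1/2 and its variance is
        p*q*(1+F)/(2k) = 7/(32k) for the F4 (F = 3/4), checked against the
        exact single-individual law {0, 1/2, 1} w.p. 7:2:7."""
        probs = np.array(NullDesign("F4", 1).genotype_probs)
        contrib = np.array([0.0, 0.5, 1.0])
        exact_mean = float(probs @ contrib)
        exact_var_single = float(probs @ contrib**2 - exact_mean**2)
        assert exact_mean == pytest.approx(0.5)
        assert exact_var_single == pytest.approx(7 / 32)
        k = 10
        rng = np.random.default_rng(4)
        counts = rng.multinomial(k, probs, size=20_000)
        p = (0.5 * counts[:, 1] + counts[:, 2]) / k
        var = exact_var_single / k
        assert abs(p.mean() - 0.5) <= 3 * p.std(ddof=1) / np.sqrt(len(p))
        # sampling variance of a variance estimate: ~ var * sqrt(2/(n-1)) for
        # near-normal p; allow 4x that slack for the skewed discrete law
        assert abs(p.var(ddof=1) - var) <= 4 * var * np.sqrt(2 / (len(p) - 1))

    def test_deterministic_under_seed(self):
        d = NullDesign("F4", 10, 0.005)
        a = simulate_null_delta(d, 25, 35, 1000, seed=9)
        b = simulate_null_delta(d, 25, 35, 1000, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            NullDesign("F5", 10)
        with pytest.raises(ValueError):
            simulate_null_delta(NullDesign(), 0, 10, 10)
        with pytest.raises(ValueError):
            simulate_null_delta(NullDesign(), 10, 10, 0)


class TestCiTable:
    @pytest.fixture(scope="class")
    def table(self):
        return build_ci_table(NullDesign("F4", 10), [10, 20, 50, 100], n_reps=10_000, seed=5)

    def test_99_bounds_enclose_95(self, table):
        b = table.bounds
        assert (b["lo99"] <= b["lo95"]).all()
        assert (b["hi99"] >= b["hi95"]).all()
        assert (b["hi95"] >= 0).all() and (b["lo95"] <= 0).all()

    def test_width_non_increasing_in_depth(self, table):
        for tag in ("95", "99"):
            width = (table.bounds[f"hi{tag}"] - table.bounds[f"lo{tag}"]).to_numpy()
            violations = (np.diff(width) > 0).sum()
            assert violations <= 1  # one Monte-Carlo inversion tolerated

    def test_lookup_clamps_to_nearest_depth(self, table):
        lo10, hi10 = table.lookup(3, 0.95)
        lo_tab, hi_tab = table.lookup(10, 0.95)
        assert lo10[0] == lo_tab[0] and hi10[0] == hi_tab[0]
        lo, _ = table.lookup([14, 16, 1000], 0.95)
        assert lo[0] == table.bounds.loc[10, "lo95"]
        assert lo[1] == table.bounds.loc[20, "lo95"]
        assert lo[2] == table.bounds.loc[100, "lo95"]

    def test_tsv_round_trip(self, table, tmp_path):
        path = tmp_path / "ci.tsv"
        table.to_tsv(path)
        back = CiTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.bounds, table.bounds, check_names=False)
        assert back.design == table.design
        assert back.n_reps == table.n_reps

    def test_low_rep_count_warns(self, caplog):
        with caplog.at_level("WARNING"):
            build_ci_table(NullDesign(), [10], n_reps=500, seed=6)
        assert any("unstable" in r.message for r in caplog.records)


class TestCoverage:
    def test_matched_depth_coverage_within_three_se(self):
        """Fresh null draws at the tabulated depths fall outside the 95%
        (99%) bounds at a rate within 3 binomial SE of 0.05 (0.01).  Depths
        are high enough that the discrete Delta lattice is fine relative
        to the tail density."""
        design = NullDesign("F4", 10, 0.0)
        depths = [75, 100]
        ci = build_ci_table(design, depths, n_reps=50_000, seed=50)
        for level, alpha in ((0.95, 0.05), (0.99, 0.01)):
            outside = total = 0
            for d in depths:
                fresh = simulate_null_delta(design, d, d, 20_000, seed=60 + d)
                lo, hi = ci.lookup(d, level)
                outside += int(((fresh < lo[0]) | (fresh > hi[0])).sum())
                total += len(fresh)
            frac = outside / total
            assert abs(frac - alpha) <= 3 * np.sqrt(alpha * (1 - alpha) / total)

    def test_end_to_end_pipeline_coverage_slightly_conservative(self, null_snp_table):
        """Through the full pipeline (Poisson depths, min-depth lookup) the
        outside fraction never exceeds alpha + 3 SE and undershoots by at
        most ~0.015: the min-depth lookup and the Delta lattice make the
        bounds conservative by design."""
        sites, ci = null_snp_table
        dmin = np.minimum(sites["lsb_depth"], sites["hsb_depth"]).to_numpy()
        delta = sites["delta"].to_numpy()
        n = len(sites)
        assert n > 15_000
        for level, alpha in ((0.95, 0.05), (0.99, 0.01)):
            lo, hi = ci.lookup(dmin, level)
            frac = ((delta < lo) | (delta > hi)).mean()
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n)
            assert frac >= alpha - 0.015

    def test_null_grand_mean_delta_near_zero(self, null_snp_table):
        sites, _ = null_snp_table
        delta = sites["delta"].to_numpy()
        se = delta.std(ddof=1) / np.sqrt(len(delta))
        assert abs(delta.mean()) <= 3 * se


class TestAttachCi:
    def windows_for(self, sites):
        return sliding_windows(sites, {"Ca1": 200}, window_bp=100, step_bp=100, min_snps=1)

    def make_sites(self, pos, depths):
        df = pd.DataFrame(
            {
                "chrom": "Ca1",
                "pos": pos,
                "lsb_high": 0,
                "lsb_depth": depths,
                "hsb_high": depths,
                "hsb_depth": depths,
            }
        )
        df["lsb_index"] = 0.0
        df["hsb_index"] = 1.0
        df["delta"] = 1.0
        return df

    @pytest.fixture(scope="class")
    def ci(self):
        return build_ci_table(NullDesign("F4", 10), [10, 100], n_reps=5000, seed=7)

    def test_uniform_depth_window_gets_tabulated_bound(self, ci):
        sites = self.make_sites([10, 50, 90], [10, 10, 10])
        win = attach_ci(self.windows_for(sites), sites, ci)
        assert win.loc[0, "lo95"] == pytest.approx(ci.bounds.loc[10, "lo95"])
        assert win.loc[0, "hi99"] == pytest.approx(ci.bounds.loc[10, "hi99"])

    def test_mixed_depths_average_to_midpoint(self, ci):
        sites = self.make_sites([10, 50], [10, 100])
        win = attach_ci(self.windows_for(sites), sites, ci)
        mid = 0.5 * (ci.bounds.loc[10, "hi95"] + ci.bounds.loc[100, "hi95"])
        assert win.loc[0, "hi95"] == pytest.approx(mid)

    def test_window_bound_matches_brute_force_average(self, ci):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 200), size=12, replace=False))
        depths = rng.choice([10, 100], size=12)
        sites = self.make_sites(pos, depths)
        win = attach_ci(self.windows_for(sites), sites, ci)
        for _, w in win.iterrows():
            inside = (pos >= w["start"]) & (pos <= w["end"])
            if not inside.any():
                assert np.isnan(w["lo95"])
                continue
            expect = np.mean([ci.bounds.loc[d, "lo95"] for d in depths[inside]])
            assert w["lo95"] == pytest.approx(expect)

    def test_empty_window_carries_no_bounds(self, ci):
        sites = self.make_sites([150], [10])
        win = attach_ci(self.windows_for(sites), sites, ci)
        assert np.isnan(win.loc[0, "lo95"])  # first window holds no SNP
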
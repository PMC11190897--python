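"""Differential-expression chain: filtering, TMM, dispersion, exact test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from nocimap import bulk_de, simulate
from nocimap.bulk_de import CountMatrix


class TestFilterLowCounts:
    def test_all_zero_gene_removed(self, toy_counts):
        kept = bulk_de.filter_low_counts(toy_counts)
        assert "g0" not in kept.gene_ids

    def test_one_sample_per_group_removed(self, toy_counts):
        # g3 reaches the CPM cutoff in exactly one sample of each group
        kept = bulk_de.filter_low_counts(toy_counts, min_cpm=1.0, min_samples_per_group=2)
        assert "g3" not in kept.gene_ids

    def test_hand_enumerated_retained_set(self, toy_counts):
        kept = bulk_de.filter_low_counts(toy_counts, min_cpm=1.0, min_samples_per_group=2)
        # g1: CPM >= 1 in s1, s2 (group A); g2, g4: everywhere
        assert list(kept.gene_ids) == ["g1", "g2", "g4"]

    def test_order_preserved_and_empty_warns(self, toy_counts):
        with pytest.warns(UserWarning):
            out = bulk_de.filter_low_counts(toy_counts, min_cpm=1e9)
        assert len(out.gene_ids) == 0


def _brute_tmm_factor(obs, ref, n_obs, n_ref, trim_m=0.3, trim_a=0.05):
    """Independent brute-force doubly-trimmed weighted mean of M-values."""
    ok = (obs > 0) & (ref > 0)
    p_obs, p_ref = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    keep = np.ones(len(m), dtype=bool)
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep &= (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    return 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(
            np.tile([[10], [200], [3000], [50]], (1, 4)),
            index=list("abcd"), columns=list("wxyz"),
        )
        cm = CountMatrix(counts, pd.Series(["A", "A", "B", "B"], index=counts.columns))
        f = bulk_de.tmm_factors(cm)
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        base = np.array([10, 200, 3000, 50, 400])
        counts = pd.DataFrame({"a": base, "b": 2 * base}, index=[f"g{i}" for i in range(5)])
        cm = CountMatrix(counts, pd.Series(["A", "B"], index=["a", "b"]))
        f = bulk_de.tmm_factors(cm)
        assert np.allclose(f.factors, 1.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(200, size=(20, 2)) + 1, index=[f"g{i}" for i in range(20)],
            columns=["ref", "obs"],
        )
        counts.iloc[:5, 1] *= 3  # asymmetry so trimming matters
        cm = CountMatrix(counts, pd.Series(["A", "B"], index=counts.columns))
        f = bulk_de.tmm_factors(cm, ref_sample="ref")
        lib = counts.sum(axis=0)
        raw = _brute_tmm_factor(
            counts["obs"].to_numpy(float), counts["ref"].to_numpy(float),
            float(lib["obs"]), float(lib["ref"]),
        )
        expected = np.array([1.0, raw])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f.factors[["ref", "obs"]].to_numpy(), expected, rtol=1e-10)

    def test_geometric_mean_one(self, nb_sim_null):
        cm, _ = nb_sim_null
        f = bulk_de.tmm_factors(cm)
        assert abs(np.exp(np.mean(np.log(f.factors))) - 1.0) < 1e-9

    def test_all_zero_sample_raises(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g0", "g1"])
        cm = CountMatrix(counts, pd.Series(["A", "B"], index=["a", "b"]))
        with pytest.raises(ValueError, match="b"):
            bulk_de.tmm_factors(cm)


class TestDispersion:
    def test_poisson_data_gives_near_zero_common(self):
        cfg = simulate.SimulationConfig(
            seed=3, n_genes=2000, n_samples_per_group=5, n_de_genes=0, dispersion=0.0
        )
        cm, _ = simulate.simulate_bulk_counts(cfg)
        f = bulk_de.tmm_factors(cm)
        disp = bulk_de.estimate_dispersion(cm, f)
        assert disp.common <= 0.01

    def test_nb_dispersion_recovered(self, nb_sim_null):
        cm, _ = nb_sim_null
        f = bulk_de.tmm_factors(cm)
        disp = bulk_de.estimate_dispersion(cm, f)
        assert 0.15 <= disp.common <= 0.25

    def test_infinite_prior_shrinks_to_common(self, nb_sim_null):
        cm, _ = nb_sim_null
        sub = cm.subset_genes(cm.gene_ids[:200])
        f = bulk_de.tmm_factors(sub)
        disp = bulk_de.estimate_dispersion(sub, f, prior_df=1e6)
        assert np.max(np.abs(disp.tagwise.to_numpy() - disp.common)) <= 1e-3

    def test_single_sample_groups_raise(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [12, 18]}, index=["g0", "g1"])
        cm = CountMatrix(counts, pd.Series(["A", "B"], index=["a", "b"]))
        f = bulk_de.tmm_factors(cm)
        with pytest.raises(ValueError):
            bulk_de.estimate_dispersion(cm, f)


def _binomial_exact_p(total, k_obs, n_a, n_b):
    """Enumeration oracle for the phi=0 conditional test."""
    from math import comb

    p_a = n_a / (n_a + n_b)
    probs = [
        comb(total, k) * p_a**k * (1 - p_a) ** (total - k) for k in range(total + 1)
    ]
    return sum(p for p in probs if p <= probs[k_obs] * (1 + 1e-12))


class TestExactTest:
    @staticmethod
    def _make(counts_a, counts_b):
        n_a, n_b = len(counts_a[0]), len(counts_b[0])
        data = np.hstack([np.array(counts_a), np.array(counts_b)])
        cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        counts = pd.DataFrame(data, index=[f"g{i}" for i in range(data.shape[0])], columns=cols)
        groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
        return CountMatrix(counts, groups)

    def test_identical_split_gives_p_one(self):
        cm = self._make([[5, 5]], [[5, 5]])
        f = bulk_de.tmm_factors(cm)
        disp = bulk_de.DispersionEstimate(0.1, pd.Series([0.1], index=cm.gene_ids))
        res = bulk_de.nb_exact_test(cm, f, disp, "A", "B")
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("k_obs", [0, 2, 5, 8, 10])
    def test_matches_binomial_enumeration_at_phi_zero(self, k_obs):
        # equal library sizes so pseudocounts equal raw counts
        cm = self._make([[k_obs, 0]], [[10 - k_obs, 0]])
        # pad with a balancing gene so library sizes match exactly
        counts = cm.counts.copy()
        counts.loc["pad"] = [1000 - k_obs, 1000, 1000 - (10 - k_obs), 1000]
        cm2 = CountMatrix(counts, cm.groups)
        f = bulk_de.NormalizationFactors(
            pd.Series(1.0, index=cm2.sample_ids), ref_sample="a0"
        )
        disp = bulk_de.DispersionEstimate(0.0, pd.Series(0.0, index=cm2.gene_ids))
        res = bulk_de.nb_exact_test(cm2, f, disp, "A", "B")
        expected = _binomial_exact_p(10, k_obs, 2, 2)
        assert res["pvalue"].loc["g0"] == pytest.approx(expected, rel=1e-9)

    def test_group_swap_negates_lfc_keeps_p(self, nb_sim_planted):
        cm, _ = nb_sim_planted
        sub = cm.subset_genes(cm.gene_ids[:100])
        f = bulk_de.tmm_factors(sub)
        disp = bulk_de.estimate_dispersion(sub, f)
        ab = bulk_de.nb_exact_test(sub, f, disp, "case", "control")
        ba = bulk_de.nb_exact_test(sub, f, disp, "control", "case")
        assert np.allclose(ab["pvalue"], ba["pvalue"])
        assert np.allclose(ab["log2fc"], -ba["log2fc"])

    def test_depth_doubling_leaves_p_invariant(self, nb_sim_null):
        cm, _ = nb_sim_null
        sub = cm.subset_genes(cm.gene_ids[:150])
        f = bulk_de.tmm_factors(sub)
        disp = bulk_de.estimate_dispersion(sub, f)
        p0 = bulk_de.nb_exact_test(sub, f, disp, "case", "control")["pvalue"]

        doubled = sub.counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        cm2 = CountMatrix(doubled, sub.groups)
        f2 = bulk_de.tmm_factors(cm2)
        disp2 = bulk_de.DispersionEstimate(disp.common, disp.tagwise)
        p1 = bulk_de.nb_exact_test(cm2, f2, disp2, "case", "control")["pvalue"]
        # pseudocount rounding makes this near- rather than bit-exact
        assert np.median(np.abs(np.log10(p1 + 1e-300) - np.log10(p0 + 1e-300))) < 0.05

    def test_bh_monotone_and_at_least_p(self, nb_sim_null):
        cm, _ = nb_sim_null
        sub = cm.subset_genes(cm.gene_ids[:300])
        f = bulk_de.tmm_factors(sub)
        disp = bulk_de.estimate_dispersion(sub, f)
        res = bulk_de.nb_exact_test(sub, f, disp, "case", "control")
        assert (res["fdr"] >= res["pvalue"] - 1e-12).all()
        srt = res.sort_values("pvalue")
        assert (np.diff(srt["fdr"].to_numpy()) >= -1e-12).all()
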
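import numpy as np
import pandas as pd
import pytest

import oracles
from rgstab import (
    BestKeeper,
    ComparativeDeltaCt,
    GeNorm,
    NormFinder,
    bestkeeper,
    delta_ct_stability,
    genorm,
    normfinder,
    to_quantities,
)

from conftest import make_crt, random_crt


def cq_dict(m):
    return {g: list(m.values.loc[g]) for g in m.gene_ids}


class TestGeNorm:
    def test_brute_force_trace(self, rng):
        m = random_crt(rng, n_genes=5, n_samples=6)
        res = genorm(to_quantities(m))
        exp_m, exp_order, exp_pair = oracles.genorm_trace(cq_dict(m))
        for g in m.gene_ids:
            assert res.reported_m[g] == pytest.approx(exp_m[g], abs=1e-12)
            assert res.exclusion_order[g] == exp_order[g]
        assert tuple(sorted(res.final_pair)) == exp_pair

    def test_constant_ratio_pair_has_zero_variation(self):
        base = np.array([18.0, 19.0, 17.5, 18.4])
        m = make_crt([base, base + np.log2(1 / 0.3), base + [0, 1, -1, 0.5]])
        res = genorm(to_quantities(m))
        # g2 = 0.3 * g1 in quantity space in every sample
        assert res.reported_m["g1"] == res.reported_m["g2"]
        assert set(res.final_pair) == {"g1", "g2"}

    def test_invariant_to_sample_offset(self, rng):
        m = random_crt(rng, n_genes=4, n_samples=5)
        shifted = m.copy()
        shifted.values.iloc[:, 2] += 0.7
        a = genorm(to_quantities(m))
        b = genorm(to_quantities(shifted))
        np.testing.assert_allclose(a.reported_m, b.reported_m, atol=1e-12)

    def test_final_pair_shares_m_and_rank_one(self, rng):
        m = random_crt(rng, n_genes=6, n_samples=5)
        res = genorm(to_quantities(m))
        a, b = res.final_pair
        assert res.reported_m[a] == res.reported_m[b]
        assert res.ranking[a] == res.ranking[b] == 1
        assert sorted(res.exclusion_order) == list(range(1, 7))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            GeNorm().fit(np.random.default_rng(0).uniform(14, 20, (4, 2)))

    def test_pairwise_v_trace_available(self, rng):
        m = random_crt(rng, n_genes=5, n_samples=6)
        res = genorm(to_quantities(m), compute_pairwise_v=True)
        assert res.pairwise_v.shape == (3,)  # n = 2..G-1
        assert np.all(res.pairwise_v >= 0)


class TestNormFinder:
    def test_identical_genes_all_zero(self):
        x = np.tile(np.array([18.0, 19.0, 17.0, 18.5]), (4, 1))
        est = NormFinder().fit(x.T)
        np.testing.assert_allclose(est.stability_, 0.0, atol=1e-12)

    def test_second_implementation_ungrouped(self, rng):
        m = random_crt(rng, n_genes=5, n_samples=7)
        logq = -m.values
        res = normfinder(logq)
        exp = oracles.normfinder_values({g: list(logq.loc[g]) for g in m.gene_ids})
        for g in m.gene_ids:
            assert res.stability[g] == pytest.approx(exp[g], abs=1e-9)
        assert res.mode == "ungrouped"

    def test_second_implementation_grouped(self, rng):
        m = random_crt(rng, n_genes=4, n_samples=6)
        groups = ["A", "A", "A", "B", "B", "B"]
        logq = -m.values
        res = normfinder(logq, groups)
        exp = oracles.normfinder_values(
            {g: list(logq.loc[g]) for g in m.gene_ids}, groups
        )
        for g in m.gene_ids:
            assert res.stability[g] == pytest.approx(exp[g], abs=1e-9)
        # intergroup d values sum to zero per gene (balanced design)
        np.testing.assert_allclose(res.intergroup_d.sum(axis=1), 0.0, atol=1e-9)

    def test_negative_variance_clamped(self):
        # one gene mirrors the panel mean so its corrected variance is negative
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 6)
        x = np.vstack([base, base, base, base + rng.normal(0, 3, 6)])
        est = NormFinder(input_scale="log2").fit(x.T)
        assert (est.intragroup_variance_ >= 0).all()
        assert (est.stability_ >= 0).all()

    def test_bad_inputs_rejected(self):
        x = np.random.default_rng(0).uniform(14, 20, (4, 2))
        with pytest.raises(ValueError, match="3 genes"):
            NormFinder().fit(x)
        x = np.random.default_rng(0).uniform(14, 20, (4, 4))
        with pytest.raises(ValueError, match="fewer than 2"):
            NormFinder().fit(x, ["A", "A", "A", "B"])
        with pytest.raises(ValueError, match="2 groups"):
            NormFinder().fit(x, ["A", "A", "A", "A"])


class TestBestKeeper:
    def test_constant_gene(self):
        m = make_crt([[15.0, 15.0, 15.0], [14.0, 16.0, 15.0]])
        res = bestkeeper(m)
        assert res.sd_cp["g1"] == 0.0
        assert res.cv_pct["g1"] == 0.0
        assert np.isnan(res.r_index["g1"])  # zero variance: missing, not error

    def test_identical_genes_correlate_perfectly_with_index(self):
        row = [14.0, 16.0, 15.0, 17.0]
        m = make_crt([row, row, row])
        res = bestkeeper(m)
        np.testing.assert_allclose(res.r_index, 1.0)
        np.testing.assert_allclose(res.index, row)

    @pytest.mark.parametrize("dispersion", ["mad", "sd"])
    def test_brute_force(self, rng, dispersion):
        m = random_crt(rng, n_genes=3, n_samples=5)
        res = bestkeeper(m, dispersion=dispersion)
        exp = oracles.bestkeeper_values(cq_dict(m), dispersion)
        for g in m.gene_ids:
            assert res.sd_cp[g] == pytest.approx(exp[g]["sd_cp"], abs=1e-9)
            assert res.cv_pct[g] == pytest.approx(exp[g]["cv_pct"], abs=1e-9)
            assert res.r_index[g] == pytest.approx(exp[g]["r_index"], abs=1e-9)

    def test_gene_shift_invariance_of_dispersion(self, rng):
        m = random_crt(rng, n_genes=4, n_samples=6)
        shifted = m.copy()
        shifted.values.loc["g2"] += 3.0
        a, b = bestkeeper(m), bestkeeper(shifted)
        np.testing.assert_allclose(a.sd_cp, b.sd_cp, atol=1e-12)
        assert a.cv_pct["g2"] != pytest.approx(b.cv_pct["g2"])


class TestComparativeDeltaCt:
    def test_constant_difference_pair(self):
        base = np.array([14.0, 15.0, 16.0, 15.5])
        m = make_crt([base, base + 2.0, base + [0, 1, 0, 1]])
        est = ComparativeDeltaCt().fit(m.values.T)
        assert est.pair_sd_[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force(self, rng):
        m = random_crt(rng, n_genes=3, n_samples=4)
        res = delta_ct_stability(m)
        exp = oracles.delta_ct_values(cq_dict(m))
        for g in m.gene_ids:
            assert res.mean_pair_sd[g] == pytest.approx(exp[g], abs=1e-9)

    def test_equals_first_pass_genorm_m(self, rng):
        """SD(log2(q_g/q_h)) = SD(Cq_h - Cq_g): ΔCt == initial geNorm M."""
        for _ in range(20):
            g = rng.integers(3, 13)
            n = rng.integers(3, 10)
            m = random_crt(rng, n_genes=g, n_samples=n)
            dct = delta_ct_stability(m).mean_pair_sd
            est = GeNorm().fit(m.values.T)
            first_m = est.pairwise_variation_matrix_.sum(axis=1) / (g - 1)
            np.testing.assert_allclose(dct.to_numpy(), first_m, atol=1e-12)


@pytest.mark.parametrize("cls", [GeNorm, NormFinder, BestKeeper, ComparativeDeltaCt])
def test_permutation_equivariance_and_nonnegativity(rng, cls):
    m = random_crt(rng, n_genes=6, n_samples=7)
    X = m.values.T
    perm = rng.permutation(6)
    a = cls().fit(X)
    b = cls().fit(X.iloc[:, perm])
    np.testing.assert_allclose(np.asarray(a.stability_)[perm], b.stability_,
                               atol=1e-9)
    assert np.all(np.asarray(a.stability_) >= 0)


def test_noisiest_gene_ranked_last_by_all_estimators(rng):
    """A gene with 4x the noise SD of its peers lands last almost always."""
    hits = 0
    n_rep = 200
    for r in range(n_rep):
        rep_rng = np.random.default_rng(5000 + r)
        base = rep_rng.uniform(12, 22, 6)
        noise = np.array([0.25, 0.25, 0.25, 0.25, 0.25, 1.0])
        x = base[:, None] + rep_rng.normal(0, 1, (6, 9)) * noise[:, None]
        X = pd.DataFrame(x.T, columns=[f"g{i}" for i in range(6)])
        last = all(
            int(np.asarray(cls().fit(X).ranking_)[5]) == 6
            for cls in (GeNorm, NormFinder, BestKeeper, ComparativeDeltaCt)
        )
        hits += last
    assert hits >= 0.95 * n_rep
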
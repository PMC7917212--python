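import numpy as np
import pytest

from rgstab import (
    SyntheticSpec,
    delta_delta_ct,
    generate,
    grubbs_test,
    mean_modulation,
    one_sample_ttest,
)
from rgstab.relquant import grubbs_critical_value

from conftest import make_crt


def paired_design(values, gene_ids, tissues=("CC", "BMSC"), donors=("d1", "d2", "d3")):
    t = [ti for ti in tissues for _ in donors]
    d = list(donors) * len(tissues)
    sample_ids = [f"{ti}_{di}" for ti, di in zip(t, d)]
    return make_crt(values, gene_ids=gene_ids, sample_ids=sample_ids,
                    tissues=t, donors=d)


class TestDeltaDeltaCt:
    def test_one_cycle_is_twofold(self):
        # target one cycle lower in BMSC than CC, RG unchanged
        m = paired_design(
            [[20.0, 20.0, 20.0, 19.0, 19.0, 19.0],
             [15.0, 15.0, 15.0, 15.0, 15.0, 15.0]],
            gene_ids=["tgt", "rg"],
        )
        fc = delta_delta_ct(m, ["tgt"], "rg", "CC")
        np.testing.assert_allclose(fc.folds("tgt", "BMSC"), 2.0)

    def test_self_normalization_is_unity(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(14, 20, (2, 6))
        m = paired_design(vals, gene_ids=["tgt", "rg"])
        same = m.copy()
        same.values.loc["tgt"] = same.values.loc["rg"]
        fc = delta_delta_ct(same, ["tgt"], "rg", "CC")
        np.testing.assert_allclose(fc.folds("tgt", "BMSC"), 1.0)

    def test_hand_evaluated_toy(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(12, 22, (3, 9))
        t = ["CC"] * 3 + ["BMSC"] * 3 + ["ASC"] * 3
        d = ["d1", "d2", "d3"] * 3
        sample_ids = [f"{ti}_{di}" for ti, di in zip(t, d)]
        m = make_crt(vals, gene_ids=["t1", "t2", "rg"], sample_ids=sample_ids,
                     tissues=t, donors=d)
        fc = delta_delta_ct(m, ["t1", "t2"], "rg", "CC")
        for tgt in ("t1", "t2"):
            for tis in ("BMSC", "ASC"):
                for i, donor in enumerate(["d1", "d2", "d3"]):
                    s_t, s_c = f"{tis}_{donor}", f"CC_{donor}"
                    ddct = (
                        m.values.loc[tgt, s_t] - m.values.loc["rg", s_t]
                    ) - (m.values.loc[tgt, s_c] - m.values.loc["rg", s_c])
                    assert fc.table.loc[(tgt, tis), f"fold_{donor}"] == \
                        pytest.approx(2.0 ** (-ddct))

    def test_rg_change_multiplies_folds_consistently(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(12, 22, (3, 6))
        m = paired_design(vals, gene_ids=["tgt", "rgA", "rgB"])
        fa = delta_delta_ct(m, ["tgt"], "rgA", "CC")
        fb = delta_delta_ct(m, ["tgt"], "rgB", "CC")
        for donor in ("d1", "d2", "d3"):
            s_t, s_c = f"BMSC_{donor}", f"CC_{donor}"
            shift = (
                m.values.loc["rgB", s_t] - m.values.loc["rgA", s_t]
            ) - (m.values.loc["rgB", s_c] - m.values.loc["rgA", s_c])
            assert fb.table.loc[("tgt", "BMSC"), f"fold_{donor}"] == pytest.approx(
                fa.table.loc[("tgt", "BMSC"), f"fold_{donor}"] * 2.0 ** shift
            )

    def test_rg_among_targets_rejected_and_unmatched_donor_dropped(self):
        rng = np.random.default_rng(9)
        m = paired_design(rng.uniform(14, 20, (2, 6)), gene_ids=["tgt", "rg"])
        with pytest.raises(ValueError, match="reference gene"):
            delta_delta_ct(m, ["rg"], "rg", "CC")
        unmatched = m.subset(sample_ids=[s for s in m.sample_ids if s != "BMSC_d3"])
        with pytest.warns(UserWarning, match="d3"):
            fc = delta_delta_ct(unmatched, ["tgt"], "rg", "CC")
        assert len(fc.folds("tgt", "BMSC")) == 2

    def test_stable_rg_recovers_true_effect(self):
        """-1 cycle tissue effect on a target + perfect RG -> fold ~ 2."""
        genes = ["tgt", "rg"]
        eff = np.zeros((2, 3))
        import pandas as pd
        spec = SyntheticSpec(
            gene_ids=genes,
            tissue_effect=pd.DataFrame(
                [[0.0, -1.0, 0.0], [0.0, 0.0, 0.0]],
                index=genes, columns=["CC", "BMSC", "ASC"],
            ),
            noise_sd=[0.05, 0.01],
            target_genes=["tgt"],
            donors=[f"d{i}" for i in range(1, 7)],
            seed=42,
        )
        folds = []
        for r in range(20):
            m, _ = generate(spec, seed=100 + r)
            fc = delta_delta_ct(m, ["tgt"], "rg", "CC")
            folds.append(fc.table.loc[("tgt", "BMSC"), "mean_fold"])
        assert np.mean(folds) == pytest.approx(2.0, rel=0.05)


class TestOneSampleTTest:
    def test_null_data(self):
        res = one_sample_ttest([1.0, 1.0, 1.0], mu=1.0)
        assert res.t_stat == 0.0 and res.p_value == 1.0 and res.tier == "ns"
        assert res.degenerate

    def test_closed_form_example(self):
        res = one_sample_ttest([0.5, 0.6, 0.4], mu=1.0)
        assert res.t_stat == pytest.approx(-8.660, abs=1e-3)
        assert res.p_value == pytest.approx(0.0131, abs=2e-4)
        assert res.tier == "*"

    def test_log2_scale(self):
        vals = [0.5, 0.25, 0.125]
        res = one_sample_ttest(vals, mu=1.0, scale="log2")
        exp = np.log2(vals)
        t = exp.mean() / (exp.std(ddof=1) / np.sqrt(3))
        assert res.t_stat == pytest.approx(t)

    def test_degenerate_nonnull(self):
        res = one_sample_ttest([2.0, 2.0], mu=1.0)
        assert res.p_value == 0.0 and res.degenerate

    @pytest.mark.parametrize("p,tier", [(0.0005, "***"), (0.005, "**"),
                                        (0.03, "*"), (0.07, "§"), (0.5, "ns")])
    def test_tier_cutoffs(self, p, tier):
        from rgstab.relquant import significance_tier
        assert significance_tier(p) == tier

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            one_sample_ttest([1.0])


class TestGrubbs:
    def test_symmetric_triplet_not_flagged(self):
        rep = grubbs_test([1.0, 2.0, 3.0])
        assert rep.g_stat == pytest.approx(1.0)
        assert not rep.has_outlier
        # n=3, alpha=0.05 critical value from the t-quantile formula
        assert rep.critical_value == pytest.approx(1.1543, abs=1e-3)

    def test_extreme_value_flagged(self):
        rep = grubbs_test([1.0, 1.1, 0.9, 3.0])
        assert rep.g_stat == pytest.approx(1.495, abs=1e-3)
        assert rep.critical_value == pytest.approx(1.4812, abs=1e-3)
        assert rep.outlier_index == 3

    def test_constant_values_degenerate(self):
        rep = grubbs_test([2.0, 2.0, 2.0])
        assert not rep.has_outlier and rep.degenerate

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            grubbs_test([1.0, 2.0])

    def test_critical_value_monotone_in_n(self):
        crits = [grubbs_critical_value(n) for n in range(3, 30)]
        assert all(a < b for a, b in zip(crits, crits[1:]))


class TestMeanModulation:
    def _fc(self, folds_by_target):
        m = paired_design(
            np.full((len(folds_by_target) + 1, 6), 15.0),
            gene_ids=list(folds_by_target) + ["rg"],
        )
        for tgt, fold in folds_by_target.items():
            m.values.loc[tgt, ["BMSC_d1", "BMSC_d2", "BMSC_d3"]] = \
                15.0 - np.log2(fold)
        return delta_delta_ct(m, list(folds_by_target), "rg", "CC")

    def test_no_modulation(self):
        mod = mean_modulation(self._fc({"t1": 1.0, "t2": 1.0}))
        assert mod.loc["BMSC", "mean"] == pytest.approx(1.0)
        assert mod.loc["BMSC", "sd"] == pytest.approx(0.0)

    def test_hand_computed(self):
        mod = mean_modulation(self._fc({"t1": 0.5, "t2": 1.5}))
        assert mod.loc["BMSC", "mean"] == pytest.approx(1.0)
        assert mod.loc["BMSC", "sd"] == pytest.approx(0.7071, abs=1e-4)

    def test_target_order_irrelevant_and_empty_rejected(self):
        fc = self._fc({"t1": 0.5, "t2": 1.5})
        a = mean_modulation(fc, ["t1", "t2"])
        b = mean_modulation(fc, ["t2", "t1"])
        assert a.loc["BMSC", "mean"] == b.loc["BMSC", "mean"]
        with pytest.raises(ValueError, match="at least one"):
            mean_modulation(fc, [])
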
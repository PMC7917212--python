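"""Relative quantification (ΔΔCt) and the impact of reference-gene choice.

Fold changes of target genes are computed per donor against a calibrator
tissue under a chosen reference gene (RG):

    ΔCt   = Cq_target − Cq_RG                (within one sample)
    ΔΔCt  = ΔCt(tissue, donor) − ΔCt(calibrator, donor)
    fold  = efficiency^(−ΔΔCt)               (calibrator ≡ 1)

Donor-matched pairing is enforced: a donor present in only one of the two
tissues being compared is dropped with a warning.  Per target × tissue the
table carries the per-donor folds, their mean and sample SD, a one-sample
Student t-test against 1 (two-sided), and a significance tier using the
cut-offs § p<0.1, * p<0.05, ** p<0.01, *** p<0.001.  A single-pass
two-sided Grubbs outlier screen is available for any value set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CrtMatrix

__all__ = [
    "FoldChangeTable",
    "OutlierReport",
    "TTestResult",
    "delta_delta_ct",
    "one_sample_ttest",
    "grubbs_test",
    "mean_modulation",
    "significance_tier",
]

_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "§"))


def significance_tier(p_value: float) -> str:
    for cut, tier in _TIERS:
        if p_value < cut:
            return tier
    return "ns"


@dataclass
class TTestResult:
    t_stat: float
    p_value: float
    tier: str
    degenerate: bool = False


@dataclass
class OutlierReport:
    """Single-pass two-sided Grubbs test on one value set."""

    g_stat: float
    critical_value: float
    outlier_index: Optional[int]
    alpha: float
    degenerate: bool = False

    @property
    def has_outlier(self) -> bool:
        return self.outlier_index is not None


@dataclass
class FoldChangeTable:
    """Fold ratios per target × non-calibrator tissue under one RG.

    ``table`` rows are (target, tissue); columns: one ``fold_<donor>`` per
    matched donor, ``mean_fold``, ``sd_fold``, ``t_stat``, ``p_value``,
    ``tier``.
    """

    table: pd.DataFrame
    rg_used: str
    calibrator: str
    efficiency: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def folds(self, target: str, tissue: str) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("fold_")]
        return self.table.loc[(target, tissue), cols].to_numpy(float)


def one_sample_ttest(
    values: Sequence[float], mu: float = 1.0, scale: str = "ratio"
) -> TTestResult:
    """Two-sided one-sample Student t-test with Fig-4-style tiers.

    ``scale="ratio"`` tests the raw ratios against ``mu`` (the GraphPad
    convention); ``scale="log2"`` tests log2 ratios against log2(mu).
    """
    x = np.asarray(list(values), float)
    if x.size < 2:
        raise ValueError("one_sample_ttest requires n >= 2 values")
    if scale not in ("ratio", "log2"):
        raise ValueError("scale must be 'ratio' or 'log2'")
    if scale == "log2":
        if np.any(x <= 0) or mu <= 0:
            raise ValueError("log2 scale requires strictly positive values and mu")
        x, mu = np.log2(x), math.log2(mu)
    sd = x.std(ddof=1)
    if sd == 0.0:
        if np.isclose(x.mean(), mu):
            return TTestResult(0.0, 1.0, "ns", degenerate=True)
        t = math.inf if x.mean() > mu else -math.inf
        return TTestResult(t, 0.0, "***", degenerate=True)
    t, p = stats.ttest_1samp(x, popmean=mu)
    return TTestResult(float(t), float(p), significance_tier(float(p)))


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student t quantile."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> OutlierReport:
    """Two-sided single-outlier Grubbs test (G = max |x − mean| / sd)."""
    x = np.asarray(list(values), float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3 values")
    crit = grubbs_critical_value(n, alpha)
    sd = x.std(ddof=1)
    if sd == 0.0:
        return OutlierReport(0.0, crit, None, alpha, degenerate=True)
    dev = np.abs(x - x.mean())
    i = int(dev.argmax())
    g = float(dev[i] / sd)
    return OutlierReport(g, crit, i if g > crit else None, alpha)


def delta_delta_ct(
    m: CrtMatrix,
    targets: Sequence[str],
    rg: str,
    calibrator_tissue: str,
    efficiency: float = 2.0,
    scale: str = "ratio",
) -> FoldChangeTable:
    """ΔΔCt fold changes of ``targets`` versus ``calibrator_tissue``.

    Requires ``donor`` and ``tissue`` metadata with one sample per
    tissue × donor.  The RG may not appear among the targets.
    """
    targets = list(targets)
    if rg in targets:
        raise ValueError("the reference gene cannot be one of the targets")
    for g in [rg, *targets]:
        if g not in m.gene_ids:
            raise KeyError(f"gene {g!r} not in the matrix")
        if not m.detected.loc[g].all():
            raise ValueError(f"gene {g!r} is not detected in every sample")
    tissues = m.meta["tissue"].astype(str)
    donors = m.meta["donor"].astype(str)
    if calibrator_tissue not in set(tissues):
        raise ValueError(f"calibrator tissue {calibrator_tissue!r} not in metadata")

    def sample_of(tissue: str, donor: str) -> Optional[str]:
        hits = m.meta.index[(tissues == tissue) & (donors == donor)]
        if len(hits) > 1:
            raise ValueError(f"multiple samples for tissue {tissue!r}, donor {donor!r}")
        return str(hits[0]) if len(hits) else None

    other_tissues = [t for t in dict.fromkeys(tissues) if t != calibrator_tissue]
    all_donors = list(dict.fromkeys(donors))
    rows = {}
    for tissue in other_tissues:
        matched = []
        for d in all_donors:
            s_t, s_c = sample_of(tissue, d), sample_of(calibrator_tissue, d)
            if s_t is None or s_c is None:
                warnings.warn(
                    f"donor {d!r} lacks a matched sample in "
                    f"{tissue!r}/{calibrator_tissue!r}; dropped"
                )
                continue
            matched.append((d, s_t, s_c))
        if len(matched) < 2:
            raise ValueError(
                f"fewer than 2 matched donors for tissue {tissue!r}"
            )
        for tgt in targets:
            folds = {}
            for d, s_t, s_c in matched:
                dct_t = m.values.loc[tgt, s_t] - m.values.loc[rg, s_t]
                dct_c = m.values.loc[tgt, s_c] - m.values.loc[rg, s_c]
                folds[d] = float(efficiency ** (-(dct_t - dct_c)))
            vals = np.array(list(folds.values()))
            tt = one_sample_ttest(vals, mu=1.0, scale=scale)
            rows[(tgt, tissue)] = {
                **{f"fold_{d}": f for d, f in folds.items()},
                "mean_fold": vals.mean(),
                "sd_fold": vals.std(ddof=1),
                "t_stat": tt.t_stat,
                "p_value": tt.p_value,
                "tier": tt.tier,
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["target", "tissue"])
    return FoldChangeTable(table, rg_used=rg, calibrator=calibrator_tissue,
                           efficiency=efficiency)


def mean_modulation(
    table: FoldChangeTable, targets: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Mean ± sample SD of the targets' mean folds, per tissue.

    This is the summary used to compare the impact of RG choice: how far
    the panel of target genes is modulated, on average, away from the
    calibrator level of 1.
    """
    df = table.table
    if targets is None:
        targets = list(dict.fromkeys(df.index.get_level_values("target")))
    targets = list(targets)
    if not targets:
        raise ValueError("mean_modulation requires at least one target")
    missing = [t for t in targets if t not in set(df.index.get_level_values("target"))]
    if missing:
        raise KeyError(f"target(s) not in the fold-change table: {missing}")
    out = {}
    for tissue in dict.fromkeys(df.index.get_level_values("tissue")):
        vals = np.array(
            [df.loc[(t, tissue), "mean_fold"] for t in targets], float
        )
        out[tissue] = {
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
            "n_targets": vals.size,
            "rg": table.rg_used,
        }
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = "tissue"
    return res
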
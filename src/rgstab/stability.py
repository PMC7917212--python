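"""The four reference-gene stability estimators.

Each algorithm is an sklearn-style estimator fitting on an
``(n_samples, n_genes)`` matrix of Cq (Crt) cycle values:

* :class:`GeNorm` — average pairwise variation M with stepwise exclusion
  of the least stable gene; M_j is the mean over partners k of the SD
  across samples of the log2 expression ratio of genes j and k.
* :class:`NormFinder` — the Andersen variance-decomposition model on the
  log2 scale, with an optional grouped mode combining intragroup variance
  and shrunken intergroup bias.
* :class:`BestKeeper` — raw-Cq descriptive dispersion (MAD or SD), the
  coefficient of variation, and Pearson correlation with the BestKeeper
  index (per-sample geometric mean Cq).
* :class:`ComparativeDeltaCt` — mean over partner genes of the SD of
  pairwise Cq differences.

Lower is more stable for every algorithm.  All estimators expose
``stability_`` (one value per gene, in fit order) and ``ranking_``
(ascending competition ranks, ties at full precision sharing the minimum
rank).  Module-level functions wrap the estimators for the pipeline's
domain objects (:class:`~rgstab.io.CrtMatrix`,
:class:`~rgstab.preprocess.QuantityMatrix`).

With efficiency 2 the comparative ΔCt values coincide exactly with
first-iteration geNorm M, since SD(log2(q_g/q_h)) = SD(Cq_h − Cq_g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CrtMatrix
from .preprocess import QuantityMatrix

__all__ = [
    "GeNorm",
    "NormFinder",
    "BestKeeper",
    "ComparativeDeltaCt",
    "GenormResult",
    "NormfinderResult",
    "BestkeeperResult",
    "DeltaCtResult",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_ct_stability",
]


def _competition_ranks(values: np.ndarray) -> np.ndarray:
    """Ascending competition ("1,1,3") ranks; exact-value ties share rank."""
    v = np.asarray(values, float)
    return (v[:, None] > v[None, :]).sum(axis=1) + 1


def _validate_cq(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(float)
    else:
        arr = np.asarray(X, float)
        names = [f"g{i}" for i in range(arr.shape[1])] if arr.ndim == 2 else []
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x genes matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError("stability estimators require a complete finite matrix")
    return arr, names


class GeNorm(BaseEstimator):
    """geNorm stability with stepwise exclusion.

    Parameters
    ----------
    efficiency : amplification efficiency (fold per cycle); log2 ratios of
        quantities are ``log2(efficiency) * ΔCq``, so 2.0 gives the classic
        cycle-scale M values.
    compute_pairwise_v : also compute the V_n/n+1 pairwise-variation trace
        of normalization factors built from the top n vs n+1 genes.

    Attributes (after fit)
    ----------------------
    stability_ : M value of each gene at the step of its exclusion; the
        two last-surviving genes share the final M.
    exclusion_order_ : removal sequence, 1 = first removed (least stable);
        the final pair takes the last two positions in gene-id order.
    ranking_ : competition ranks, final pair tied at rank 1.
    final_pair_ : the two last-surviving gene ids.
    pairwise_v_ : optional array of V_n/n+1 for n = 2..G-1.
    """

    def __init__(self, efficiency: float = 2.0, compute_pairwise_v: bool = False):
        self.efficiency = efficiency
        self.compute_pairwise_v = compute_pairwise_v

    def fit(self, X, y=None):
        arr, names = _validate_cq(X)
        n, g = arr.shape
        if g < 3:
            raise ValueError("geNorm requires at least 3 genes")
        if n < 2:
            raise ValueError("geNorm requires at least 2 samples")
        scale = np.log2(self.efficiency)
        # log2 quantities up to per-gene constants (which cancel in ratios)
        logq = -arr * scale
        # V[j, k] = SD over samples of log2(q_j / q_k)
        pairwise = logq[:, :, None] - logq[:, None, :]
        vmat = pairwise.std(axis=0, ddof=1)

        active = list(range(g))
        reported = np.full(g, np.nan)
        excl = np.zeros(g, dtype=int)
        step = 0
        while len(active) > 2:
            sub = vmat[np.ix_(active, active)]
            m = sub.sum(axis=1) / (len(active) - 1)
            worst_m = m.max()
            tied = [active[i] for i in range(len(active)) if m[i] == worst_m]
            # deterministic tie-break: drop the lexicographically last id
            drop = max(tied, key=lambda i: names[i])
            step += 1
            reported[drop] = m[active.index(drop)]
            excl[drop] = step
            active.remove(drop)
        final_m = vmat[active[0], active[1]]
        pair = sorted(active, key=lambda i: names[i])
        reported[pair[0]] = final_m
        reported[pair[1]] = final_m
        excl[pair[0]] = g - 1
        excl[pair[1]] = g
        ranks = g + 1 - excl
        ranks[pair[0]] = 1
        ranks[pair[1]] = 1

        self.n_features_in_ = g
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.pairwise_variation_matrix_ = vmat
        self.stability_ = reported
        self.exclusion_order_ = excl
        self.ranking_ = ranks
        self.final_pair_ = (names[pair[0]], names[pair[1]])
        self.pairwise_v_ = (
            self._v_trace(logq, np.argsort(excl)[::-1]) if self.compute_pairwise_v else None
        )
        return self

    @staticmethod
    def _v_trace(logq: np.ndarray, stability_order: np.ndarray) -> np.ndarray:
        """V_n/n+1 between normalization factors of the top n and n+1 genes."""
        g = logq.shape[1]
        out = []
        for nn in range(2, g):
            top_n = stability_order[:nn]
            top_n1 = stability_order[: nn + 1]
            nf_n = logq[:, top_n].mean(axis=1)
            nf_n1 = logq[:, top_n1].mean(axis=1)
            out.append(np.std(nf_n - nf_n1, ddof=1))
        return np.asarray(out)


class NormFinder(BaseEstimator):
    """NormFinder model-based stability on the log2 scale.

    Data are per-sample gene-mean centered.  Ungrouped mode estimates the
    per-gene variance with the bias correction
    ``max(0, (s² − T/(G(G−1))) · G/(G−2))`` and reports its square root.
    Grouped mode (group labels passed as ``y`` to :meth:`fit`) applies the
    same correction within each group, estimates the intergroup bias d of
    each gene, shrinks it toward 0 by the empirical-Bayes factor
    ``γ²/(γ² + σ²/n)``, and reports ``mean over groups of
    (|d̃| + sqrt(σ²/n))``.

    Parameters
    ----------
    input_scale : ``"cq"`` (Cq cycles, negated internally so that larger
        means more expressed) or ``"log2"`` (already log2 expression).
    efficiency : fold per cycle used when ``input_scale="cq"``.
    """

    def __init__(self, input_scale: str = "cq", efficiency: float = 2.0):
        self.input_scale = input_scale
        self.efficiency = efficiency

    def fit(self, X, y=None):
        if self.input_scale not in ("cq", "log2"):
            raise ValueError("input_scale must be 'cq' or 'log2'")
        arr, names = _validate_cq(X)
        n, g = arr.shape
        if g < 3:
            raise ValueError("NormFinder requires at least 3 genes")
        logq = -arr * np.log2(self.efficiency) if self.input_scale == "cq" else arr
        z = logq - logq.mean(axis=1, keepdims=True)

        self.n_features_in_ = g
        self.feature_names_in_ = np.asarray(names, dtype=object)

        if y is None:
            var = self._corrected_var(z)
            self.mode_ = "ungrouped"
            self.groups_ = None
            self.intragroup_variance_ = var
            self.intergroup_d_ = None
            self.intergroup_d_shrunk_ = None
            self.stability_ = np.sqrt(var)
        else:
            groups = np.asarray(y)
            if len(groups) != n:
                raise ValueError("group labels must match the number of samples")
            labels = list(dict.fromkeys(groups.tolist()))
            if len(labels) < 2:
                raise ValueError("grouped NormFinder requires >= 2 groups")
            sizes = {lab: int((groups == lab).sum()) for lab in labels}
            single = [lab for lab, c in sizes.items() if c < 2]
            if single:
                raise ValueError(f"group(s) with fewer than 2 samples: {single}")
            m = len(labels)
            var_gi = np.empty((g, m))
            d_hat = np.empty((g, m))
            ni = np.array([sizes[lab] for lab in labels], float)
            overall = z.mean(axis=0)
            for i, lab in enumerate(labels):
                zi = z[groups == lab]
                var_gi[:, i] = self._corrected_var(zi)
                d_hat[:, i] = zi.mean(axis=0) - overall
            sampling = var_gi / ni[None, :]
            gamma2 = max(
                0.0,
                float((d_hat**2).sum() / ((g - 1) * (m - 1)) - sampling.mean()),
            )
            with np.errstate(invalid="ignore"):
                shrink = np.where(
                    gamma2 + sampling > 0, gamma2 / (gamma2 + sampling), 0.0
                )
            d_tilde = d_hat * shrink
            self.mode_ = "grouped"
            self.groups_ = labels
            self.intragroup_variance_ = var_gi
            self.intergroup_d_ = d_hat
            self.intergroup_d_shrunk_ = d_tilde
            self.gamma2_ = gamma2
            self.stability_ = (np.abs(d_tilde) + np.sqrt(sampling)).mean(axis=1)

        self.ranking_ = _competition_ranks(self.stability_)
        return self

    @staticmethod
    def _corrected_var(z: np.ndarray) -> np.ndarray:
        """Per-gene variance of centered data, corrected for the centering."""
        g = z.shape[1]
        s2 = z.var(axis=0, ddof=1)
        t = s2.sum()
        return np.maximum(0.0, (s2 - t / (g * (g - 1))) * g / (g - 2))


class BestKeeper(BaseEstimator):
    """BestKeeper descriptive stability on raw Cq values.

    Per gene: ``sd_cp_`` is the mean absolute deviation around the
    arithmetic mean Cq (``dispersion="mad"``, the BestKeeper tool
    convention) or the sample SD (``dispersion="sd"``); ``cv_pct_`` is
    100·sd_cp/mean; ``r_index_`` is the Pearson correlation with the
    BestKeeper index (per-sample geometric mean Cq over genes), NaN for a
    zero-variance gene.  Genes are ranked by ``sd_cp_`` ascending.  The
    original tool's "SD > 1 cycle" exclusion screen is only flagged
    (``high_sd_flag_``), never applied.
    """

    def __init__(self, dispersion: str = "mad"):
        self.dispersion = dispersion

    def fit(self, X, y=None):
        if self.dispersion not in ("mad", "sd"):
            raise ValueError("dispersion must be 'mad' or 'sd'")
        arr, names = _validate_cq(X)
        n, g = arr.shape
        mean = arr.mean(axis=0)
        if self.dispersion == "mad":
            sd_cp = np.abs(arr - mean).mean(axis=0)
        else:
            sd_cp = arr.std(axis=0, ddof=1)
        cv = 100.0 * sd_cp / mean
        # geometric mean Cq per sample (Cq > 0 by contract)
        index = np.exp(np.log(arr).mean(axis=1))
        r = np.full(g, np.nan)
        if n >= 3:
            idx_c = index - index.mean()
            denom_idx = np.sqrt((idx_c**2).sum())
            for j in range(g):
                xc = arr[:, j] - mean[j]
                denom = np.sqrt((xc**2).sum()) * denom_idx
                if denom > 0:
                    r[j] = float((xc * idx_c).sum() / denom)
        self.n_features_in_ = g
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.stability_ = sd_cp
        self.sd_cp_ = sd_cp
        self.cv_pct_ = cv
        self.r_index_ = r
        self.index_ = index
        self.high_sd_flag_ = arr.std(axis=0, ddof=1) > 1.0
        self.ranking_ = _competition_ranks(sd_cp)
        return self


class ComparativeDeltaCt(BaseEstimator):
    """Comparative ΔCt stability: mean over partners of pairwise-ΔCq SD."""

    def fit(self, X, y=None):
        arr, names = _validate_cq(X)
        n, g = arr.shape
        if g < 2:
            raise ValueError("comparative ΔCt requires at least 2 genes")
        if n < 2:
            raise ValueError("comparative ΔCt requires at least 2 samples")
        diffs = arr[:, :, None] - arr[:, None, :]
        sd = diffs.std(axis=0, ddof=1)
        self.n_features_in_ = g
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.pair_sd_ = sd
        self.stability_ = sd.sum(axis=1) / (g - 1)
        self.ranking_ = _competition_ranks(self.stability_)
        return self


# ---------------------------------------------------------------------------
# result containers + functional wrappers over the domain objects
# ---------------------------------------------------------------------------


def _series(values, genes, name) -> pd.Series:
    return pd.Series(np.asarray(values), index=list(genes), name=name)


@dataclass
class GenormResult:
    reported_m: pd.Series
    exclusion_order: pd.Series
    ranking: pd.Series
    final_pair: tuple[str, str]
    pairwise_v: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "M": self.reported_m,
                "exclusion_order": self.exclusion_order,
                "rank": self.ranking,
            }
        )
        df.index.name = "gene"
        return df.sort_values("rank")


@dataclass
class NormfinderResult:
    stability: pd.Series
    ranking: pd.Series
    mode: str
    intragroup_variance: pd.DataFrame
    intergroup_d: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"stability": self.stability, "rank": self.ranking})
        df.index.name = "gene"
        return df.sort_values("rank")


@dataclass
class BestkeeperResult:
    sd_cp: pd.Series
    cv_pct: pd.Series
    r_index: pd.Series
    index: pd.Series
    ranking: pd.Series
    high_sd_flag: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sd_cp": self.sd_cp,
                "cv_pct": self.cv_pct,
                "r_index": self.r_index,
                "sd_above_1_cycle": self.high_sd_flag,
                "rank": self.ranking,
            }
        )
        df.index.name = "gene"
        return df.sort_values("rank")


@dataclass
class DeltaCtResult:
    mean_pair_sd: pd.Series
    ranking: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mean_pair_sd": self.mean_pair_sd, "rank": self.ranking})
        df.index.name = "gene"
        return df.sort_values("rank")


def _complete_cq(m: CrtMatrix) -> pd.DataFrame:
    genes = m.candidate_genes()
    det = m.detected.loc[genes]
    if not bool(det.all(axis=None)):
        bad = sorted(set(det.index[~det.all(axis=1)]))
        raise ValueError(
            f"stability requires genes detected in all samples; offending: {bad}"
        )
    return m.values.loc[genes].T  # samples x genes


def genorm(q: QuantityMatrix, compute_pairwise_v: bool = False) -> GenormResult:
    """geNorm on a quantity matrix (genes x samples, per-gene max = 1)."""
    logq = np.log2(q.q.to_numpy(float))
    X = pd.DataFrame(-logq.T, columns=q.gene_ids)  # back to a Cq-like scale
    est = GeNorm(efficiency=2.0, compute_pairwise_v=compute_pairwise_v).fit(X)
    genes = q.gene_ids
    return GenormResult(
        _series(est.stability_, genes, "M"),
        _series(est.exclusion_order_, genes, "exclusion_order"),
        _series(est.ranking_, genes, "rank"),
        est.final_pair_,
        est.pairwise_v_,
    )


def normfinder(
    logq: pd.DataFrame, groups: Optional[Sequence] = None
) -> NormfinderResult:
    """NormFinder on a genes x samples log2-expression matrix."""
    est = NormFinder(input_scale="log2").fit(
        logq.T, None if groups is None else np.asarray(list(groups))
    )
    genes = list(logq.index)
    if est.mode_ == "grouped":
        intra = pd.DataFrame(est.intragroup_variance_, index=genes, columns=est.groups_)
        inter = pd.DataFrame(est.intergroup_d_, index=genes, columns=est.groups_)
    else:
        intra = pd.DataFrame({"all": est.intragroup_variance_}, index=genes)
        inter = None
    return NormfinderResult(
        _series(est.stability_, genes, "stability"),
        _series(est.ranking_, genes, "rank"),
        est.mode_,
        intra,
        inter,
    )


def bestkeeper(m: CrtMatrix, dispersion: str = "mad") -> BestkeeperResult:
    """BestKeeper on the raw Cq values of a CrtMatrix."""
    X = _complete_cq(m)
    est = BestKeeper(dispersion=dispersion).fit(X)
    genes = list(X.columns)
    return BestkeeperResult(
        _series(est.sd_cp_, genes, "sd_cp"),
        _series(est.cv_pct_, genes, "cv_pct"),
        _series(est.r_index_, genes, "r_index"),
        pd.Series(est.index_, index=list(X.index), name="bestkeeper_index"),
        _series(est.ranking_, genes, "rank"),
        _series(est.high_sd_flag_, genes, "sd_above_1_cycle"),
    )


def delta_ct_stability(m: CrtMatrix) -> DeltaCtResult:
    """Comparative ΔCt method on the Cq values of a CrtMatrix."""
    X = _complete_cq(m)
    est = ComparativeDeltaCt().fit(X)
    genes = list(X.columns)
    return DeltaCtResult(
        _series(est.stability_, genes, "mean_pair_sd"),
        _series(est.ranking_, genes, "rank"),
    )
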
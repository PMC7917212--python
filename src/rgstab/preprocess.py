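"""Preprocessing of Cq matrices ahead of stability analysis.

Four steps are provided, mirroring the standard OpenArray qPCR workflow:

1. a detection filter (mask wells with Crt above a cycle threshold or an
   amplification score below a quality threshold),
2. spike-in equalization (remove per-sample technical offsets estimated
   from an exogenous spiked miRNA, e.g. ath-miR-159a),
3. global-mean centering (equalize subtle differences in starting RNA by
   centering every sample on the panel mean),
4. conversion of Crt to linear-scale relative quantities
   q = E^(Crt_min - Crt), the convention used by geNorm.

Steps 2 and 3 add per-sample constants on the Crt scale.  Every stability
measure built from within-sample differences (geNorm, the comparative ΔCt
method) is exactly invariant under them; they matter for measures of raw
dispersion such as BestKeeper's SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CrtMatrix

__all__ = [
    "PreprocessConfig",
    "QuantityMatrix",
    "apply_detection_filter",
    "spike_in_equalize",
    "global_mean_center",
    "to_quantities",
    "dynamic_range",
]


@dataclass
class PreprocessConfig:
    """Thresholds and conventions for preprocessing.

    crt_threshold : cycles; wells with Crt strictly above it are "not
        present" (OpenArray manufacturer default 27).
    amp_score_threshold : unitless amplification-quality score; wells
        strictly below it are "not present" (default 1.24).
    filter_logic : ``either`` masks a well failing either rule (common
        practice); ``both`` masks only wells failing both.
    efficiency : amplification efficiency as fold-change per cycle
        (2.0 = perfect doubling).
    spike_gene : optional spike-in gene id, exempt from the filter.
    """

    crt_threshold: float = 27.0
    amp_score_threshold: float = 1.24
    filter_logic: str = "either"
    efficiency: float = 2.0
    spike_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.crt_threshold <= 0:
            raise ValueError("crt_threshold must be > 0")
        if self.efficiency <= 1:
            raise ValueError("efficiency must be > 1")
        if self.filter_logic not in ("either", "both"):
            raise ValueError("filter_logic must be 'either' or 'both'")


@dataclass
class QuantityMatrix:
    """Linear-scale relative quantities, genes x samples, per-gene max = 1."""

    q: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.q.to_numpy(float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("quantities must be finite and > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)


def apply_detection_filter(
    m: CrtMatrix,
    amp_scores: Optional[pd.DataFrame] = None,
    cfg: Optional[PreprocessConfig] = None,
) -> CrtMatrix:
    """Mask wells failing the presence rule; values are kept, flags change.

    A well fails the Crt rule when Crt > ``crt_threshold`` and the score
    rule when amp score < ``amp_score_threshold``.  Under
    ``filter_logic='either'`` one failure masks the well; under ``'both'``
    only a joint failure does (in which case a well with no amp score is
    never masked by the Crt rule alone).  The spike row is never masked.
    """
    cfg = cfg or PreprocessConfig()
    out = m.copy()
    vals = out.values.to_numpy(float)
    high_crt = np.where(np.isnan(vals), False, vals > cfg.crt_threshold)
    if amp_scores is not None:
        if amp_scores.shape != out.values.shape:
            raise ValueError(
                f"amp_scores shape {amp_scores.shape} does not match "
                f"matrix shape {out.values.shape}"
            )
        sc = amp_scores.to_numpy(float)
        low_score = np.where(np.isnan(sc), False, sc < cfg.amp_score_threshold)
    else:
        low_score = np.zeros_like(high_crt, dtype=bool)
    if cfg.filter_logic == "either":
        fail = high_crt | low_score
    else:
        fail = high_crt & low_score if amp_scores is not None else high_crt
    mask = pd.DataFrame(fail, index=out.values.index, columns=out.values.columns)
    spike = cfg.spike_gene or out.spike_gene
    if spike is not None and spike in mask.index:
        mask.loc[spike] = False
    out.detected &= ~mask
    return out


def spike_in_equalize(m: CrtMatrix) -> CrtMatrix:
    """Remove per-sample technical offsets using the spike-in row.

    For each sample s the offset is spike_Crt_s minus the mean spike Crt
    over samples; every Crt in sample s (spike included) is decremented by
    it, so the returned spike row is constant and keeps its original mean.
    """
    if m.spike_gene is None:
        raise ValueError("spike_in_equalize requires a spike_gene")
    spike_det = m.detected.loc[m.spike_gene]
    if not spike_det.all():
        missing = [s for s in m.sample_ids if not spike_det[s]]
        raise ValueError(f"spike-in not detected in sample(s): {missing}")
    spike = m.values.loc[m.spike_gene]
    offsets = spike - spike.mean()
    out = m.copy()
    out.values = out.values.sub(offsets, axis=1)
    return out


def global_mean_center(
    m: CrtMatrix, gene_subset: Optional[Sequence[str]] = None
) -> CrtMatrix:
    """Equalize starting-RNA differences by centering sample panel means.

    Each sample is shifted so that its mean Crt over ``gene_subset``
    (default: all non-spike genes detected in every sample) equals the
    grand mean of the subset; the grand mean itself is preserved.
    """
    if gene_subset is None:
        gene_subset = m.fully_detected_genes()
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise ValueError("global_mean_center: empty usable gene subset")
    sub = m.values.loc[gene_subset]
    sample_means = sub.mean(axis=0)
    grand = float(sub.to_numpy().mean())
    out = m.copy()
    out.values = out.values.add(grand - sample_means, axis=1)
    return out


def to_quantities(m: CrtMatrix, cfg: Optional[PreprocessConfig] = None) -> QuantityMatrix:
    """Convert Crt to relative linear quantities q = E^(min Crt - Crt).

    Per gene the most expressed sample gets q = 1 (the geNorm convention);
    every retained gene must be detected in every sample.
    """
    cfg = cfg or PreprocessConfig()
    genes = m.candidate_genes()
    det = m.detected.loc[genes]
    if not det.all(axis=None):
        bad = [
            (g, s)
            for g in genes
            for s in m.sample_ids
            if not det.loc[g, s]
        ]
        raise ValueError(
            f"undetected cells among retained genes (drop them first): {bad[:10]}"
        )
    crt = m.values.loc[genes]
    q = np.power(cfg.efficiency, crt.min(axis=1).to_numpy()[:, None] - crt.to_numpy())
    return QuantityMatrix(
        pd.DataFrame(q, index=genes, columns=m.sample_ids), m.meta.copy()
    )


def dynamic_range(
    m: CrtMatrix, efficiency: float = 2.0
) -> tuple[float, tuple[str, str], tuple[str, str]]:
    """Fold difference spanned by detected non-spike wells.

    Returns ``(fold, (gene, sample) of the min-Crt well, (gene, sample) of
    the max-Crt well)`` where fold = efficiency^(max Crt - min Crt).
    """
    genes = m.candidate_genes()
    vals = m.values.loc[genes].where(m.detected.loc[genes])
    arr = vals.to_numpy(float)
    if not np.isfinite(arr).any():
        raise ValueError("dynamic_range: no detected values")
    imin = np.unravel_index(np.nanargmin(arr), arr.shape)
    imax = np.unravel_index(np.nanargmax(arr), arr.shape)
    lo_cell = (genes[imin[0]], m.sample_ids[imin[1]])
    hi_cell = (genes[imax[0]], m.sample_ids[imax[1]])
    fold = float(efficiency ** (arr[imax] - arr[imin]))
    return fold, lo_cell, hi_cell
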
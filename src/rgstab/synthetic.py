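"""Synthetic Cq-matrix generator with known ground-truth stability.

The generator emulates a donor-matched qPCR study design: one sample per
tissue × donor, an additive model on the Cq (log2) scale

    Cq[g, (t, d)] = baseline_g + tissue_effect[g, t] + donor_effect_d
                    + sample_offset_(t,d) + ε,    ε ~ N(0, noise_sd_g)

plus an exogenous spike-in row carrying only the per-sample technical
offset (``spike_crt + sample_offset``), and detection dropout for wells
whose generated Cq exceeds a threshold.  Because every sample-level term
(donor effect, technical offset) is shared by all genes, the designed
stability of a gene is fully described by the variance of its tissue
effects plus its noise variance; :func:`ground_truth_ranking` orders genes
by that quantity.

:func:`default_study_spec` mirrors the motivating study design: 12
candidate reference miRNAs and 4 target miRNAs measured in 3 donor-matched
tissue sources (CC, BMSC, ASC), with one designed-stable candidate (no
effects, minimal noise) and one designed-unstable candidate carrying a
1-cycle tissue effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CrtMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "ground_truth_ranking",
    "default_study_spec",
]


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic study.

    gene_ids : all assayed genes, candidates first (spike excluded).
    baseline_crt : per-gene baseline cycles; ``None`` draws them uniformly
        in [9, 23], the span observed for abundant EV miRNAs.
    tissue_effect : genes x tissues cycle shifts (rows of designed-stable
        genes are all zero); ``None`` means no tissue effects.
    noise_sd : per-gene Gaussian noise SD in cycles (scalar broadcast).
    sample_offset_sd : SD of the per-sample technical offset (cycles).
    donor_effect_sd : SD of the per-donor shift shared by all genes.
    target_genes : genes quantified downstream but excluded from the
        reference-gene candidate panel.
    """

    gene_ids: Sequence[str]
    tissues: Sequence[str] = ("CC", "BMSC", "ASC")
    donors: Sequence[str] = ("D1", "D2", "D3")
    baseline_crt: Optional[Sequence[float]] = None
    baseline_range: tuple[float, float] = (9.0, 23.0)
    sample_offset_sd: float = 0.5
    tissue_effect: Optional[pd.DataFrame] = None
    donor_effect_sd: float = 0.2
    noise_sd: float | Sequence[float] = 0.3
    target_genes: Sequence[str] = ()
    spike_gene: str = "ath-miR-159a"
    spike_crt: float = 15.0
    dropout_crt: float = 27.0
    seed: int = 1

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if not self.gene_ids or not list(self.tissues) or not list(self.donors):
            raise ValueError("genes, tissues and donors must be non-empty")
        if np.any(np.asarray(self.noise_sd_per_gene()) < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.spike_gene in self.gene_ids:
            raise ValueError("spike gene is generated separately; omit it from gene_ids")
        unknown = set(self.target_genes) - set(self.gene_ids)
        if unknown:
            raise ValueError(f"target gene(s) not in gene_ids: {sorted(unknown)}")
        eff = self.tissue_effect_frame()
        if list(eff.index) != self.gene_ids or list(eff.columns) != list(self.tissues):
            raise ValueError("tissue_effect must be indexed by gene_ids x tissues")

    def noise_sd_per_gene(self) -> np.ndarray:
        arr = np.asarray(self.noise_sd, float)
        if arr.ndim == 0:
            return np.full(len(self.gene_ids), float(arr))
        if arr.shape != (len(self.gene_ids),):
            raise ValueError("noise_sd must be scalar or one value per gene")
        return arr

    def tissue_effect_frame(self) -> pd.DataFrame:
        if self.tissue_effect is None:
            return pd.DataFrame(
                0.0, index=list(self.gene_ids), columns=list(self.tissues)
            )
        return self.tissue_effect.reindex(
            index=list(self.gene_ids), columns=list(self.tissues)
        ).fillna(0.0)

    @property
    def candidate_genes(self) -> list[str]:
        return [g for g in self.gene_ids if g not in set(self.target_genes)]


@dataclass
class GroundTruth:
    """What was actually drawn, and the designed stability ordering."""

    designed_stability_order: list[str]
    designed_variance: pd.Series          # cycles^2, per candidate gene
    baseline_crt: pd.Series
    tissue_effect: pd.DataFrame
    donor_effect: pd.Series
    sample_offset: pd.Series
    noise_sd: pd.Series


def ground_truth_ranking(spec: SyntheticSpec) -> list[str]:
    """Candidate genes ordered most to least stable by design.

    The key is the population variance of a gene's tissue effects across
    tissues plus its noise variance (sample-level terms are shared by all
    genes and carry no between-gene information); ties break
    lexicographically.
    """
    eff = spec.tissue_effect_frame()
    noise = pd.Series(spec.noise_sd_per_gene(), index=spec.gene_ids)
    total = eff.var(axis=1, ddof=0) + noise**2
    cands = spec.candidate_genes
    return sorted(cands, key=lambda g: (total[g], g))


def generate(
    spec: SyntheticSpec, seed: Optional[int] = None
) -> tuple[CrtMatrix, GroundTruth]:
    """Draw one synthetic CrtMatrix (identical seed, identical output)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = list(spec.gene_ids)
    tissues, donors = list(spec.tissues), list(spec.donors)
    sample_ids = [f"{t}_{d}" for t in tissues for d in donors]

    if spec.baseline_crt is None:
        lo, hi = spec.baseline_range
        baseline = rng.uniform(lo, hi, size=len(genes))
    else:
        baseline = np.asarray(list(spec.baseline_crt), float)
        if baseline.shape != (len(genes),):
            raise ValueError("baseline_crt must have one value per gene")
    donor_eff = rng.normal(0.0, spec.donor_effect_sd, size=len(donors))
    offsets = rng.normal(0.0, spec.sample_offset_sd, size=len(sample_ids))
    noise_sd = spec.noise_sd_per_gene()
    eps = rng.normal(0.0, 1.0, size=(len(genes), len(sample_ids))) * noise_sd[:, None]

    eff = spec.tissue_effect_frame()
    vals = np.empty((len(genes), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        t, d = sid.split("_", 1)
        vals[:, j] = (
            baseline
            + eff[t].to_numpy()
            + donor_eff[donors.index(d)]
            + offsets[j]
            + eps[:, j]
        )
    spike_row = spec.spike_crt + offsets

    values = pd.DataFrame(
        np.vstack([vals, spike_row]),
        index=genes + [spec.spike_gene],
        columns=sample_ids,
    )
    detected = values <= spec.dropout_crt
    detected.loc[spec.spike_gene] = True
    meta = pd.DataFrame(
        {
            "donor": [s.split("_", 1)[1] for s in sample_ids],
            "tissue": [s.split("_", 1)[0] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = CrtMatrix(values, meta, detected, spike_gene=spec.spike_gene)

    noise = pd.Series(noise_sd, index=genes, name="noise_sd")
    truth = GroundTruth(
        designed_stability_order=ground_truth_ranking(spec),
        designed_variance=(eff.var(axis=1, ddof=0) + noise**2)[spec.candidate_genes],
        baseline_crt=pd.Series(baseline, index=genes, name="baseline_crt"),
        tissue_effect=eff,
        donor_effect=pd.Series(donor_eff, index=donors, name="donor_effect"),
        sample_offset=pd.Series(offsets, index=sample_ids, name="sample_offset"),
        noise_sd=noise,
    )
    return matrix, truth


def default_study_spec(seed: int = 1) -> SyntheticSpec:
    """The default donor-matched panel: 12 candidates, 4 targets, 1 spike.

    cand01 is the designed-stable gene (no effects, 0.05-cycle noise);
    cand02..cand11 form a noise ladder from 0.30 to 0.75 cycles, the range
    of per-gene Cq dispersions typical of candidate reference panels in EV
    miRNA profiling; cand12 is the designed-unstable gene (0.50-cycle
    noise plus a 1-cycle tissue effect, opposite signs in the two MSC-like
    tissues).  The ladder starts well above the panel's effective noise
    floor: with 16 assayed genes, global-mean centering leaves every gene
    a shared residual of about 0.12 cycles, below which per-gene noise
    differences are undetectable at n = 9.  Targets carry 0.10-cycle noise
    and no tissue effect, so any fold deviation from 1 seen downstream is
    attributable to the reference gene used.
    """
    cands = [f"cand{i:02d}" for i in range(1, 13)]
    tgts = [f"tgt{i}" for i in range(1, 5)]
    genes = cands + tgts
    noise = [0.05, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.50]
    noise += [0.10] * 4
    eff = pd.DataFrame(0.0, index=genes, columns=["CC", "BMSC", "ASC"])
    eff.loc["cand12"] = [0.0, 1.0, -1.0]
    return SyntheticSpec(
        gene_ids=genes,
        tissue_effect=eff,
        noise_sd=noise,
        target_genes=tgts,
        seed=seed,
    )


def rg_impact_spec(seed: int = 1) -> SyntheticSpec:
    """Scenario isolating the impact of reference-gene choice on ΔΔCt.

    Four target genes carry no tissue effect (true fold = 1 everywhere);
    ``rg-stable`` is an ideal normalizer (no effect, 0.05-cycle noise);
    ``rg-unstable`` carries a 1-cycle tissue effect with ordinary
    technical noise, so normalizing by it shifts every target's apparent
    fold by a factor of about 2.  Filler candidates keep the panel size
    realistic for the global-mean step.
    """
    genes = ["rg-stable", "rg-unstable", "fill1", "fill2", "fill3", "fill4"]
    tgts = [f"tgt{i}" for i in range(1, 5)]
    genes += tgts
    noise = [0.05, 0.10, 0.30, 0.35, 0.40, 0.45] + [0.10] * 4
    eff = pd.DataFrame(0.0, index=genes, columns=["CC", "BMSC", "ASC"])
    eff.loc["rg-unstable"] = [0.0, 1.0, -1.0]
    return SyntheticSpec(
        gene_ids=genes,
        tissue_effect=eff,
        noise_sd=noise,
        target_genes=tgts,
        seed=seed,
    )
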
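"""End-to-end orchestration: preprocess → stability → consensus → relquant.

:func:`run_stability_analysis` is the core composition used both by the
command-line interface and programmatically: it filters and normalizes a
Cq matrix, runs the requested stability algorithms on the candidate
panel, and aggregates their rankings into the geomean consensus.
:func:`run_pipeline` adds artifact persistence and a reproducibility
manifest around it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .consensus import ConsensusRanking, rank_stability_values
from .io import CrtMatrix, read_amp_scores, read_crt_table, write_crt_matrix, \
    write_json_report, write_table
from .preprocess import PreprocessConfig, apply_detection_filter, \
    global_mean_center, spike_in_equalize, to_quantities
from .relquant import delta_delta_ct, mean_modulation
from .multivariate import hier_cluster, pca_clustvis
from .stability import bestkeeper, delta_ct_stability, genorm, normfinder

log = logging.getLogger("rgstab")

ALL_ALGORITHMS = ("deltact", "bestkeeper", "normfinder", "genorm")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_path: Optional[str] = None
    meta_path: Optional[str] = None
    amp_path: Optional[str] = None
    out_dir: str = "rgstab_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    algorithms: Sequence[str] = ALL_ALGORITHMS
    group_by: str = "tissue"        # none | tissue | donor
    bestkeeper_dispersion: str = "mad"
    spike_gene: Optional[str] = None
    exclude_genes: Sequence[str] = ()   # e.g. downstream target genes
    targets: Sequence[str] = ()
    rg: Optional[str] = None
    calibrator_tissue: Optional[str] = None
    ttest_scale: str = "ratio"
    seed: int = 1
    verbosity: str = "info"

    def validate(self, m: CrtMatrix) -> None:
        for g in [*self.targets, *(() if self.rg is None else (self.rg,))]:
            if g not in m.gene_ids:
                raise ValueError(f"configured gene {g!r} not in the input matrix")
        if self.calibrator_tissue is not None:
            tissues = set(m.meta.get("tissue", pd.Series(dtype=str)).astype(str))
            if self.calibrator_tissue not in tissues:
                raise ValueError(
                    f"calibrator tissue {self.calibrator_tissue!r} not in metadata"
                )
        bad = set(self.algorithms) - set(ALL_ALGORITHMS)
        if bad:
            raise ValueError(f"unknown algorithm(s): {sorted(bad)}")
        if self.group_by not in ("none", "tissue", "donor"):
            raise ValueError("group_by must be none, tissue or donor")


def preprocess_matrix(
    m: CrtMatrix,
    cfg: PreprocessConfig,
    amp_scores: Optional[pd.DataFrame] = None,
    exclude_genes: Sequence[str] = (),
) -> tuple[CrtMatrix, list[str]]:
    """Filter, equalize and center; return the matrix and the usable panel.

    Genes not detected in every sample after the filter are excluded from
    the stability panel (never imputed) and logged, as are configured
    exclusions such as downstream target genes.
    """
    filtered = apply_detection_filter(m, amp_scores, cfg)
    if filtered.spike_gene is not None:
        filtered = spike_in_equalize(filtered)
        log.info("spike-in equalization applied (gene %s)", filtered.spike_gene)
    usable = filtered.fully_detected_genes()
    dropped = [g for g in filtered.candidate_genes() if g not in usable]
    if dropped:
        log.info("excluded from stability (not detected everywhere): %s", dropped)
    panel = [g for g in usable if g not in set(exclude_genes)]
    if not panel:
        raise ValueError("no usable genes after filtering")
    centered = global_mean_center(filtered, gene_subset=usable)
    return centered, panel


def run_stability_analysis(
    m: CrtMatrix,
    panel: Optional[Sequence[str]] = None,
    algorithms: Sequence[str] = ALL_ALGORITHMS,
    group_by: str = "none",
    bestkeeper_dispersion: str = "mad",
    efficiency: float = 2.0,
) -> tuple[ConsensusRanking, dict]:
    """Run the chosen algorithms on the candidate panel and aggregate.

    ``group_by`` selects NormFinder's grouping factor (a metadata column,
    or ``"none"`` for the ungrouped estimator).  geNorm's final tied pair
    is carried into the consensus as a forced rank-1 tie.
    """
    if panel is None:
        panel = m.fully_detected_genes()
    sub = m.subset(genes=list(panel) + ([m.spike_gene] if m.spike_gene else []))
    values: dict[str, dict[str, float]] = {}
    tied: dict[str, list] = {}
    results: dict[str, object] = {}
    for alg in algorithms:
        if alg == "deltact":
            res = delta_ct_stability(sub)
            values["deltact"] = res.mean_pair_sd.to_dict()
        elif alg == "bestkeeper":
            res = bestkeeper(sub, dispersion=bestkeeper_dispersion)
            log.info("BestKeeper dispersion = %s", bestkeeper_dispersion)
            values["bestkeeper"] = res.sd_cp.to_dict()
        elif alg == "normfinder":
            logq = -np.log2(efficiency) * sub.values.loc[list(panel)]
            groups = (
                None if group_by == "none" else sub.meta[group_by].astype(str).tolist()
            )
            res = normfinder(logq, groups)
            log.info("NormFinder mode = %s", res.mode)
            values["normfinder"] = res.stability.to_dict()
        elif alg == "genorm":
            q = to_quantities(sub, PreprocessConfig(efficiency=efficiency))
            res = genorm(q)
            values["genorm"] = res.reported_m.to_dict()
            tied["genorm"] = [list(res.final_pair)]
        else:  # pragma: no cover - guarded by RunConfig.validate
            raise ValueError(f"unknown algorithm {alg!r}")
        results[alg] = res
    consensus = rank_stability_values(values, tied)
    return consensus, results


def _config_hash(cfg: RunConfig) -> str:
    def _default(o):
        return str(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, m: Optional[CrtMatrix] = None) -> dict:
    """Execute all configured stages, persisting artifacts under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if m is None:
        if cfg.input_path is None or cfg.meta_path is None:
            raise ValueError("run_pipeline needs input_path and meta_path (or a matrix)")
        m = read_crt_table(cfg.input_path, cfg.meta_path,
                           spike_gene=cfg.spike_gene or cfg.preprocess.spike_gene)
    cfg.validate(m)
    amp = read_amp_scores(cfg.amp_path, like=m) if cfg.amp_path else None

    centered, usable = preprocess_matrix(m, cfg.preprocess, amp, cfg.exclude_genes)
    write_crt_matrix(centered, out / "preprocessed_crt.csv", out / "metadata.csv")

    panel = [g for g in usable if g not in set(cfg.targets)]
    consensus, results = run_stability_analysis(
        centered, panel, cfg.algorithms, cfg.group_by, cfg.bestkeeper_dispersion,
        cfg.preprocess.efficiency,
    )
    for alg, res in results.items():
        write_table(res.to_frame(), out / f"stability_{alg}.tsv", sep="\t")
    write_table(consensus.to_frame(), out / "consensus.tsv", sep="\t")
    write_json_report(consensus, out / "consensus.json")

    bundle: dict = {"consensus": consensus, "stability": results,
                    "matrix": centered, "panel": panel}

    if cfg.targets and cfg.rg and cfg.calibrator_tissue:
        fc = delta_delta_ct(
            centered, list(cfg.targets), cfg.rg, cfg.calibrator_tissue,
            efficiency=cfg.preprocess.efficiency, scale=cfg.ttest_scale,
        )
        write_table(fc.to_frame(), out / f"foldchange_{cfg.rg}.tsv", sep="\t")
        write_table(mean_modulation(fc), out / f"modulation_{cfg.rg}.tsv", sep="\t")
        bundle["foldchange"] = fc

    cq_panel = centered.values.loc[panel]
    bundle["pca"] = pca_clustvis(cq_panel)
    write_table(bundle["pca"].scores, out / "pca_scores.tsv", sep="\t")
    bundle["dendrograms"] = hier_cluster(cq_panel, axis="both")
    write_table(bundle["dendrograms"]["columns"].to_frame(),
                out / "sample_dendrogram.tsv", sep="\t")

    manifest = {
        "rgstab_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_genes": m.n_genes,
        "n_samples": m.n_samples,
        "panel": panel,
        "group_by": cfg.group_by,
        "bestkeeper_dispersion": cfg.bestkeeper_dispersion,
        "filter_logic": cfg.preprocess.filter_logic,
    }
    write_json_report(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
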
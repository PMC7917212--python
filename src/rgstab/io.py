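"""Reading and writing Cq (Crt) matrices, sample metadata and result tables.

All on-disk formats are plain delimited text.  Matrices are stored with
genes in rows and samples in columns (the orientation used throughout the
qPCR reference-gene literature); the first column holds the gene id and the
header row the sample ids.  Missing cells are written as ``NA`` and read
back from either ``NA`` or an empty cell.  The delimiter is auto-detected
between comma and tab on read and is a comma on write.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "CrtMatrix",
    "read_crt_table",
    "read_amp_scores",
    "write_crt_matrix",
    "write_table",
    "write_json_report",
]

_NA_VALUES = ["", "NA", "na", "NaN", "nan"]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: its label and the design factors."""

    sample_id: str
    donor: str = ""
    tissue: str = ""
    extra: Mapping[str, str] = field(default_factory=dict)


class CrtMatrix:
    """A genes x samples matrix of qPCR cycle-threshold (Cq/Crt) values.

    Parameters
    ----------
    values
        DataFrame of Crt cycles, genes in rows (unique index), samples in
        columns.  ``NaN`` marks a missing measurement.
    meta
        Sample metadata indexed by sample id, in matrix column order, with
        (at least) ``donor`` and ``tissue`` columns when group-aware
        analyses are requested.
    detected
        Boolean DataFrame of the same shape; ``False`` marks cells that are
        either missing or masked by the detection filter (the Crt value is
        kept, only the flag changes).  Defaults to "present wherever a
        numeric value is".
    spike_gene
        Optional gene id designating the exogenous spike-in row (for the
        study design, ath-miR-159a).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        meta: pd.DataFrame,
        detected: Optional[pd.DataFrame] = None,
        spike_gene: Optional[str] = None,
    ) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dups}")
        if list(values.columns) != list(meta.index):
            raise ValueError(
                "sample ids of matrix columns and metadata rows disagree: "
                f"{list(values.columns)} vs {list(meta.index)}"
            )
        if detected is None:
            detected = values.notna()
        detected = detected.astype(bool)
        if detected.shape != values.shape:
            raise ValueError("values and detected shapes disagree")
        detected = detected & values.notna()
        finite = values.to_numpy()
        bad = np.isfinite(finite) & (finite <= 0)
        if bad.any():
            raise ValueError("Crt values must be finite and > 0")
        if np.isinf(finite).any():
            raise ValueError("Crt values must be finite and > 0")
        if spike_gene is not None and spike_gene not in values.index:
            raise ValueError(f"spike gene {spike_gene!r} not in gene ids")
        self.values = values
        self.detected = pd.DataFrame(
            detected.to_numpy(), index=values.index, columns=values.columns
        )
        self.meta = meta
        self.spike_gene = spike_gene

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples(self) -> list[SampleMeta]:
        out = []
        for sid, row in self.meta.iterrows():
            known = {k: row[k] for k in ("donor", "tissue") if k in row.index}
            extra = {
                k: str(v) for k, v in row.items() if k not in ("donor", "tissue")
            }
            out.append(SampleMeta(str(sid), str(known.get("donor", "")),
                                  str(known.get("tissue", "")), extra))
        return out

    def candidate_genes(self) -> list[str]:
        """Gene ids excluding the spike-in row."""
        return [g for g in self.gene_ids if g != self.spike_gene]

    def fully_detected_genes(self, include_spike: bool = False) -> list[str]:
        """Genes flagged detected in every sample."""
        ok = self.detected.all(axis=1)
        genes = [g for g in self.gene_ids if ok[g]]
        if not include_spike:
            genes = [g for g in genes if g != self.spike_gene]
        return genes

    def subset(
        self,
        genes: Optional[Sequence[str]] = None,
        sample_ids: Optional[Sequence[str]] = None,
    ) -> "CrtMatrix":
        genes = list(genes) if genes is not None else self.gene_ids
        sample_ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene id(s): {missing}")
        missing_s = [s for s in sample_ids if s not in self.values.columns]
        if missing_s:
            raise KeyError(f"unknown sample id(s): {missing_s}")
        spike = self.spike_gene if self.spike_gene in genes else None
        return CrtMatrix(
            self.values.loc[genes, sample_ids].copy(),
            self.meta.loc[sample_ids].copy(),
            self.detected.loc[genes, sample_ids].copy(),
            spike,
        )

    def copy(self) -> "CrtMatrix":
        return CrtMatrix(
            self.values.copy(), self.meta.copy(), self.detected.copy(),
            self.spike_gene,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CrtMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"spike={self.spike_gene!r})"
        )


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _read_matrix_file(path: Path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES,
        keep_default_na=False, dtype=str,
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dups}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                out.iloc[i, j] = np.nan
                continue
            text = str(cell).strip()
            if text in _NA_VALUES:
                out.iloc[i, j] = np.nan
                continue
            try:
                out.iloc[i, j] = float(text)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell {text!r} at gene {df.index[i]!r}, "
                    f"sample {col!r} in {path}"
                ) from exc
    return out


def read_crt_table(
    path: str | Path,
    meta_path: str | Path,
    spike_gene: Optional[str] = None,
    transpose: bool = False,
) -> CrtMatrix:
    """Read a Crt matrix plus its sample metadata table.

    The matrix file has gene ids in the first column and sample ids in the
    header; the metadata file has a ``sample_id`` first column and (usually)
    ``donor`` and ``tissue`` columns.  Cells are detected wherever a numeric
    value is present; blank/``NA`` cells are missing.
    """
    path, meta_path = Path(path), Path(meta_path)
    values = _read_matrix_file(path)
    if transpose:
        values = values.T
    sep = _sniff_sep(meta_path)
    meta = pd.read_csv(meta_path, sep=sep, dtype=str, keep_default_na=False)
    meta = meta.set_index(meta.columns[0])
    meta.index = meta.index.astype(str)
    if set(values.columns) != set(meta.index):
        raise ValueError(
            "sample ids in matrix header and metadata disagree: "
            f"matrix {sorted(values.columns)}, metadata {sorted(meta.index)}"
        )
    meta = meta.loc[list(values.columns)]
    return CrtMatrix(values, meta, spike_gene=spike_gene)


def read_amp_scores(path: str | Path, like: Optional[CrtMatrix] = None) -> pd.DataFrame:
    """Read an Amp-Score matrix; when ``like`` is given, enforce its shape."""
    scores = _read_matrix_file(Path(path))
    if like is not None:
        if list(scores.index) != like.gene_ids or list(scores.columns) != like.sample_ids:
            raise ValueError("amp-score matrix shape/labels do not match the Crt matrix")
    return scores


def write_crt_matrix(
    m: CrtMatrix, path: str | Path, meta_path: Optional[str | Path] = None,
    decimals: int = 6,
) -> None:
    """Write a CrtMatrix (and optionally its metadata) as CSV.

    Cells that are missing are written as ``NA``; masked-but-measured cells
    keep their value (the detection flag is not part of the matrix file).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = m.values.round(decimals)
    out.index.name = "gene_id"
    out.to_csv(path, na_rep="NA", float_format=f"%.{decimals}f")
    if meta_path is not None:
        meta = m.meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(Path(meta_path))


def _as_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        return result
    if isinstance(result, pd.Series):
        return result.to_frame()
    if hasattr(result, "to_frame"):
        return result.to_frame()
    raise TypeError(f"cannot tabulate object of type {type(result).__name__}")


def write_table(result, path: str | Path, decimals: int = 6, sep: str = ",") -> None:
    """Write any tabular result (DataFrame or object with ``to_frame``).

    Floats are rendered with ``decimals`` decimal places; an empty result
    produces a header-only file.
    """
    df = _as_frame(result)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, na_rep="NA", float_format=f"%.{decimals}f")


def write_json_report(obj, path: str | Path) -> None:
    """Write a machine-readable JSON report (dict or object with ``to_dict``)."""
    if hasattr(obj, "to_dict") and not isinstance(obj, dict):
        obj = obj.to_dict()

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o).__name__}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
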
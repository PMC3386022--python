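"""Treatment-instance expression matrices: loading, batch centring, subsetting.

A *treatment instance* is one expression measurement of a (compound,
concentration, cell line, platform) combination.  All downstream
correlation work operates on an :class:`ExpressionMatrix` of instances x
probesets.  Batch effects are removed by mean-centring each probeset
within each batch, the standard treatment for Connectivity-Map-style
compendia where no vehicle controls enter the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentInstance",
    "ExpressionMatrix",
    "load_expression",
    "batch_mean_center",
    "subset_probesets",
]


@dataclass(frozen=True)
class TreatmentInstance:
    """One expression measurement and its experimental annotations."""

    instance_id: str
    compound_id: str
    batch_id: str
    cell_line: str = ""
    concentration_um: float = float("nan")
    platform: str = ""

    def __post_init__(self) -> None:
        if not self.instance_id:
            raise ValueError("instance_id must be non-empty")
        if not self.compound_id:
            raise ValueError(f"instance {self.instance_id!r}: compound_id must be non-empty")
        if not self.batch_id:
            raise ValueError(f"instance {self.instance_id!r}: batch_id must be non-empty")


@dataclass
class ExpressionMatrix:
    """Instances x probesets matrix of (log-scale) expression values.

    ``centred`` records whether batch mean-centring has been applied;
    the loader always returns ``centred=False``.
    """

    instances: list[TreatmentInstance]
    probeset_ids: list[str]
    values: np.ndarray
    centred: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.instances), len(self.probeset_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.instances)} instances x {len(self.probeset_ids)} probesets"
            )
        ids = [i.instance_id for i in self.instances]
        if len(set(ids)) != len(ids):
            dup = _first_duplicate(ids)
            raise ValueError(f"duplicate instance id: {dup!r}")
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            dup = _first_duplicate(self.probeset_ids)
            raise ValueError(f"duplicate probeset id: {dup!r}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    # -- convenience views -------------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    @property
    def instance_ids(self) -> list[str]:
        return [i.instance_id for i in self.instances]

    @property
    def compound_ids(self) -> list[str]:
        return [i.compound_id for i in self.instances]

    @property
    def batch_ids(self) -> list[str]:
        return [i.batch_id for i in self.instances]

    def probeset_index(self, probeset_ids: Sequence[str]) -> np.ndarray:
        """Column indices for ``probeset_ids``; unknown ids raise with the id named."""
        pos = {p: j for j, p in enumerate(self.probeset_ids)}
        missing = [p for p in probeset_ids if p not in pos]
        if missing:
            raise KeyError(f"unknown probeset id(s): {', '.join(missing[:10])}")
        return np.array([pos[p] for p in probeset_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.instance_ids, columns=self.probeset_ids)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# loading


_META_REQUIRED = ("instance_id", "compound_id", "batch_id")
_META_OPTIONAL = ("cell_line", "concentration_um", "platform")


def read_metadata(path: str | Path) -> dict[str, TreatmentInstance]:
    """Read the instance-annotation TSV into a mapping instance_id -> record."""
    meta = pd.read_csv(path, sep="\t", dtype={c: str for c in _META_REQUIRED})
    missing = [c for c in _META_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks required column(s): {missing}")
    out: dict[str, TreatmentInstance] = {}
    for _, row in meta.iterrows():
        inst = TreatmentInstance(
            instance_id=str(row["instance_id"]),
            compound_id=str(row["compound_id"]),
            batch_id=str(row["batch_id"]),
            cell_line=str(row["cell_line"]) if "cell_line" in meta.columns else "",
            concentration_um=float(row["concentration_um"]) if "concentration_um" in meta.columns else float("nan"),
            platform=str(row["platform"]) if "platform" in meta.columns else "",
        )
        if inst.instance_id in out:
            raise ValueError(f"duplicate instance id in metadata: {inst.instance_id!r}")
        out[inst.instance_id] = inst
    return out


def load_expression(
    path: str | Path,
    metadata_path: str | Path,
    orientation: str = "auto",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load an expression matrix (TSV or GCT 1.2) plus instance metadata.

    Parameters
    ----------
    path
        TSV (first column = row ids, orientation auto-detected against the
        metadata) or a GCT 1.2 file (probesets x instances by definition).
    metadata_path
        TSV mapping instance_id -> compound_id, batch_id and optional
        cell_line, concentration_um, platform.  Every instance in the
        matrix must have metadata.
    orientation
        ``"auto"`` (default), ``"instances_in_columns"`` or
        ``"instances_in_rows"`` to override auto-detection.
    impute_missing
        If true, missing cells are imputed with the probeset median
        instead of rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = read_metadata(metadata_path)

    if _is_gct(path):
        frame = _read_gct(path)  # probesets x instances
        inst_in_cols = True
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if orientation == "instances_in_columns":
            inst_in_cols = True
        elif orientation == "instances_in_rows":
            inst_in_cols = False
        elif orientation == "auto":
            cols_any = any(c in meta for c in frame.columns)
            rows_any = any(r in meta for r in frame.index)
            if cols_any and rows_any:
                raise ValueError(
                    "orientation is ambiguous: both row and column ids match known "
                    "instances; pass orientation explicitly"
                )
            if not cols_any and not rows_any:
                raise ValueError(
                    "cannot detect orientation: neither row nor column ids match "
                    "any instance in the metadata"
                )
            inst_in_cols = cols_any
        else:
            raise ValueError(f"unknown orientation {orientation!r}")

    if inst_in_cols:
        frame = frame.T  # -> instances x probesets

    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate instance id: {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicate probeset id: {dup!r}")

    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = frame.isna().to_numpy()
    if (np.isnan(values) & ~raw_na).any():
        raise ValueError("non-numeric cell in expression matrix")
    if np.isnan(values).any():
        if not impute_missing:
            raise ValueError("expression matrix contains missing values (impute_missing=False)")
        med = np.nanmedian(values, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = med[nan_c]
        logger.info("imputed %d missing cells with probeset medians", len(nan_r))

    unknown = [i for i in frame.index if i not in meta]
    if unknown:
        raise ValueError(f"instances lacking metadata: {', '.join(unknown[:10])}")
    instances = [meta[i] for i in frame.index]
    return ExpressionMatrix(
        instances=instances,
        probeset_ids=list(frame.columns),
        values=values,
        centred=False,
    )


def _is_gct(path: Path) -> bool:
    with open(path) as fh:
        return fh.readline().strip() == "#1.2"


def _read_gct(path: Path) -> pd.DataFrame:
    """GCT 1.2: version line, dims line, then Name/Description + sample columns."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError("malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in frame.columns:
        frame = frame.drop(columns=["Description"])
    if frame.shape != (n_rows, n_cols):
        raise ValueError(
            f"GCT declares {n_rows}x{n_cols} but body is {frame.shape[0]}x{frame.shape[1]}"
        )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write probesets x instances TSV (the on-disk convention)."""
    m.to_frame().T.to_csv(path, sep="\t", index_label="probeset_id")


def write_metadata(instances: Sequence[TreatmentInstance], path: str | Path) -> None:
    rows = [
        {
            "instance_id": i.instance_id,
            "compound_id": i.compound_id,
            "batch_id": i.batch_id,
            "cell_line": i.cell_line,
            "concentration_um": i.concentration_um,
            "platform": i.platform,
        }
        for i in instances
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# batch mean-centring


def batch_mean_center(m: ExpressionMatrix, min_batch_size: int = 5) -> ExpressionMatrix:
    """Subtract each probeset's within-batch mean, batch by batch.

    Only batches with *more than* ``min_batch_size`` instances are centred;
    instances in smaller batches are dropped from the returned matrix,
    because leaving them un-centred would let batch offsets dominate the
    correlation structure.  The number of dropped instances is logged.
    """
    if m.centred:
        raise ValueError("matrix is already centred")
    batches = np.asarray(m.batch_ids)
    keep_rows: list[int] = []
    centred = m.values.copy()
    for b in pd.unique(batches):
        rows = np.nonzero(batches == b)[0]
        if len(rows) > min_batch_size:
            centred[rows] -= centred[rows].mean(axis=0, keepdims=True)
            keep_rows.extend(rows.tolist())
    keep_rows.sort()
    n_dropped = m.n_instances - len(keep_rows)
    if n_dropped:
        logger.info(
            "batch_mean_center: dropped %d instance(s) in batches of <= %d",
            n_dropped,
            min_batch_size,
        )
    if not keep_rows:
        raise ValueError(f"no batch has more than {min_batch_size} instances")
    return ExpressionMatrix(
        instances=[m.instances[r] for r in keep_rows],
        probeset_ids=list(m.probeset_ids),
        values=centred[keep_rows],
        centred=True,
    )


def subset_probesets(m: ExpressionMatrix, sig: GeneSignature) -> ExpressionMatrix:
    """Restrict the matrix to the signature's probesets, in signature order."""
    cols = m.probeset_index(sig.probeset_ids)
    return ExpressionMatrix(
        instances=list(m.instances),
        probeset_ids=list(sig.probeset_ids),
        values=m.values[:, cols],
        centred=m.centred,
    )
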
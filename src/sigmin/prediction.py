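"""Correlation k-NN target prediction and the set-intersection accuracy metric.

Guilt-by-association: a query treatment instance inherits the targets of
the treatment instances whose expression profiles (restricted to the
signature's probesets) correlate with it most strongly.  Every instance
of the query's own compound is barred from the neighbour list — a
self-match carries no information about an unknown compound — and a
prediction counts as a success when the predicted and true target sets
intersect.  The intersection rule is deliberately lenient: the annotation
matrix is so sparse that stricter per-target metrics would be dominated
by false false-positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import TargetAnnotationTable, shuffle_associations
from .expr_data import ExpressionMatrix
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionConfig",
    "Neighbor",
    "PredictionResult",
    "ScoreReport",
    "BaselineSummary",
    "ConstantProfileError",
    "pearson",
    "nearest_neighbors",
    "predict_and_score",
    "random_baseline",
]


class ConstantProfileError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class PredictionConfig:
    k_neighbors: int = 1
    correlation: str = "pearson"
    restrict_to_annotated: bool = True

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.correlation != "pearson":
            raise ValueError(f"unsupported correlation {self.correlation!r}")


@dataclass(frozen=True)
class Neighbor:
    instance_id: str
    compound_id: str
    correlation: float


@dataclass(frozen=True)
class PredictionResult:
    query_instance: str
    query_compound: str
    neighbors: tuple[Neighbor, ...]
    predicted_targets: frozenset[str]
    true_targets: frozenset[str]
    success: bool


@dataclass(frozen=True)
class ScoreReport:
    accuracy: float
    precision: float
    n_queries: int
    n_skipped: int
    per_query: tuple[PredictionResult, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class BaselineSummary:
    mean: float
    sd: float
    accuracies: tuple[float, ...]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    nx_ = float(np.sqrt((xc * xc).sum()))
    ny_ = float(np.sqrt((yc * yc).sum()))
    if nx_ == 0.0 or ny_ == 0.0:
        raise ConstantProfileError("correlation undefined for a constant vector")
    return float(np.clip((xc * yc).sum() / (nx_ * ny_), -1.0, 1.0))


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-centred, unit-norm matrix plus a validity mask (non-constant rows)."""
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    valid = norms > 0
    z = np.zeros_like(centred)
    z[valid] = centred[valid] / norms[valid, None]
    return z, valid


def _correlations(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z, valid = _standardize_rows(values)
    return np.clip(z @ z.T, -1.0, 1.0), valid


def _rank_order(ids: Sequence[str]) -> np.ndarray:
    """Lexicographic rank of each instance id, for deterministic tie-breaks."""
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    rank = np.empty(len(ids), dtype=int)
    for r, i in enumerate(order):
        rank[i] = r
    return rank


def _top_k(
    corr_row: np.ndarray, candidate_mask: np.ndarray, id_rank: np.ndarray, k: int
) -> list[int]:
    cand = np.nonzero(candidate_mask)[0]
    if len(cand) < k:
        raise ValueError(f"only {len(cand)} eligible candidate(s) for k={k}")
    # sort by correlation descending, ties by instance id
    order = cand[np.lexsort((id_rank[cand], -corr_row[cand]))]
    return order[:k].tolist()


def nearest_neighbors(
    m: ExpressionMatrix,
    sig: GeneSignature,
    query: str,
    cfg: PredictionConfig,
    annotations: TargetAnnotationTable | None = None,
) -> tuple[Neighbor, ...]:
    """Top-k correlated instances for one query, self-compound excluded.

    Correlations are computed on the signature's probesets only.  When
    ``cfg.restrict_to_annotated`` is set, ``annotations`` must be supplied
    and candidate instances are limited to annotated compounds.
    """
    ids = m.instance_ids
    if query not in ids:
        raise KeyError(f"unknown query instance {query!r}")
    qi = ids.index(query)
    cols = m.probeset_index(sig.probeset_ids)
    if len(cols) < 3:
        raise ValueError("signature must contain at least 3 probesets for correlation")
    sub = m.values[:, cols]
    corr, valid = _correlations(sub)
    if not valid[qi]:
        raise ConstantProfileError(f"query {query!r} has a constant profile on this signature")
    compounds = np.asarray(m.compound_ids)
    mask = valid & (compounds != compounds[qi])
    if cfg.restrict_to_annotated:
        if annotations is None:
            raise ValueError("restrict_to_annotated requires an annotation table")
        mask &= np.array([c in annotations for c in compounds])
    picked = _top_k(corr[qi], mask, _rank_order(ids), cfg.k_neighbors)
    return tuple(
        Neighbor(instance_id=ids[j], compound_id=str(compounds[j]), correlation=float(corr[qi, j]))
        for j in picked
    )


def predict_and_score(
    m: ExpressionMatrix,
    sig: GeneSignature,
    annotations: TargetAnnotationTable,
    cfg: PredictionConfig = PredictionConfig(),
    keep_per_query: bool = False,
) -> ScoreReport:
    """Score every annotated instance as a query; report accuracy and precision.

    accuracy = fraction of queries whose predicted target union intersects
    the true target set; precision = mean over queries of
    ``|predicted & true| / |predicted|``.  Queries with a constant profile
    on the signature are skipped (counted in ``n_skipped``); constant
    candidates are excluded from neighbour lists.
    """
    ids = m.instance_ids
    compounds = np.asarray(m.compound_ids)
    annotated = np.array([c in annotations for c in compounds])
    if len(set(compounds[annotated])) < 2:
        raise ValueError("need at least two annotated compounds in the matrix")
    cols = m.probeset_index(sig.probeset_ids)
    if len(cols) < 3:
        raise ValueError("signature must contain at least 3 probesets for correlation")
    corr, valid = _correlations(m.values[:, cols])
    id_rank = _rank_order(ids)
    candidate_base = valid & (annotated if cfg.restrict_to_annotated else np.ones_like(valid))

    successes = 0
    precisions: list[float] = []
    per_query: list[PredictionResult] = []
    n_queries = 0
    n_skipped = 0
    for qi in np.nonzero(annotated)[0]:
        if not valid[qi]:
            n_skipped += 1
            continue
        mask = candidate_base & (compounds != compounds[qi])
        picked = _top_k(corr[qi], mask, id_rank, cfg.k_neighbors)
        true = annotations[str(compounds[qi])]
        predicted: frozenset[str] = frozenset().union(
            *(annotations[str(compounds[j])] if str(compounds[j]) in annotations else frozenset()
              for j in picked)
        )
        hit = len(predicted & true) > 0
        successes += hit
        precisions.append(len(predicted & true) / len(predicted) if predicted else 0.0)
        n_queries += 1
        if keep_per_query:
            per_query.append(
                PredictionResult(
                    query_instance=ids[qi],
                    query_compound=str(compounds[qi]),
                    neighbors=tuple(
                        Neighbor(ids[j], str(compounds[j]), float(corr[qi, j])) for j in picked
                    ),
                    predicted_targets=predicted,
                    true_targets=true,
                    success=hit,
                )
            )
    if n_skipped:
        logger.info("predict_and_score: skipped %d constant-profile quer(ies)", n_skipped)
    if n_queries == 0:
        raise ValueError("no scoreable queries (all profiles constant on this signature)")
    return ScoreReport(
        accuracy=successes / n_queries,
        precision=float(np.mean(precisions)),
        n_queries=n_queries,
        n_skipped=n_skipped,
        per_query=tuple(per_query),
    )


def random_baseline(
    m: ExpressionMatrix,
    sig: GeneSignature,
    annotations: TargetAnnotationTable,
    cfg: PredictionConfig,
    n_shuffles: int,
    seed: int,
) -> BaselineSummary:
    """Accuracy of guessing: re-score against shuffled compound-target maps."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_shuffles) % (2**31)
    accs = []
    for s in child_seeds:
        shuffled = shuffle_associations(annotations, seed=int(s))
        accs.append(predict_and_score(m, sig, shuffled, cfg).accuracy)
    accs_arr = np.asarray(accs)
    sd = float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0
    return BaselineSummary(mean=float(accs_arr.mean()), sd=sd, accuracies=tuple(accs))
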
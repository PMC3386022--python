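"""Gene signatures: expression-statistic ranking, random sampling, overlap.

A gene signature is a fixed-size, duplicate-free, ordered set of probeset
ids; correlations between treatment instances are computed on the
signature's probesets only.  Signatures are designed unsupervised, from
statistics of the expression matrix alone (no target labels enter the
ranking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .expr_data import ExpressionMatrix

__all__ = [
    "GeneSignature",
    "SIZE_LADDER",
    "EXPRESSION_CRITERIA",
    "rank_by_criterion",
    "shannon_entropy",
    "random_signature",
    "signature_overlap",
    "OverlapReport",
    "read_signature",
    "write_signature",
]

#: Signature sizes in half-logarithmic steps of base 2 (2**(n/2), rounded).
SIZE_LADDER: tuple[int, ...] = (
    16, 22, 32, 45, 64, 90, 128, 181, 256, 362, 512, 724, 1024, 1448, 2048, 2896, 4096,
)

#: The seven unsupervised expression-statistic ranking criteria.
EXPRESSION_CRITERIA: tuple[str, ...] = (
    "max_mean", "min_mean", "max_sd", "min_sd", "max_abs_mean", "min_abs_mean", "shannon",
)


@dataclass(frozen=True)
class GeneSignature:
    """An ordered, duplicate-free list of probeset ids with a provenance label."""

    probeset_ids: tuple[str, ...]
    origin: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "probeset_ids", tuple(self.probeset_ids))
        if len(self.probeset_ids) < 1:
            raise ValueError("signature must contain at least one probeset")
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ValueError("signature contains duplicate probeset ids")

    @property
    def size(self) -> int:
        return len(self.probeset_ids)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.probeset_ids)

    def __len__(self) -> int:
        return self.size

    def __iter__(self):
        return iter(self.probeset_ids)

    def __contains__(self, probeset_id: str) -> bool:
        return probeset_id in self.as_set()


def shannon_entropy(
    values: np.ndarray,
    bins: int = 200,
    range_lo: float = -5.0,
    range_hi: float = 8.0,
) -> float:
    """Shannon entropy (bits) of expression values binned on a fixed range.

    Values are histogrammed into ``bins`` equal-width bins on
    ``[range_lo, range_hi]``; out-of-range values are clamped into the
    boundary bins so every observation contributes.  Empty bins contribute
    nothing (0 * log 0 := 0).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot compute entropy of an empty vector")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if not range_lo < range_hi:
        raise ValueError("range_lo must be < range_hi")
    clamped = np.clip(values, range_lo, range_hi)
    counts, _ = np.histogram(clamped, bins=bins, range=(range_lo, range_hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def rank_by_criterion(m: "ExpressionMatrix", criterion: str, k: int) -> GeneSignature:
    """Top-k probesets under one of the seven expression-statistic criteria.

    Statistics are computed per probeset across *all* instances of ``m``.
    ``max_*`` criteria rank descending, ``min_*`` ascending, ``shannon``
    descending by entropy of the binned values.  Ties are broken by
    lexicographic probeset id so the cut at ``k`` is deterministic.
    """
    if criterion not in EXPRESSION_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {EXPRESSION_CRITERIA}")
    if not 1 <= k <= m.n_probesets:
        raise ValueError(f"k={k} out of range [1, {m.n_probesets}]")
    x = m.values
    if criterion in ("max_mean", "min_mean"):
        stat = x.mean(axis=0)
    elif criterion in ("max_sd", "min_sd"):
        stat = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    elif criterion in ("max_abs_mean", "min_abs_mean"):
        stat = np.abs(x).mean(axis=0)
    else:  # shannon
        stat = np.array([shannon_entropy(x[:, j]) for j in range(x.shape[1])])
    descending = criterion.startswith("max_") or criterion == "shannon"
    keyed = sorted(
        zip(stat, m.probeset_ids),
        key=(lambda t: (-t[0], t[1])) if descending else (lambda t: (t[0], t[1])),
    )
    return GeneSignature(tuple(p for _, p in keyed[:k]), origin=criterion)


def random_signature(universe: Sequence[str], k: int, seed: int) -> GeneSignature:
    """Uniform sample of ``k`` probesets without replacement; seeded."""
    universe = list(universe)
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    rng = np.random.default_rng([seed, 0x524E44])  # stream disjoint from other seeded components
    picked = rng.choice(len(universe), size=k, replace=False)
    return GeneSignature(tuple(universe[i] for i in picked), origin="random")


@dataclass(frozen=True)
class OverlapReport:
    shared: int
    fraction_of_smaller: float  # percent


def signature_overlap(a: GeneSignature, b: GeneSignature) -> OverlapReport:
    """Shared probesets, expressed as a percentage of the smaller signature.

    The maximum possible overlap between two signatures equals the size of
    the smaller one, so the fraction of the smaller signature found in the
    larger is the natural normalisation.
    """
    shared = len(a.as_set() & b.as_set())
    return OverlapReport(
        shared=shared,
        fraction_of_smaller=100.0 * shared / min(a.size, b.size),
    )


def read_signature(path: str | Path, origin: str = "file") -> GeneSignature:
    """One probeset id per line; ``#`` starts a comment."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return GeneSignature(tuple(ids), origin=origin)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    Path(path).write_text(
        f"# signature origin={sig.origin} size={sig.size}\n"
        + "\n".join(sig.probeset_ids)
        + "\n"
    )
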
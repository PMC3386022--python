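"""Compound-target annotations: potency filtering, matrix statistics, shuffled null.

The ground truth for target prediction is a sparse compound -> target-set
map built from bioactivity records.  Only IC50/Ki activities at
pharmacological potency (<= 5 uM by default) count as associations; the
resulting matrix is typically well under 1% dense, with a heavy-tailed
distribution of targets per compound.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "TargetAnnotationTable",
    "AnnotationStats",
    "ALLOWED_ACTIVITY_TYPES",
    "build_annotations",
    "matrix_stats",
    "shuffle_associations",
    "load_activities",
]

ALLOWED_ACTIVITY_TYPES = frozenset({"IC50", "Ki"})


@dataclass(frozen=True)
class ActivityRecord:
    """One measured bioactivity: compound, protein target, type, value in uM."""

    compound_id: str
    target_id: str
    activity_type: str
    activity_um: float

    def __post_init__(self) -> None:
        if self.activity_um <= 0:
            raise ValueError(
                f"activity value must be positive, got {self.activity_um} "
                f"for ({self.compound_id}, {self.target_id})"
            )


@dataclass(frozen=True)
class TargetAnnotationTable:
    """Potency-filtered compound -> target-set mapping."""

    mapping: Mapping[str, frozenset[str]]
    potency_cutoff_um: float = 5.0

    def __post_init__(self) -> None:
        for c, ts in self.mapping.items():
            if not ts:
                raise ValueError(f"compound {c!r} has an empty target set")

    @property
    def compounds(self) -> list[str]:
        return sorted(self.mapping)

    @property
    def targets(self) -> list[str]:
        return sorted(set().union(*self.mapping.values())) if self.mapping else []

    @property
    def n_pairs(self) -> int:
        return sum(len(ts) for ts in self.mapping.values())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.mapping

    def __getitem__(self, compound_id: str) -> frozenset[str]:
        return self.mapping[compound_id]


def build_annotations(
    records: Sequence[ActivityRecord], cutoff_um: float = 5.0
) -> TargetAnnotationTable:
    """Keep the pair (compound, target) iff some IC50/Ki record is <= cutoff.

    Activity types outside {IC50, Ki} are dropped (count logged); compounds
    whose every record fails the filter are absent from the result.  The
    cutoff is inclusive.
    """
    if not records:
        raise ValueError("no activity records supplied")
    n_dropped_type = sum(1 for r in records if r.activity_type not in ALLOWED_ACTIVITY_TYPES)
    if n_dropped_type:
        logger.info("build_annotations: dropped %d record(s) with activity type outside %s",
                    n_dropped_type, sorted(ALLOWED_ACTIVITY_TYPES))
    mapping: dict[str, set[str]] = {}
    for r in records:
        if r.activity_type in ALLOWED_ACTIVITY_TYPES and r.activity_um <= cutoff_um:
            mapping.setdefault(r.compound_id, set()).add(r.target_id)
    if not mapping:
        logger.info("build_annotations: no association survives the %.3g uM cutoff", cutoff_um)
    return TargetAnnotationTable(
        mapping={c: frozenset(ts) for c, ts in mapping.items()},
        potency_cutoff_um=cutoff_um,
    )


@dataclass(frozen=True)
class AnnotationStats:
    compounds: int
    targets: int
    pairs: int
    density_percent: float
    per_compound_counts: Mapping[str, int]
    min_targets: int
    max_targets: int
    n_single_target: int
    n_five_or_more: int


def matrix_stats(t: TargetAnnotationTable) -> AnnotationStats:
    """Sparsity and per-compound target-count summary of the annotation matrix."""
    if not t.mapping:
        raise ValueError("annotation table is empty")
    counts = {c: len(ts) for c, ts in t.mapping.items()}
    n_compounds = len(t.mapping)
    n_targets = len(t.targets)
    pairs = t.n_pairs
    return AnnotationStats(
        compounds=n_compounds,
        targets=n_targets,
        pairs=pairs,
        density_percent=100.0 * pairs / (n_compounds * n_targets),
        per_compound_counts=counts,
        min_targets=min(counts.values()),
        max_targets=max(counts.values()),
        n_single_target=sum(1 for v in counts.values() if v == 1),
        n_five_or_more=sum(1 for v in counts.values() if v >= 5),
    )


def shuffle_associations(
    t: TargetAnnotationTable, seed: int, unit: str = "sets"
) -> TargetAnnotationTable:
    """Randomise the compound -> target assignment for a chance baseline.

    ``unit="sets"`` (default) permutes whole target *sets* across compound
    ids uniformly (identity permutation allowed), which preserves each
    compound's target count and therefore the marginal structure that the
    set-intersection success metric sees.  ``unit="pairs"`` instead
    permutes the target column over individual (compound, target) pairs;
    duplicate pairs created by collisions collapse, so set sizes may shrink.
    """
    compounds = sorted(t.mapping)
    if len(compounds) < 2:
        raise ValueError("need at least two compounds to shuffle")
    rng = np.random.default_rng([seed, 0x53484C])  # stream disjoint from other seeded components
    if unit == "sets":
        sets = [t.mapping[c] for c in compounds]
        perm = rng.permutation(len(compounds))
        mapping = {compounds[i]: sets[perm[i]] for i in range(len(compounds))}
    elif unit == "pairs":
        pairs = [(c, x) for c in compounds for x in sorted(t.mapping[c])]
        targets = [x for _, x in pairs]
        perm = rng.permutation(len(targets))
        mapping_sets: dict[str, set[str]] = {}
        for (c, _), j in zip(pairs, perm):
            mapping_sets.setdefault(c, set()).add(targets[j])
        mapping = {c: frozenset(ts) for c, ts in mapping_sets.items()}
    else:
        raise ValueError(f"unknown shuffle unit {unit!r}")
    return TargetAnnotationTable(mapping=mapping, potency_cutoff_um=t.potency_cutoff_um)


# ---------------------------------------------------------------------------
# I/O


def load_activities(path: str | Path) -> list[ActivityRecord]:
    """Read activity TSV with columns compound_id, target_id, activity_type, activity_um."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "target_id": str})
    required = ("compound_id", "target_id", "activity_type", "activity_um")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"activity file {path} lacks column(s): {missing}")
    return [
        ActivityRecord(
            compound_id=row.compound_id,
            target_id=row.target_id,
            activity_type=row.activity_type,
            activity_um=float(row.activity_um),
        )
        for row in df.itertuples(index=False)
    ]


def write_activities(records: Iterable[ActivityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "target_id": r.target_id,
                "activity_type": r.activity_type,
                "activity_um": r.activity_um,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_pairs(t: TargetAnnotationTable, path: str | Path) -> None:
    """Two-column pairs TSV (compound_id, target_id)."""
    rows = [(c, x) for c in sorted(t.mapping) for x in sorted(t.mapping[c])]
    pd.DataFrame(rows, columns=["compound_id", "target_id"]).to_csv(path, sep="\t", index=False)


def load_pairs(path: str | Path, potency_cutoff_um: float = 5.0) -> TargetAnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.compound_id, set()).add(row.target_id)
    return TargetAnnotationTable(
        mapping={c: frozenset(ts) for c, ts in mapping.items()},
        potency_cutoff_um=potency_cutoff_um,
    )
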
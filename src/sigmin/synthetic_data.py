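"""Synthetic compendium generator with planted target-driven signal.

Emulates the statistical structure the pipeline assumes of a
Connectivity-Map-style compendium plus a bioactivity repository, at desk
scale: batched treatment instances, a sparse compound-target matrix with
a heavy-tailed targets-per-compound distribution, and expression profiles
in which compounds sharing targets correlate on a planted subset of
informative probesets.

The signal model is deliberately the simplest generative story consistent
with the guilt-by-association premise: each target owns a fixed effect
vector supported on a few informative probesets, and an instance's
expression is the sum of its compound's target effects, a per-batch
offset, and i.i.d. Gaussian noise.  The generator also emits an
interaction network wiring the informative genes downstream of
'expression'-mode regulators, a probeset-gene map, and a gene-set
collection containing one planted pathway (the informative genes) among
random decoy sets — so every stage of the pipeline, through enrichment,
can be exercised against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotations import ActivityRecord, write_activities
from .enrichment import GeneSetCollection, enrich, write_gmt
from .expr_data import ExpressionMatrix, TreatmentInstance, write_expression, write_metadata
from .network_signatures import InteractionNetwork, ProbesetGeneMap
from .signatures import GeneSignature

__all__ = ["SimConfig", "SimTruth", "SimBundle", "RecoveryReport",
           "generate", "truth_recovery_report", "write_bundle"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic compendium."""

    n_probesets: int = 1000
    n_informative: int = 32
    n_compounds: int = 100
    n_targets: int = 40
    replicates_per_compound: int = 3
    n_batches: int = 10
    max_targets_per_compound: int = 10
    effect_support: int = 8          # informative probesets per target effect
    effect_size: float = 2.0         # effect scale, in units of noise sd
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    n_decoy_sets: int = 30           # decoy pathways in the GMT collection
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_probesets:
            raise ValueError("n_informative cannot exceed n_probesets")
        if self.effect_support > self.n_informative:
            raise ValueError("effect_support cannot exceed n_informative")
        for name in ("n_probesets", "n_informative", "n_compounds", "n_targets",
                     "replicates_per_compound", "n_batches", "max_targets_per_compound"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth carried alongside the generated data."""

    informative_probesets: tuple[str, ...]
    effect_vectors: Mapping[str, Mapping[str, float]]  # target -> probeset -> effect
    planted_set_name: str


@dataclass(frozen=True)
class SimBundle:
    config: SimConfig
    expression: ExpressionMatrix            # raw, un-centred
    activities: tuple[ActivityRecord, ...]
    network: InteractionNetwork
    probeset_gene_map: ProbesetGeneMap
    collection: GeneSetCollection
    truth: SimTruth


PLANTED_SET_NAME = "PLANTED_TARGET_MODULE"


def generate(cfg: SimConfig) -> SimBundle:
    """Build the full synthetic bundle, deterministically from ``cfg.seed``."""
    # domain-separated stream: the same user seed passed to other seeded
    # components (GA, random signatures) must not replay the draws that
    # planted the ground truth
    rng = np.random.default_rng([cfg.seed, 0x53494D])
    probesets = [f"PS{i:04d}" for i in range(cfg.n_probesets)]
    genes = [f"G{i:04d}" for i in range(cfg.n_probesets)]
    targets = [f"T{i:03d}" for i in range(cfg.n_targets)]
    compounds = [f"C{i:03d}" for i in range(cfg.n_compounds)]

    informative_idx = np.sort(rng.choice(cfg.n_probesets, size=cfg.n_informative, replace=False))
    informative = [probesets[i] for i in informative_idx]

    # per-target effect vectors on a random subset of the informative probesets
    effects = np.zeros((cfg.n_targets, cfg.n_probesets))
    effect_vectors: dict[str, dict[str, float]] = {}
    for ti in range(cfg.n_targets):
        support = rng.choice(informative_idx, size=cfg.effect_support, replace=False)
        vals = rng.normal(0.0, 1.0, size=cfg.effect_support) * cfg.effect_size
        effects[ti, support] = vals
        effect_vectors[targets[ti]] = {probesets[j]: float(v) for j, v in zip(support, vals)}

    # heavy-tailed targets per compound: 1 + truncated (Zipf - 1)
    mapping: dict[str, frozenset[str]] = {}
    for c in compounds:
        extra = min(int(rng.zipf(2.0)) - 1, cfg.max_targets_per_compound - 1)
        size = min(1 + extra, cfg.n_targets)
        picked = rng.choice(cfg.n_targets, size=size, replace=False)
        mapping[c] = frozenset(targets[j] for j in picked)

    # expression: target effects + batch offset + noise
    batch_offsets = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_batches, cfg.n_probesets))
    instances: list[TreatmentInstance] = []
    rows: list[np.ndarray] = []
    target_index = {t: i for i, t in enumerate(targets)}
    for c in compounds:
        signal = effects[[target_index[t] for t in sorted(mapping[c])]].sum(axis=0)
        for r in range(cfg.replicates_per_compound):
            b = int(rng.integers(cfg.n_batches))
            instances.append(
                TreatmentInstance(
                    instance_id=f"{c}_r{r}",
                    compound_id=c,
                    batch_id=f"B{b:02d}",
                    cell_line="CL1",
                    concentration_um=10.0,
                    platform="SYNTH1",
                )
            )
            rows.append(signal + batch_offsets[b] + rng.normal(0.0, cfg.noise_sd, cfg.n_probesets))
    expression = ExpressionMatrix(
        instances=instances, probeset_ids=list(probesets),
        values=np.vstack(rows), centred=False,
    )

    # bioactivities: potent records for true pairs, impotent decoys, plus a
    # few out-of-scope activity types to exercise the filter
    records: list[ActivityRecord] = []
    true_pairs = [(c, t) for c in compounds for t in sorted(mapping[c])]
    for c, t in true_pairs:
        records.append(ActivityRecord(c, t, str(rng.choice(["IC50", "Ki"])),
                                      float(rng.uniform(0.01, 5.0))))
    true_set = set(true_pairs)
    free_cells = [(c, t) for c in compounds for t in targets if (c, t) not in true_set]
    n_decoys = min(max(1, len(true_pairs) // 2), len(free_cells))
    for i in rng.choice(len(free_cells), size=n_decoys, replace=False) if free_cells else []:
        c, t = free_cells[int(i)]
        records.append(ActivityRecord(c, t, str(rng.choice(["IC50", "Ki"])),
                                      float(rng.uniform(5.001, 100.0))))
    for _ in range(10):
        c = compounds[int(rng.integers(cfg.n_compounds))]
        t = targets[int(rng.integers(cfg.n_targets))]
        records.append(ActivityRecord(c, t, "EC50", float(rng.uniform(0.01, 5.0))))

    pmap = ProbesetGeneMap.from_pairs(zip(probesets, genes))
    network = _build_network(cfg, rng, genes, informative_idx, effects, targets, target_index)
    collection = _build_collection(cfg, rng, genes, informative_idx)

    truth = SimTruth(
        informative_probesets=tuple(informative),
        effect_vectors=effect_vectors,
        planted_set_name=PLANTED_SET_NAME,
    )
    return SimBundle(
        config=cfg, expression=expression, activities=tuple(records),
        network=network, probeset_gene_map=pmap, collection=collection, truth=truth,
    )


def _build_network(cfg, rng, genes, informative_idx, effects, targets, target_index):
    """Regulators -> informative-gene modules, plus random background edges."""
    edges: list[tuple[str, str, str]] = []
    non_informative = sorted(set(range(cfg.n_probesets)) - set(informative_idx.tolist()))
    reg_idx = rng.choice(len(non_informative), size=2, replace=False)
    regulators = [genes[non_informative[i]] for i in reg_idx]
    for reg in regulators:
        downstream = rng.choice(informative_idx, size=min(12, len(informative_idx)), replace=False)
        edges.extend((reg, genes[j], "expression") for j in downstream)
        broad = rng.choice(cfg.n_probesets, size=min(20, cfg.n_probesets), replace=False)
        edges.extend((reg, genes[j], "expression") for j in broad if genes[j] != reg)
    # wire each target's effect-support genes into a chain (co-perturbed module)
    for t in targets:
        support = np.nonzero(effects[target_index[t]])[0]
        for a, b in zip(support[:-1], support[1:]):
            edges.append((genes[a], genes[b], "binding"))
    # background edges, mean out-degree ~3: supercritical, so most of the
    # network is reachable from the regulatory layer (STRING-like)
    n_background = 3 * cfg.n_probesets
    for _ in range(n_background):
        a, b = rng.integers(cfg.n_probesets, size=2)
        if a != b:
            edges.append((genes[a], genes[b], str(rng.choice(["binding", "activation"]))))
    return InteractionNetwork.from_edges(edges, extra_nodes=genes)


def _build_collection(cfg, rng, genes, informative_idx):
    sets = {PLANTED_SET_NAME: frozenset(genes[i] for i in informative_idx)}
    for s in range(cfg.n_decoy_sets):
        size = int(rng.integers(10, 51))
        members = rng.choice(cfg.n_probesets, size=size, replace=False)
        sets[f"DECOY_{s:03d}"] = frozenset(genes[i] for i in members)
    return GeneSetCollection(sets=sets, universe=frozenset(genes))


@dataclass(frozen=True)
class RecoveryReport:
    planted_recovery: float   # |sig ∩ planted| / |planted|
    pathway_rank: int         # 1-based rank of the planted set in enrich(sig)


def truth_recovery_report(bundle: SimBundle, sig: GeneSignature) -> RecoveryReport:
    """How much of the planted signal a signature captured."""
    planted = set(bundle.truth.informative_probesets)
    recovery = len(planted & sig.as_set()) / len(planted)
    table = enrich(sig, bundle.probeset_gene_map, bundle.collection)
    rank = int(table.index[table["set_name"] == bundle.truth.planted_set_name][0]) + 1
    return RecoveryReport(planted_recovery=recovery, pathway_rank=rank)


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Materialise the bundle as the plain-text files the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expression, outdir / "expr.tsv")
    write_metadata(bundle.expression.instances, outdir / "meta.tsv")
    write_activities(bundle.activities, outdir / "activities.tsv")
    bundle.network.write_edges(outdir / "edges.tsv")
    bundle.probeset_gene_map.write(outdir / "map.tsv")
    write_gmt(bundle.collection, outdir / "pathways.gmt")
    truth = {
        "informative_probesets": list(bundle.truth.informative_probesets),
        "effect_vectors": {t: dict(v) for t, v in bundle.truth.effect_vectors.items()},
        "planted_set_name": bundle.truth.planted_set_name,
        "config": asdict(bundle.config),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
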
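import numpy as np
import pytest

from sigmin import (
    ExpressionMatrix,
    SimConfig,
    TreatmentInstance,
    generate,
)
from sigmin.annotations import build_annotations
from sigmin.expr_data import batch_mean_center


def make_matrix(values, compounds=None, batches=None, probesets=None, centred=False):
    """Hand-built ExpressionMatrix with simple default annotations."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    compounds = compounds or [f"c{i+1}" for i in range(n)]
    batches = batches or ["b1"] * n
    probesets = probesets or [f"p{j+1}" for j in range(p)]
    instances = [
        TreatmentInstance(instance_id=f"i{i+1}", compound_id=compounds[i], batch_id=batches[i])
        for i in range(n)
    ]
    return ExpressionMatrix(instances=instances, probeset_ids=probesets,
                            values=values, centred=centred)


@pytest.fixture(scope="session")
def bundle7():
    return generate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def bundle11():
    return generate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def prepared11(bundle11):
    """Centred matrix + potency-filtered annotations for the seed-11 compendium."""
    m = batch_mean_center(bundle11.expression)
    table = build_annotations(list(bundle11.activities))
    return m, table


@pytest.fixture(scope="session")
def prepared7(bundle7):
    m = batch_mean_center(bundle7.expression)
    table = build_annotations(list(bundle7.activities))
    return m, table


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale compendium for fast GA / pipeline exercising."""
    cfg = SimConfig(n_probesets=60, n_informative=12, n_compounds=20, n_targets=8,
                    replicates_per_compound=2, n_batches=3, effect_support=4,
                    n_decoy_sets=5, seed=3)
    return generate(cfg)


@pytest.fixture(scope="session")
def prepared_small(small_bundle):
    m = batch_mean_center(small_bundle.expression)
    table = build_annotations(list(small_bundle.activities))
    return m, table
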
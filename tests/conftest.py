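import numpy as np
import pandas as pd
import pytest

from pluristate import (
    ConditionTruth,
    GenePanelTruth,
    KineticParams,
    MixtureTruth,
    SimulationConfig,
)


@pytest.fixture
def truth_params():
    """Planted transition rates used throughout the recovery tests."""
    return KineticParams(0.3, 0.5, 0.1, 0.05)


@pytest.fixture
def truth_p0():
    return (0.8, 0.15, 0.05)


@pytest.fixture
def mixture_truth():
    return MixtureTruth(means=(1.0, 3.0, 5.0), sds=(0.4, 0.4, 0.4))


@pytest.fixture
def washoff_config(truth_params, truth_p0):
    """A small wash-off design: one condition, 2 replicates, days 0-5."""
    return SimulationConfig(
        seed=11,
        n_cells_per_sample=2000,
        timepoints=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        n_replicates=2,
        conditions=[ConditionTruth(label="ctrl", params=truth_params, p0=truth_p0)],
    )


def make_panel(
    n_genes=10,
    p_detect=0.9,
    cv_inflation_alt=1.0,
    planted=(),
    seed=5,
    conditions=("A", "B"),
):
    """Hand-rolled small panel with fixed means/sds for arithmetic checks."""
    rng = np.random.default_rng(seed)
    names = [f"g{i+1}" for i in range(n_genes)]
    means = rng.uniform(5.0, 9.0, n_genes)
    genes = pd.DataFrame({"mean": means, "sd": 0.4 * means}, index=names)
    for c in conditions:
        genes[f"p_detect_{c}"] = p_detect
    return GenePanelTruth(
        genes=genes,
        planted_correlations=list(planted),
        cv_inflation={conditions[0]: 1.0, conditions[1]: cv_inflation_alt},
        h3k9ac_targets=set(names[:2]),
    )


@pytest.fixture
def small_panel():
    return make_panel()


def euler_trajectory(params, p0, times, dt=1e-4):
    """Independent explicit-Euler oracle for dp/dt = Q p.

    Deliberately avoids the package's propagator: builds Q by hand from
    the four rates and steps forward with a fixed small dt.
    """
    a1, a2, a3, a4 = params.a1, params.a2, params.a3, params.a4
    q = np.array([[-a1, a2, 0.0], [a1, -(a2 + a3), a4], [0.0, a3, -a4]])
    out = []
    p = np.asarray(p0, dtype=float).copy()
    t = 0.0
    for target in times:
        while t < target - dt / 2:
            p = p + dt * (q @ p)
            t += dt
        out.append(p.copy())
    return np.array(out)
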
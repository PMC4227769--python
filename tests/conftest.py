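import numpy as np
import pytest

from flipkin.mechanism import MechanismSpec, table1_rates
from flipkin.synth import (
    FluorescenceModel,
    MixingExperiment,
    default_time_grid,
    synthesize_association_trace,
    synthesize_double_mixing_trace,
)


@pytest.fixture(scope="session")
def wt():
    return table1_rates("WT")


@pytest.fixture(scope="session")
def y162a():
    return table1_rates("Y162A")


@pytest.fixture(scope="session")
def tec():
    return FluorescenceModel.tec_default()


@pytest.fixture(scope="session")
def aea_wt():
    return FluorescenceModel.aea_default("WT")


@pytest.fixture(scope="session")
def wt_tec_trace(wt, tec):
    """Noiseless WT association trace at saturating enzyme (300/50 nM)."""
    exp = MixingExperiment("single-mix", 300e-9, 50e-9, noise_sd=0.0)
    return synthesize_association_trace(MechanismSpec(wt), tec, exp)


def build_wt_ensemble(wt_rates, tec_model, aea_model, noise_sd, seed):
    """Standard four-trace WT study: two excess-protein association traces,
    one excess-DNA association trace, one double-mixing chase recovery."""
    items = []
    designs = [
        (150e-9, 50e-9, "single-mix", "TEC", default_time_grid(3.0, 250)),
        (300e-9, 50e-9, "single-mix", "TEC", default_time_grid(3.0, 250)),
        (100e-9, 600e-9, "single-mix", "TEC", default_time_grid(3.0, 250)),
        (300e-9, 100e-9, "double-mix", "AEA", np.geomspace(1e-3, 4000, 250)),
    ]
    spec = MechanismSpec(wt_rates)
    for i, (E, D, mode, ctx, times) in enumerate(designs):
        exp = MixingExperiment(
            mode, E, D, times=times,
            age_time=1.0 if mode == "double-mix" else 0.0,
            noise_sd=noise_sd, seed=seed * 16 + i, context=ctx)
        fl = tec_model if ctx == "TEC" else aea_model
        synth = (synthesize_association_trace if mode == "single-mix"
                 else synthesize_double_mixing_trace)
        items.append((exp, synth(spec, fl, exp)))
    return items
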
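import numpy as np
import pytest

from pulsedose import InitialCondition, PhaseRates, TwoStateModel


@pytest.fixture
def ecoli_model() -> TwoStateModel:
    """Full-fit E. coli / ampicillin parameter set."""
    return TwoStateModel(
        on=PhaseRates(K_n=-3.8, K_p=-0.2, a=0.0, b=0.0),
        off=PhaseRates(K_n=1.35, K_p=-1.2, a=0.0, b=1.2),
        cap_log10=9.0,
    )


@pytest.fixture
def ecoli_ic() -> InitialCondition:
    return InitialCondition(log10_c0=7.8, f0=9e-7)


def random_phase(rng: np.random.Generator, kill: bool) -> PhaseRates:
    """A plausible random phase: killing (on) or regrowing (off)."""
    if kill:
        return PhaseRates(
            K_n=-rng.uniform(0.5, 6.0),
            K_p=-rng.uniform(0.0, 0.8),
            a=rng.uniform(0.0, 0.2),
            b=rng.uniform(0.0, 0.1),
        )
    return PhaseRates(
        K_n=rng.uniform(0.3, 3.0),
        K_p=-rng.uniform(0.2, 2.0),
        a=rng.uniform(0.0, 0.2),
        b=rng.uniform(0.0, 2.0),
    )


def random_model(rng: np.random.Generator, switching: bool = True) -> TwoStateModel:
    on = random_phase(rng, kill=True)
    off = random_phase(rng, kill=False)
    if not switching:
        from dataclasses import replace

        on = replace(on, a=0.0)
        off = replace(off, a=0.0)
    return TwoStateModel(on=on, off=off, cap_log10=None)
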
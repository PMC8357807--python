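import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def one_plate():
    """A single screen plate (2 blanks, 3 quasi-WT, 91 test mutants)."""
    from macroscreen import synth

    specs, truth = synth.make_screen_layout(n_plates=1, seed=3)
    return specs[0], truth


@pytest.fixture(scope="session")
def kinetics():
    from macroscreen import synth

    return synth.OxidationKineticModel()


def make_trace(times, ys, mutant_id="m1", acceptor="fumarate", **kw):
    """Single-replicate intensity trace from plain arrays."""
    from macroscreen.redox import IntensityTrace

    return IntensityTrace(
        mutant_id=mutant_id,
        acceptor=acceptor,
        replicates=[(np.asarray(times, float), np.asarray(ys, float))],
        **kw,
    )
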
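import numpy as np
import pytest

from ictrack import ICParams, SystemSpec, make_plant, make_step_sequence, render_target


@pytest.fixture(scope="session")
def zero_order_plant():
    return make_plant(SystemSpec(order=0))


@pytest.fixture(scope="session")
def reference_params():
    """Reference intermittent-control configuration on the zero-order system."""
    return ICParams(open_loop_interval=0.35, feedback_delay=0.14, trigger_mode="external")


@pytest.fixture(scope="session")
def reference_external_run():
    """Noise-free externally triggered virtual experiment (zero-order system).

    Shared by the slope-law and parameter-recovery checks; computing it once
    keeps the suite fast without weakening any individual assertion.
    """
    from ictrack.experiments import run_external_condition

    return run_external_condition(seed=101, participants=4, repetitions=1)


def reversal_trial(isi=0.2, pattern="rev_RL", dt=0.001, trail=1.2):
    seq = make_step_sequence(pattern, isi=isi)
    w = render_target(seq, dt, duration=seq.step_times[-1] + trail)
    return seq, w
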
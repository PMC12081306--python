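"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

from pulsechase import kinetics, synthetic


@pytest.fixture(scope="session")
def clearance_82min():
    return kinetics.ClearanceParams.with_effective_minutes(82.0)


@pytest.fixture(scope="session")
def excess_dose_trajectory(clearance_82min):
    """Dose 2x pool, tau 14 d, 82-min clearance, readout after chase clears."""
    pool = 14.0
    system = kinetics.KineticSystem(
        synthesis_rate=1.0, degradation_rate=1.0 / 14.0,
        dye_dose_pulse=2 * pool, dye_dose_chase=2 * pool,
        clearance=clearance_82min)
    schedule = kinetics.standard_schedule(14.0, clearance_82min)
    traj = kinetics.simulate_pulse_chase(system, schedule)
    return system, schedule, traj


@pytest.fixture(scope="session")
def noiseless_image():
    return synthetic.make_image(n_objects=60, tau_days=10.0, delta_t=7.0,
                                snr=np.inf, seed=11)


@pytest.fixture(scope="session")
def noisy_image():
    return synthetic.make_image(n_objects=100, tau_days=10.0, delta_t=7.0,
                                snr=20.0, seed=12)
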
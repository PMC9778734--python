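import numpy as np
import pytest

from glycopmf import (
    PotentialSpec,
    equilibration_discard,
    generate_umbrella_set,
    wham_solve,
)

# Umbrella-set scale used for the heavier statistical checks: 26 windows every
# 0.10 Å, k = 150 kcal/mol/Å², 2e4 samples per window.  dt is chosen so that
# dt·κ_max/γ < 0.1 while keeping enough decorrelated samples per window.
UMBRELLA_DT = 4e-4
UMBRELLA_SEED = 7
UMBRELLA_RANGE = (-1.3, 1.3)


@pytest.fixture(scope="session")
def double_well():
    return PotentialSpec(
        "double_well", {"barrier": 5.0, "half_separation": 1.0}, domain=(-2.0, 2.0)
    )


@pytest.fixture(scope="session")
def umbrella_windows(double_well):
    centers = np.round(np.arange(-1.25, 1.2501, 0.10), 10)
    windows = generate_umbrella_set(
        double_well, centers, force_constant=150.0, steps_per_window=20000,
        temperature=310.0, seed=UMBRELLA_SEED, dt=UMBRELLA_DT,
    )
    return [equilibration_discard(w, t_eq=2000 * UMBRELLA_DT) for w in windows]


@pytest.fixture(scope="session")
def wham_result(umbrella_windows):
    return wham_solve(
        umbrella_windows, n_bins=100, bin_range=UMBRELLA_RANGE,
        tolerance=1e-8, max_iter=200000,
    )
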
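import numpy as np
import pytest

from ssbl.benchmark import run_benchmark
from ssbl.simulate import SimulationConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_problem(rng, n_sensors=6, n_gen=16, n_times=4, noise=0.05):
    """Small random inverse problem with a sparse truth."""
    K = rng.standard_normal((n_sensors, n_gen))
    K /= np.linalg.norm(K, axis=0)
    J = np.zeros((n_gen, n_times))
    active = rng.choice(n_gen, size=3, replace=False)
    J[active[0]] = 1.0
    J[active[1]] = np.cos(np.arange(n_times))
    J[active[2], n_times // 2] = -1.5
    V = K @ J + noise * rng.standard_normal((n_sensors, n_times))
    return K, V, J


@pytest.fixture(scope="session")
def desk_benchmark(tmp_path_factory):
    """The 20-trial desk-scale study shared by the acceptance tests.

    One hemispheric configuration at S=300, N=32, T=101, SNR 6 dB with a
    jittered inversion lead field; all three methods fitted per trial.
    """
    config = SimulationConfig(S=300, N=32, T=101, seed=7, n_trials=20)
    out = tmp_path_factory.mktemp("desk_benchmark")
    result = run_benchmark(config, out, n_trials=20,
                           layouts=[("L", "L", "L")], n_time_points=3)
    result["out_dir"] = out
    return result
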
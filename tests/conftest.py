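import pytest
from hypothesis import HealthCheck, settings

import tcgafed as tf

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark_fixture():
    """10-endpoint benchmark conditions: 25 patients over 10 tumours,
    2 blue / 3 pink / 5 green endpoints."""
    return tf.generate(tf.benchmark_config(seed=1))


@pytest.fixture(scope="session")
def benchmark_pool(benchmark_fixture):
    return tf.spawn_endpoints(benchmark_fixture)


@pytest.fixture(scope="session")
def benchmark_union(benchmark_pool):
    return benchmark_pool.union_graph()


@pytest.fixture(scope="session")
def deployment_fixture():
    """17-endpoint deployment layout: 33 tumours, 2 blue / 6 pink / 9 green."""
    return tf.generate(tf.deployment_config(seed=1))


@pytest.fixture(scope="session")
def deployment_pool(deployment_fixture):
    return tf.spawn_endpoints(deployment_fixture)


@pytest.fixture(scope="session")
def small_fixture():
    return tf.generate(tf.FixtureConfig(
        n_tumours=4, n_patients=6, seed=3,
        layout={"blue": 1, "pink": 2, "green": 2},
        records_per_kind={k: 2 for k in tf.synthetic.RESULT_KINDS}))
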
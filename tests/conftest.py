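import pytest

from amygsim import CircuitParameters, build_preset, run_protocol
from amygsim.suite import run_battery


@pytest.fixture(scope="session")
def params():
    return CircuitParameters()


@pytest.fixture(scope="session")
def preset_results():
    """Lazily-run cache of preset simulations shared across the session."""
    cache = {}

    def get(name, trials_per_epoch=15, record_trace=False):
        key = (name, trials_per_epoch, record_trace)
        if key not in cache:
            cache[key] = run_protocol(
                build_preset(name, trials_per_epoch),
                record_trace=record_trace)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def normal_result(preset_results):
    return preset_results("normal")


@pytest.fixture(scope="session")
def battery():
    """The full property battery on the shipped default configuration."""
    return run_battery()
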
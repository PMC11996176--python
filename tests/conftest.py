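import numpy as np
import pytest

from cbtdcs.protocol import StimProtocol
from cbtdcs.synth.neurons import (
    NeuronSpec,
    simulate_unit_on_trials,
    trial_table_for_protocol,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pc_unit_fixture():
    """One modulated PC simulated on a 5-trial anodal protocol."""
    proto = StimProtocol(polarity=1, intensity_uA=200.0, n_trials=5)
    trials = trial_table_for_protocol(proto)
    spec = NeuronSpec(unit_id="pc0", depth_mm=1.0, theta_deg=0.0)
    from cbtdcs.synth.neurons import plateau_modulation

    m = plateau_modulation(spec, 1, 200.0)
    res = simulate_unit_on_trials(spec, trials, np.full(len(trials), m), seed_or_rng=7)
    res["trials"] = trials
    res["true_mod_fraction"] = m
    return res
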
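import numpy as np
import pytest

from sexhap import presets, sim, yhap


@pytest.fixture(scope="session")
def study():
    """The full-scale synthetic study: X region, genes, variant spec, true Y
    (every edit applied), and the expected-Y model (size-class rules)."""
    x, genes = presets.build_study_region(seed=1)
    spec = presets.default_yspec(x)
    true_y, coord = sim.make_true_y(x, spec)
    model = yhap.build_expected_y(x, genes, spec)
    return {
        "x": x,
        "genes": genes,
        "spec": spec,
        "true_y": true_y,
        "coord": coord,
        "model": model,
    }


@pytest.fixture(scope="session")
def diag_junction(study):
    """1-based position on the true Y of the last copy base before the
    diagnostic deletion."""
    spec = study["spec"]
    return int(study["coord"]["copy_to_y"][spec.diagnostic_deletion.start - 1])


def make_noisy(template: str, seed: int, error_rate: float = 0.0644) -> str:
    model = sim.LongReadErrorModel(error_rate=error_rate, seed=seed)
    return sim._inject_errors(np.random.default_rng(seed), template, model)
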
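import numpy as np
import pytest

import neocca as nc


@pytest.fixture(scope="session")
def small_spec():
    """Small 2-modality study: quick to generate, enough structure to recover."""
    modalities = [
        nc.ModalitySpec("volume", (10, 10, 6), noise_sd=0.05, smooth_fwhm_mm=3.0),
        nc.ModalitySpec("skeleton", (10, 10, 6), noise_sd=0.05, kind="skeleton"),
    ]
    clinical = [
        nc.ClinicalVariableSpec("age", "continuous", linked_component=0, link_strength=0.85),
        nc.ClinicalVariableSpec("weight", "continuous", linked_component=1, link_strength=0.6),
        nc.ClinicalVariableSpec("score", "continuous"),
        nc.ClinicalVariableSpec("flag_common", "binary", prevalence=0.5),
        nc.ClinicalVariableSpec("flag_mid", "binary", prevalence=0.3),
    ]
    return nc.SimulationSpec(
        n_subjects=150, k_components=3, modality_specs=modalities,
        clinical_spec=clinical, n_active_per_map=12, planted_rho=(0.85, 0.6),
        outcome_spec=[nc.OutcomeSpec("cognitive", linked_pair=0, effect_r=0.4),
                      nc.OutcomeSpec("motor", linked_pair=None, effect_r=0.0)],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return nc.simulate_study(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def planted_pair(n, rho, p=3, k=3, seed=0):
    """Two blocks with a single planted canonical correlation rho."""
    g = np.random.default_rng(seed)
    z = g.standard_normal(n)
    X = g.standard_normal((n, p))
    Y = g.standard_normal((n, k))
    X[:, 0] = rho * z + np.sqrt(1 - rho**2) * g.standard_normal(n)
    Y[:, 0] = z
    return X, Y
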
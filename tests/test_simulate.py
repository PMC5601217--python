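"""Synthetic-data generator: determinism, planted structure, validity guards."""

import numpy as np
import pytest

import neocca as nc
from neocca.simulate import generate_clinical, generate_latents, generate_multimodal, \
    generate_outcomes, generate_spatial_maps


def tiny_spec(**kw):
    defaults = dict(
        n_subjects=60, k_components=2,
        modality_specs=[nc.ModalitySpec("m1", (8, 8, 4), noise_sd=0.1, smooth_fwhm_mm=2.0),
                        nc.ModalitySpec("m2", (8, 8, 4), noise_sd=0.1)],
        clinical_spec=[nc.ClinicalVariableSpec("a", "continuous", linked_component=0,
                                               link_strength=0.8),
                       nc.ClinicalVariableSpec("b", "binary", prevalence=0.4)],
        n_active_per_map=8, planted_rho=(0.8,),
        outcome_spec=[nc.OutcomeSpec("cog", linked_pair=0, effect_r=0.5)],
        seed=0)
    defaults.update(kw)
    return nc.SimulationSpec(**defaults)


def test_generation_is_deterministic(small_spec):
    d1, c1, o1, l1, m1 = nc.simulate_study(small_spec)
    d2, c2, o2, l2, m2 = nc.simulate_study(small_spec)
    assert np.array_equal(l1.values, l2.values)
    for b1, b2 in zip(d1.blocks, d2.blocks):
        assert np.array_equal(b1.values, b2.values)
    assert c1.data.equals(c2.data)
    assert o1.equals(o2)


def test_latents_standardized_and_nearly_uncorrelated():
    spec = tiny_spec(n_subjects=500, k_components=4)
    lat = generate_latents(spec)
    assert np.abs(lat.values.mean(axis=0)).max() < 1e-9
    assert np.abs(lat.values.std(axis=0) - 1).max() < 1e-9
    C = np.corrcoef(lat.values.T)
    assert np.abs(C - np.eye(4)).max() < 0.15


@pytest.mark.parametrize("field,value,msg", [
    ("n_subjects", -1, "n_subjects"),
    ("k_components", 0, "k_components"),
    ("planted_rho", (0.5, 0.8), "descending"),
    ("planted_rho", (1.5,), "planted_rho"),
    ("n_active_per_map", 0, "n_active_per_map"),
])
def test_invalid_spec_rejected(field, value, msg):
    with pytest.raises(ValueError, match=msg):
        tiny_spec(**{field: value})


def test_spec_identifiability_guard():
    with pytest.raises(ValueError, match="identifiability"):
        tiny_spec(n_subjects=4)


def test_spatial_maps_support_norm_disjoint():
    spec = tiny_spec(modality_specs=[nc.ModalitySpec("m1", (8, 8, 4), smooth_fwhm_mm=0.0)])
    maps = generate_spatial_maps(spec)["m1"]
    for k in range(spec.k_components):
        assert np.count_nonzero(maps[:, k]) == spec.n_active_per_map
        assert np.linalg.norm(maps[:, k]) == pytest.approx(1.0, abs=1e-9)
    # disjoint supports across components
    support = maps != 0
    assert not np.any(support[:, 0] & support[:, 1])
    # smoothing preserves unit norm
    sm = generate_spatial_maps(tiny_spec())["m1"]
    assert np.allclose(np.linalg.norm(sm, axis=0), 1.0, atol=1e-9)


def test_spatial_maps_refuse_overfull_grid():
    spec = tiny_spec(modality_specs=[nc.ModalitySpec("m1", (3, 3, 1))],
                     n_active_per_map=5)
    with pytest.raises(ValueError, match="disjoint|enlarge"):
        generate_spatial_maps(spec)


def test_multimodal_noiseless_is_exact_product():
    spec = tiny_spec(modality_specs=[nc.ModalitySpec("m1", (8, 8, 4), noise_sd=0.0),
                                     nc.ModalitySpec("m2", (8, 8, 4), noise_sd=0.0)])
    lat = generate_latents(spec)
    maps = generate_spatial_maps(spec)
    ds = generate_multimodal(lat, maps, spec)
    for b in ds.blocks:
        expected = lat.values @ maps[b.name].T
        assert np.array_equal(b.values, expected)
    assert ds.modality_names == ["m1", "m2"]


def test_multimodal_overwhelming_noise_drowns_signal():
    spec = tiny_spec(modality_specs=[nc.ModalitySpec("m1", (8, 8, 4), noise_sd=200.0)])
    lat = generate_latents(spec)
    maps = generate_spatial_maps(spec)
    ds = generate_multimodal(lat, maps, spec)
    signal = (lat.values @ maps["m1"].T).ravel()
    observed = ds.blocks[0].values.ravel()
    assert abs(np.corrcoef(signal, observed)[0, 1]) < 0.05


def test_multimodal_dimension_mismatch_named():
    spec = tiny_spec()
    lat = generate_latents(spec)
    maps = generate_spatial_maps(spec)
    maps["m1"] = maps["m1"][:, :1]
    with pytest.raises(ValueError, match="components"):
        generate_multimodal(lat, maps, spec)


def test_clinical_perfect_link_and_prevalence():
    spec = tiny_spec(n_subjects=10_000,
                     clinical_spec=[
                         nc.ClinicalVariableSpec("exact", "continuous",
                                                 linked_component=0, link_strength=1.0),
                         nc.ClinicalVariableSpec("coin", "binary", prevalence=0.5),
                     ])
    lat = generate_latents(spec)
    table = generate_clinical(lat, spec)
    r = np.corrcoef(table.data["exact"], lat.values[:, 0])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)
    assert abs(table.data["coin"].mean() - 0.5) < 0.02


def test_clinical_invalid_prevalence_rejected():
    with pytest.raises(ValueError, match="prevalence"):
        tiny_spec(clinical_spec=[nc.ClinicalVariableSpec("b", "binary", prevalence=1.5),
                                 nc.ClinicalVariableSpec("c", "continuous")])


def test_planted_canonical_correlation_recoverable_by_cca():
    """Oracle check: CCA between the clinical block and the latents finds rho."""
    spec = tiny_spec(n_subjects=2000, k_components=2, planted_rho=(0.9,),
                     clinical_spec=[
                         nc.ClinicalVariableSpec("link", "continuous",
                                                 linked_component=0, link_strength=0.9),
                         nc.ClinicalVariableSpec("noise1", "continuous"),
                         nc.ClinicalVariableSpec("noise2", "continuous"),
                     ])
    lat = generate_latents(spec)
    table = generate_clinical(lat, spec)
    X = nc.encode(table)
    r1 = nc.fit_cca(X.values, lat.values).r[0]
    assert 0.85 <= r1 <= 0.95


def test_outcomes_link_and_missingness():
    spec = tiny_spec(n_subjects=2000,
                     outcome_spec=[nc.OutcomeSpec("null", linked_pair=0, effect_r=0.0),
                                   nc.OutcomeSpec("exact", linked_pair=0, effect_r=1.0)],
                     n_outcome_missing=0)
    lat = generate_latents(spec)
    out = generate_outcomes(lat.values[:, :1], spec)
    v = lat.values[:, 0]
    assert abs(np.corrcoef(out["null"], v)[0, 1]) < 0.1
    # effect_r = 1: exact affine function of the variate
    assert np.allclose(out["exact"], 100 + 15 * (v - v.mean()) / v.std(), atol=1e-9)


def test_outcome_default_missingness_matches_followup():
    spec = tiny_spec(n_subjects=449)
    lat = generate_latents(spec)
    out = generate_outcomes(lat.values[:, :1], spec)
    assert out["cog"].notna().sum() == 425


def test_outcome_unknown_pair_rejected():
    spec = tiny_spec(outcome_spec=[nc.OutcomeSpec("cog", linked_pair=5, effect_r=0.3)])
    lat = generate_latents(spec)
    with pytest.raises(KeyError, match="linked_pair"):
        generate_outcomes(lat.values[:, :1], spec)


def test_study_spec_shape_and_missingness():
    spec = nc.study_spec(n_subjects=449, seed=0)
    ds, clin, outc, lat, maps = nc.simulate_study(spec)
    assert ds.n_subjects == 449 and len(ds.blocks) == 4
    assert len(clin.names) == 32
    kinds = list(clin.kinds.values())
    assert kinds.count("continuous") == 7 and kinds.count("binary") == 25
    assert int(clin.data["parenteral_nutrition_days"].isna().sum()) == 1
    assert int(outc["cognitive"].notna().sum()) == 425


def test_null_mode_controls_false_positives():
    """With no planted links, the smallest pipeline p-value rarely dips below 0.05."""
    n_reps, hits = 40, 0
    for rep in range(n_reps):
        spec = tiny_spec(
            n_subjects=80, seed=900 + rep, planted_rho=(),
            modality_specs=[nc.ModalitySpec("m1", (6, 6, 3), noise_sd=0.1, smooth_fwhm_mm=2.0),
                            nc.ModalitySpec("m2", (6, 6, 3), noise_sd=0.1)],
            clinical_spec=[nc.ClinicalVariableSpec("a", "continuous"),
                           nc.ClinicalVariableSpec("c", "continuous"),
                           nc.ClinicalVariableSpec("b", "binary", prevalence=0.5)],
            outcome_spec=[])
        ds, clin, _, _, _ = nc.simulate_study(spec)
        cfg = nc.PipelineConfig(max_components=4, perms=99, boot=0, seed=rep)
        res = nc.run_pipeline(ds, clin, None, cfg)
        hits += res.report.pair_test.p_values.min() <= 0.05
    assert hits <= 0.10 * n_reps + 2  # >=90% of null replicates stay above 0.05
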
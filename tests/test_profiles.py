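import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlcedge import (
    FluenceProfile,
    GaussianMixture,
    NoCrossingError,
    NoEdgeError,
    analyze_profile,
    evaluate_mixture,
    find_crossing,
    fit_edge_mixture,
    normalize_profile,
    penumbra_width,
    profile_offsets,
)
from mlcedge.experiments import REFERENCE_MIXTURE, generate_fixture

REF_WINDOW = (9.0, 10.5)
Z80 = 0.8416212335729143  # standard-normal 0.8 quantile


def ramp_profile():
    xs = np.linspace(-1.0, 2.0, 301)
    values = np.clip(1.0 - xs, 0.0, 1.0)
    return FluenceProfile(xs=xs, values=values)


class TestNormalize:
    def test_scale_invariance_and_idempotence(self):
        prof = generate_fixture("erf_edge", {"sigma_mm": 1.0})
        scaled = FluenceProfile(xs=prof.xs, values=prof.values * 37.2)
        a = normalize_profile(scaled)
        b = normalize_profile(prof)
        assert np.allclose(a.values, b.values)
        again = normalize_profile(a)
        assert np.allclose(again.values, a.values)

    def test_plateau_maps_to_one(self):
        # the plateau band includes a sliver of shoulder, so the level is
        # recovered to ~1e-3; the induced edge shift is < 1e-3 mm
        prof = normalize_profile(generate_fixture("erf_edge", {"sigma_mm": 1.0}))
        assert prof.values[: len(prof.values) // 4].mean() == pytest.approx(1.0, abs=2e-3)

    def test_constant_profile_rejected(self):
        flat = FluenceProfile(xs=np.linspace(0, 1, 11), values=np.ones(11))
        with pytest.raises(NoEdgeError):
            normalize_profile(flat)


class TestEvaluateMixture:
    def test_single_peak_center_value(self):
        gm = GaussianMixture(np.array([[0.7, 1.0, 0.5]]))
        assert evaluate_mixture(gm, 1.0) == pytest.approx(0.7)

    def test_reference_values(self):
        # near the broad peak the mixture is ~1 (plateau shoulder); at the
        # reported field edge it reads one half
        assert evaluate_mixture(REFERENCE_MIXTURE, 9.054) == pytest.approx(1.0, abs=0.01)
        assert evaluate_mixture(REFERENCE_MIXTURE, 9.932) == pytest.approx(0.50, abs=0.005)

    def test_vectorised_matches_scalar(self):
        xs = np.linspace(9.0, 10.5, 7)
        vec = evaluate_mixture(REFERENCE_MIXTURE, xs)
        assert vec == pytest.approx([evaluate_mixture(REFERENCE_MIXTURE, x) for x in xs])


class TestFindCrossing:
    def test_linear_ramp_crossing(self):
        assert find_crossing(ramp_profile(), 0.5, (-1.0, 2.0)) == pytest.approx(0.5, abs=1e-6)

    def test_reference_field_edge(self):
        x50 = find_crossing(REFERENCE_MIXTURE, 0.5, REF_WINDOW)
        assert x50 == pytest.approx(9.932, abs=0.005)

    def test_erf_crossings_at_gaussian_quantiles(self):
        sigma = 0.1  # cm
        prof = generate_fixture("erf_edge", {"sigma_mm": 1.0, "step": 0.002})
        for level, z in ((0.2, Z80), (0.8, -Z80)):
            x = find_crossing(prof, level, (-1.0, 1.0))
            assert x == pytest.approx(z * sigma, abs=1e-4)

    def test_unbracketed_level_raises(self):
        with pytest.raises(NoCrossingError):
            find_crossing(ramp_profile(), 0.5, (1.2, 1.9))


class TestPenumbraWidth:
    def test_reference_width(self):
        assert penumbra_width(REFERENCE_MIXTURE, REF_WINDOW) == pytest.approx(1.98, abs=0.02)

    def test_erf_closed_form(self):
        prof = generate_fixture("erf_edge", {"sigma_mm": 1.0, "step": 0.002})
        assert penumbra_width(prof, (-1.0, 1.0)) == pytest.approx(2 * Z80 * 1.0, abs=0.01)

    def test_step_profile_width_within_one_grid_spacing(self):
        prof = generate_fixture("step", {"step": 0.01})
        assert penumbra_width(prof, (-0.5, 0.5)) <= 0.01 * 10.0

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        shift=st.floats(-5.0, 5.0),
        scale=st.floats(0.5, 3.0),
    )
    def test_translation_invariant_and_dilation_linear(self, shift, scale):
        gm = REFERENCE_MIXTURE
        base = penumbra_width(gm, REF_WINDOW)
        moved = GaussianMixture(
            np.column_stack(
                [
                    gm.coefficients[:, 0],
                    (gm.coefficients[:, 1] + shift - 9.75) * scale + 9.75,
                    gm.coefficients[:, 2] * scale,
                ]
            )
        )
        lo = (REF_WINDOW[0] + shift - 9.75) * scale + 9.75
        hi = (REF_WINDOW[1] + shift - 9.75) * scale + 9.75
        assert penumbra_width(moved, (lo, hi)) == pytest.approx(base * scale, rel=1e-6)


class TestFitEdgeMixture:
    def test_exact_recovery_of_single_gaussian(self):
        xs = np.linspace(-2.0, 2.0, 401)
        truth = GaussianMixture(np.array([[0.9, 0.2, 0.6]]))
        prof = FluenceProfile(xs=xs, values=evaluate_mixture(truth, xs))
        gm, rmse = fit_edge_mixture(prof, n=1, window=(-2.0, 2.0))
        assert rmse < 1e-6
        assert gm.coefficients.ravel() == pytest.approx([0.9, 0.2, 0.6], abs=1e-6)

    def test_noiseless_erf_edge_recovered(self):
        prof = generate_fixture("erf_edge", {"sigma_mm": 1.0})
        ana = analyze_profile(prof, edge_from="fit")
        assert abs(ana.field_edge) * 10.0 <= 0.01  # mm

    def test_parameter_recovery_on_seeded_noisy_fixtures(self):
        # reduced-size version of the full acceptance sweep
        errors = []
        for s in range(25):
            sigma = 0.3 + 1.7 * s / 24
            prof = generate_fixture(
                "erf_edge", {"sigma_mm": sigma, "edge": 0.0, "noise_sd": 0.005}, seed=s
            )
            errors.append(analyze_profile(prof, edge_from="fit").field_edge * 10.0)
        errors = np.array(errors)
        assert abs(errors.mean()) < 0.01
        assert errors.std() < 0.05

    def test_fit_and_raw_edges_agree_for_noiseless_profile(self, geom, mm_source):
        from mlcedge import FieldConfig, simulate_profile

        prof = simulate_profile(geom, FieldConfig(radius=15.0, nominal_edge=0.0), mm_source)
        fit_edge = analyze_profile(prof, edge_from="fit").field_edge
        raw_edge = analyze_profile(prof, edge_from="raw").field_edge
        assert abs(fit_edge - raw_edge) * 10.0 <= 0.05

    def test_auto_peak_selection_prefers_parsimony_on_pure_gaussian(self):
        xs = np.linspace(-2.0, 2.0, 401)
        truth = GaussianMixture(np.array([[0.9, 0.2, 0.6]]))
        prof = FluenceProfile(xs=xs, values=evaluate_mixture(truth, xs))
        ana = analyze_profile(prof, n_peaks="auto", window=(-2.0, 2.0), edge_from="fit")
        assert ana.fit.n == 1


class TestProfileOffsets:
    def test_zero_when_edge_equals_nominal(self):
        off = profile_offsets(edge=10.0, nominal=10.0, geometric=10.05)
        assert off.pno == pytest.approx(0.0)

    def test_reference_worked_example(self):
        x50 = find_crossing(REFERENCE_MIXTURE, 0.5, REF_WINDOW)
        off = profile_offsets(edge=x50, nominal=10.0, geometric=10.0)
        assert abs(off.pno) == pytest.approx(0.68, abs=0.02)

    def test_identity(self):
        off = profile_offsets(edge=9.932, nominal=10.0, geometric=9.95)
        assert off.pno == pytest.approx(off.lpo + off.rfo, abs=1e-12)


def test_edge_analysis_record_round_trip(tmp_path):
    prof = generate_fixture("erf_edge", {"sigma_mm": 1.0})
    ana = analyze_profile(prof, edge_from="fit")
    out = tmp_path / "edge.json"
    ana.to_json(out)
    import json

    rec = json.loads(out.read_text())
    assert rec["n_peaks"] == 3
    assert rec["field_edge_cm"] == pytest.approx(ana.field_edge)
    assert len(rec["coefficients"]) == 3
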
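"""synthetic_cohort: covariate marginals, implanted effects, bundles."""

import json

import numpy as np
import pandas as pd
import pytest

from subshape.features import medial_curve, radial_distance
from subshape.mesh import enclosed_volume, vertex_normals
from subshape.synthetic import (
    COVARIATE_DEFAULTS,
    SHAPE_STRUCTURES,
    STRUCTURES,
    VOLUME_ONLY_STRUCTURES,
    CohortBundle,
    CohortConfig,
    EffectSpec,
    default_effect_menu,
    geodesic_distances,
    make_template,
    simulate_cohort,
    simulate_covariates,
    simulate_subject,
    suggest_patch_center,
)
from subshape.synthetic import _TemplateCache, _patch_window  # test-only internals


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

class TestTemplates:
    def test_fourteen_bilateral_plus_midline(self):
        assert len(SHAPE_STRUCTURES) == 14
        assert set(VOLUME_ONLY_STRUCTURES) == {
            "callosum", "left_lateral_ventricle", "right_lateral_ventricle",
            "third_ventricle",
        }
        assert len(STRUCTURES) == 18

    @pytest.mark.parametrize("sid", ["left_thalamus", "right_caudate",
                                     "left_hippocampus", "callosum",
                                     "third_ventricle"])
    def test_templates_valid_and_volume_on_target(self, sid):
        t = make_template(sid)
        t.validate()
        from subshape.synthetic import _spec_for

        (_, target, _), _ = _spec_for(sid)
        assert abs(enclosed_volume(t) - target) < 0.05 * target

    def test_right_is_mirror_of_left(self):
        left = make_template("left_putamen")
        right = make_template("right_putamen")
        assert np.allclose(right.vertices, left.vertices * [1, -1, 1])
        right.validate()  # orientation restored despite the mirror


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

class TestCovariates:
    def test_default_cohort_shape(self):
        df = simulate_covariates(63, 31, seed=1)
        assert len(df) == 94
        assert int(df["HIVStatus"].sum()) == 63

    def test_determinism(self):
        a = simulate_covariates(63, 31, seed=5)
        b = simulate_covariates(63, 31, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_large_n_age_marginal(self):
        df = simulate_covariates(1000, 1000, seed=2)
        case_age = df.loc[df.HIVStatus == 1, "Age"]
        assert abs(case_age.mean() - 64.68) < 0.5

    def test_exact_reported_counts(self):
        df = simulate_covariates(63, 31, seed=3)
        case = df.HIVStatus == 1
        assert int(df.loc[case, "Sex"].sum()) == 2
        assert int(df.loc[~case, "Sex"].sum()) == 4
        assert int(df.loc[case, "ViralDetectable"].sum()) == 24
        assert int(df.loc[case, "HAND"].sum()) == 30

    def test_controls_have_nan_clinical_fields(self):
        df = simulate_covariates(10, 10, seed=4)
        ctrl = df[df.HIVStatus == 0]
        for col in ("nCD4", "TSD", "ViralDetectable"):
            assert ctrl[col].isna().all()
        for col in ("HIVStatus", "Age", "Sex", "ICV"):
            assert df[col].notna().all()

    def test_truncation_positive(self):
        df = simulate_covariates(500, 10, seed=6)
        case = df.HIVStatus == 1
        assert (df.loc[case, "nCD4"] > 0).all()
        assert (df.loc[case, "TSD"] > 0).all()

    def test_bad_n_error(self):
        with pytest.raises(ValueError):
            simulate_covariates(0, 5)


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

class TestSimulateSubject:
    def _row(self, hiv=1, icv=COVARIATE_DEFAULTS["icv"][0]):
        return pd.Series({"subject_id": "s0", "HIVStatus": hiv, "Age": 65.0,
                          "Sex": 0, "ICV": icv, "TSD": 20.0})

    def test_identity_without_noise_or_effects(self):
        t = make_template("left_amygdala")
        sub = simulate_subject(t, self._row(), noise_sd=0.0, seed=0)
        assert np.max(np.abs(sub.mesh.vertices - t.vertices)) < 1e-12
        assert np.array_equal(sub.mesh.faces, t.faces)

    def test_thickness_effect_shrinks_volume(self):
        t = make_template("left_thalamus")
        eff = EffectSpec("left_thalamus", -0.10,
                         patch_center=suggest_patch_center(t), patch_radius=9.0)
        twin = simulate_subject(t, self._row(), noise_sd=0.0, seed=1)
        case = simulate_subject(t, self._row(), effects=[eff], noise_sd=0.0, seed=1)
        assert enclosed_volume(case.mesh) < enclosed_volume(twin.mesh)

    def test_control_not_affected_by_binary_effect(self):
        t = make_template("left_thalamus")
        eff = EffectSpec("left_thalamus", -0.10, patch_center=12, patch_radius=9.0)
        ctrl = simulate_subject(t, self._row(hiv=0), effects=[eff], noise_sd=0.0, seed=2)
        assert np.max(np.abs(ctrl.mesh.vertices - t.vertices)) < 1e-12

    def test_determinism(self):
        t = make_template("left_thalamus")
        a = simulate_subject(t, self._row(), noise_sd=0.5, seed=9)
        b = simulate_subject(t, self._row(), noise_sd=0.5, seed=9)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)

    def test_wrong_structure_effect_error(self):
        t = make_template("left_thalamus")
        with pytest.raises(ValueError, match="right_caudate"):
            simulate_subject(t, self._row(),
                             effects=[EffectSpec("right_caudate", -0.1)])

    def test_icv_scaling(self):
        t = make_template("left_thalamus")
        icv0 = COVARIATE_DEFAULTS["icv"][0]
        big = simulate_subject(t, self._row(icv=1.2 * icv0), noise_sd=0.0, seed=0)
        assert abs(enclosed_volume(big.mesh) / enclosed_volume(t) - 1.2) < 1e-9

    def test_effect_recoverable_by_construction(self):
        """Case-minus-control displacement equals amplitude*RD*window exactly
        in the noiseless limit (along template normals)."""
        t = make_template("left_thalamus")
        cache = _TemplateCache(t)
        center = suggest_patch_center(t)
        eff = EffectSpec("left_thalamus", -0.08, patch_center=center, patch_radius=9.0)
        case = simulate_subject(t, self._row(), effects=[eff], noise_sd=0.0,
                                seed=0, cache=cache)
        disp = np.einsum("ij,ij->i", case.mesh.vertices - t.vertices,
                         vertex_normals(t))
        expected = eff.amplitude * cache.rd * cache.window(center, 9.0)
        assert np.allclose(disp, expected, atol=1e-9)

    def test_negative_noise_error(self):
        t = make_template("left_amygdala")
        with pytest.raises(ValueError):
            simulate_subject(t, self._row(), noise_sd=-1.0)


# ---------------------------------------------------------------------------
# Patch machinery
# ---------------------------------------------------------------------------

class TestPatchWindow:
    def test_plateau_and_taper(self):
        t = make_template("left_thalamus")
        w = _patch_window(t, 12, 9.0)
        d = geodesic_distances(t, 12)
        assert w[12] == 1.0
        assert np.all(w[d <= 0.6 * 9.0] == 1.0)
        assert np.all(w[d >= 9.0] == 0.0)
        inside = (d > 0.6 * 9.0) & (d < 9.0)
        assert np.all((w[inside] > 0) & (w[inside] < 1))

    def test_geodesic_lower_bounded_by_euclidean(self):
        t = make_template("left_thalamus")
        d = geodesic_distances(t, 0)
        eu = np.linalg.norm(t.vertices - t.vertices[0], axis=1)
        assert np.all(d >= eu - 1e-9)

    def test_suggest_patch_center_is_thickest_vertex(self):
        t = make_template("left_thalamus")
        c = medial_curve(t)
        rd = radial_distance(t, c).values
        assert suggest_patch_center(t) == int(np.argmax(rd))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

class TestCohorts:
    def test_null_config_empty_ground_truth(self, small_cohort):
        assert all(not e.mask.any() for e in small_cohort.ground_truth.entries)

    def test_bundle_written_with_manifest(self, tmp_path):
        cfg = CohortConfig(n_cases=2, n_controls=2, resolution=2)
        b = simulate_cohort(cfg, seed=7, outdir=tmp_path / "run")
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        for rel in manifest["files"]:
            assert (tmp_path / "run" / rel).exists()
        # every subject x structure mesh is listed
        n_meshes = sum(1 for k in manifest["files"] if k.endswith(".ply"))
        assert n_meshes == 4 * len(cfg.structures) + len(cfg.structures)

    def test_bundle_round_trip(self, tmp_path):
        cfg = CohortConfig(n_cases=2, n_controls=2, resolution=2,
                           effects=(EffectSpec("left_thalamus", -0.08,
                                               patch_center=12, patch_radius=9.0),))
        b = simulate_cohort(cfg, seed=8, outdir=tmp_path / "run")
        back = CohortBundle.load(tmp_path / "run")
        assert back.subject_ids == b.subject_ids
        s = cfg.structures[0]
        sub = b.subject_ids[0]
        assert np.allclose(back.surfaces[sub][s].mesh.vertices,
                           b.surfaces[sub][s].mesh.vertices, atol=1e-6)
        assert np.array_equal(back.ground_truth.entries[0].mask,
                              b.ground_truth.entries[0].mask)

    def test_unknown_config_field_named(self):
        with pytest.raises(ValueError, match="n_subjects"):
            CohortConfig.from_dict({"n_subjects": 94})

    def test_effect_on_missing_structure_error(self):
        cfg = CohortConfig(structures=("left_thalamus",),
                           effects=(EffectSpec("callosum", -0.1,
                                               effect_type="volume"),))
        with pytest.raises(ValueError, match="callosum"):
            simulate_cohort(cfg, seed=0)

    def test_volume_effect_mean_deficit(self):
        cfg = CohortConfig(n_cases=150, n_controls=150, structures=("callosum",),
                           effects=(EffectSpec("callosum", -0.107,
                                               effect_type="volume"),))
        b = simulate_cohort(cfg, seed=11)
        case = b.covariates["HIVStatus"].to_numpy() == 1
        vols = np.array([
            enclosed_volume(b.surfaces[s]["callosum"].mesh) for s in b.subject_ids
        ])
        icv = b.covariates["ICV"].to_numpy()
        adj = vols / (icv / COVARIATE_DEFAULTS["icv"][0])  # remove ICV scale
        deficit = adj[case].mean() / adj[~case].mean() - 1.0
        assert abs(deficit - (-0.107)) < 0.02

    def test_determinism(self):
        cfg = CohortConfig(n_cases=2, n_controls=2, resolution=2)
        a = simulate_cohort(cfg, seed=13)
        b = simulate_cohort(cfg, seed=13)
        s = cfg.structures[0]
        for sub in a.subject_ids:
            assert np.array_equal(a.surfaces[sub][s].mesh.vertices,
                                  b.surfaces[sub][s].mesh.vertices)

    def test_amplitude_bound(self):
        with pytest.raises(ValueError):
            EffectSpec("left_thalamus", -0.6)

    def test_default_effect_menu_signs(self):
        menu = default_effect_menu()
        by_id = {e.structure_id: e for e in menu}
        assert by_id["callosum"].amplitude == -0.107
        assert all(e.amplitude > 0 for e in menu if "ventricle" in e.structure_id)
        assert all(e.effect_type == "volume" for e in menu)
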
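"""Synthetic-data generator: signal model, masks, cohorts, dynamics, serum."""

import numpy as np
import pytest

from nephna.core import ConfigError, GeometryError
from nephna import synthkid as sk
from nephna.stats import cov_percent, max_percent_change

from conftest import SMALL_GRID


class TestSubject:
    def test_identity_chain(self, noiseless_subject):
        """No noise, flat B1, unit slope, no saturation: signal == truth."""
        np.testing.assert_array_equal(noiseless_subject.signal.data,
                                      noiseless_subject.truth_conc.data)

    def test_regional_truth_means_match_config(self, noiseless_subject):
        """Linear-profile anchoring makes regional truth means exact."""
        t = noiseless_subject.truth_conc.data
        assert t[noiseless_subject.cortex_mask].mean() == pytest.approx(72.0)
        assert t[noiseless_subject.medulla_mask].mean() == pytest.approx(136.0)

    def test_background_noise_is_rayleigh(self, small_cfg):
        """Zero-signal voxels follow a Rayleigh law: mean = sigma*sqrt(pi/2)."""
        sub = sk.generate_subject(small_cfg, seed=3)
        bg = sub.truth_conc.data == 0
        sigma = small_cfg.noise_sigma
        expected = sigma * np.sqrt(np.pi / 2.0)
        assert sub.signal.data[bg].mean() == pytest.approx(expected, rel=0.02)

    def test_uniform_region_noise_sd(self, small_cfg):
        """At high SNR the magnitude noise is ~Gaussian with sd ~ sigma."""
        sub = sk.generate_subject(small_cfg, seed=3)
        ph = sub.phantom_masks[-1]  # 154 mmol/L: SNR ~ 30
        vals = sub.signal.data[ph]
        assert vals.std(ddof=1) == pytest.approx(small_cfg.noise_sigma, rel=0.25)

    def test_masks_partition(self, noiseless_subject):
        s = noiseless_subject
        assert not (s.cortex_mask & s.medulla_mask).any()
        assert ((s.cortex_mask | s.medulla_mask) == s.kidney_mask).all()
        for pm in s.phantom_masks:
            assert not (pm & s.kidney_mask).any()

    def test_truth_affine_in_depth(self, noiseless_subject):
        """With the linear profile, truth is voxelwise affine in depth."""
        from nephna.layers import depth_map
        s = noiseless_subject
        d = depth_map(s.kidney_mask, s.truth_conc.spacing)[s.kidney_mask]
        t = s.truth_conc.data[s.kidney_mask]
        coeffs = np.polyfit(d, t, 1)
        resid = t - np.polyval(coeffs, d)
        assert np.abs(resid).max() < 1e-9
        assert coeffs[0] == pytest.approx(s.true_slope)

    def test_step_profile(self):
        cfg = sk.human_config(profile_kind="step", noise_sigma=0.0,
                              b1_amplitude=0.0, apply_saturation=False,
                              **SMALL_GRID)
        s = sk.generate_subject(cfg, seed=0)
        t = s.truth_conc.data
        assert set(np.unique(t[s.kidney_mask])) == {72.0, 136.0}

    def test_determinism(self, small_cfg):
        a = sk.generate_subject(small_cfg, seed=11)
        b = sk.generate_subject(small_cfg, seed=11)
        c = sk.generate_subject(small_cfg, seed=12)
        np.testing.assert_array_equal(a.signal.data, b.signal.data)
        np.testing.assert_array_equal(a.b1_true.data, b.b1_true.data)
        assert not np.array_equal(a.signal.data, c.signal.data)

    def test_geometry_overflow_names_axis(self):
        geo = sk.KidneyGeometry.from_medulla_fraction((120.0, 28.0, 22.0), 0.33)
        cfg = sk.SubjectConfig(kidney_geometry=geo, **SMALL_GRID)
        with pytest.raises(GeometryError, match="axis 'x'"):
            sk.generate_subject(cfg, seed=0)

    def test_b1_field_amplitude(self, clean_subject):
        b1 = clean_subject.b1_true.data
        assert np.abs(b1 - 1.0).max() == pytest.approx(0.10, abs=1e-9)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            sk.human_config(intersubject_cov=1.5)
        with pytest.raises(ConfigError):
            sk.human_config(noise_sigma=-1.0)
        with pytest.raises(ConfigError):
            sk.human_config(phantom_concs=(50.0, 50.0))
        with pytest.raises(ConfigError):
            sk.human_config(profile_kind="spiral")


class TestCohort:
    def test_empty_cohort(self, small_cfg):
        assert sk.generate_cohort(0, [small_cfg], seed=0) == [[]]

    def test_site_means_and_cov(self):
        """Subject-level truth concentrations track the site means with the
        configured inter-subject coefficient of variation."""
        cfg_a = sk.human_config(medulla_conc=137.0, cortex_conc=72.0, **SMALL_GRID)
        cfg_b = sk.human_config(medulla_conc=133.0, cortex_conc=70.0, **SMALL_GRID)
        # cheap: inspect the drawn configs of a large cohort
        cohort = sk.generate_cohort(25, [cfg_a, cfg_b], seed=5)
        med_a = np.array([s.config.medulla_conc for s in cohort[0]])
        med_b = np.array([s.config.medulla_conc for s in cohort[1]])
        assert med_a.mean() == pytest.approx(137.0, abs=4.0)
        assert med_b.mean() == pytest.approx(133.0, abs=4.0)
        assert cov_percent(np.concatenate([med_a / 137.0, med_b / 133.0])) == \
            pytest.approx(5.0, abs=1.5)

    def test_cohort_reproducible(self, small_cfg):
        a = sk.generate_cohort(2, [small_cfg], seed=9)
        b = sk.generate_cohort(2, [small_cfg], seed=9)
        for s1, s2 in zip(a[0], b[0]):
            np.testing.assert_array_equal(s1.signal.data, s2.signal.data)


class TestDynamic:
    def test_washout_closed_form(self):
        w = sk.WashoutConfig(baseline_medulla=92.0, plateau_medulla=69.0,
                             tau_min=8.0)
        assert w.medulla_at(0.0) == pytest.approx(92.0)
        assert w.medulla_at(8.0) == pytest.approx(92.0 - 23.0 * (1 - np.exp(-1)))
        assert w.medulla_at(30.0) == pytest.approx(69.0, abs=0.6)

    def test_washout_monotone(self):
        w = sk.WashoutConfig()
        t = np.linspace(0, 30, 61)
        m = np.array([w.medulla_at(x) for x in t])
        assert np.all(np.diff(m) < 0)

    def test_truth_endpoints(self, noiseless_cfg):
        study = sk.generate_dynamic_study(
            noiseless_cfg,
            sk.WashoutConfig(baseline_medulla=92.0, plateau_medulla=69.0,
                             tau_min=8.0, cortex_drift=0.0,
                             times_min=(0.0, 30.0)),
            seed=2)
        med0 = study.subjects[0].truth_conc.data[study.subjects[0].medulla_mask].mean()
        med30 = study.subjects[1].truth_conc.data[study.subjects[1].medulla_mask].mean()
        assert med0 == pytest.approx(92.0)
        assert med30 == pytest.approx(69.0, abs=0.6)

    def test_zero_effect(self, noiseless_cfg):
        study = sk.generate_dynamic_study(
            noiseless_cfg,
            sk.WashoutConfig(baseline_medulla=136.0, plateau_medulla=136.0,
                             cortex_drift=0.0, times_min=(0.0, 15.0, 30.0)),
            seed=2)
        for sub in study.subjects[1:]:
            np.testing.assert_allclose(sub.truth_conc.data,
                                       study.subjects[0].truth_conc.data)

    def test_fixed_anatomy_and_b1(self, small_cfg):
        study = sk.generate_dynamic_study(small_cfg, sk.WashoutConfig(
            baseline_medulla=136.0, times_min=(0.0, 30.0)), seed=2)
        np.testing.assert_array_equal(study.subjects[0].kidney_mask,
                                      study.subjects[1].kidney_mask)
        np.testing.assert_array_equal(study.subjects[0].b1_true.data,
                                      study.subjects[1].b1_true.data)

    def test_negative_concentration_rejected(self, noiseless_cfg):
        w = sk.WashoutConfig(baseline_medulla=10.0, plateau_medulla=-40.0,
                             tau_min=3.0, times_min=(0.0, 30.0))
        with pytest.raises(ConfigError, match="non-positive|negative"):
            sk.generate_dynamic_study(noiseless_cfg, w, seed=0)


class TestIRAndSerum:
    def test_full_recovery_limit(self, noiseless_cfg):
        series = sk.generate_ir_series(noiseless_cfg, [10.0, 20.0, 2000.0], seed=0)
        sub = sk.generate_subject(noiseless_cfg, seed=0)
        kidney = sub.kidney_mask
        s0 = sub.truth_conc.data[kidney]
        np.testing.assert_allclose(series.volumes[-1].data[kidney], s0, rtol=1e-6)

    def test_null_point(self, noiseless_cfg):
        ti_null = noiseless_cfg.t1_tissue * np.log(2.0)
        series = sk.generate_ir_series(noiseless_cfg, [5.0, ti_null, 60.0], seed=0)
        sub = sk.generate_subject(noiseless_cfg, seed=0)
        assert np.abs(series.volumes[1].data[sub.kidney_mask]).max() < 1e-9

    def test_serum_flat_and_noisy(self):
        panel = sk.simulate_serum(noise_cv=0.0, seed=1)
        np.testing.assert_array_equal(panel.analytes["sodium"],
                                      np.full(7, 139.0))
        noisy = sk.simulate_serum(noise_cv=0.015, seed=1)
        assert noisy.analytes["sodium"].mean() == pytest.approx(139.0, rel=0.02)

    def test_serum_independent_of_imaging_seed(self):
        p1 = sk.simulate_serum(seed=4)
        p2 = sk.simulate_serum(seed=4)
        np.testing.assert_array_equal(p1.analytes["sodium"], p2.analytes["sodium"])

    def test_max_percent_change_hand_case(self):
        assert max_percent_change([100.0, 99.0, 101.0], 100.0) == pytest.approx(1.0)


def test_write_subject_roundtrip(tmp_path, noiseless_subject):
    from nephna.core import read_nifti
    out = sk.write_subject(noiseless_subject, tmp_path / "sub")
    vol = read_nifti(out / "signal.nii.gz")
    assert vol.spacing == noiseless_subject.signal.spacing
    np.testing.assert_allclose(vol.data, noiseless_subject.signal.data,
                               rtol=1e-6, atol=1e-3)  # float32 storage
    assert (out / "subject.yaml").exists()
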
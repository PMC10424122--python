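"""Synthetic cohort generator: determinism, calibrated signals, motion
spikes, injected effects and the phenotype link."""

import numpy as np
import pandas as pd
import pytest

from couplemap.alff import compute_alff
from couplemap.preproc import Volume4D, compute_fd
from couplemap.synth import (
    CohortConfig,
    EffectRegion,
    MMSEModel,
    default_wm_effect_region,
    generate_bold_timeseries,
    generate_cohort,
    generate_motion,
    generate_subject,
    load_cohort,
    write_cohort,
)
from couplemap.validation import dft_alff_oracle


class TestDeterminism:
    def test_same_config_same_seed_bit_identical(self, tiny_cohort_config):
        a, pheno_a = generate_cohort(tiny_cohort_config)
        b, pheno_b = generate_cohort(tiny_cohort_config)
        for sa, sb in zip(a, b):
            assert sa.bold.data.tobytes() == sb.bold.data.tobytes()
            assert sa.tpm_wm.tobytes() == sb.tpm_wm.tobytes()
            assert sa.motion.params.tobytes() == sb.motion.params.tobytes()
        pd.testing.assert_frame_equal(pheno_a, pheno_b)

    def test_subject_reproducible_in_isolation(self, tiny_cohort_config):
        cohort, _ = generate_cohort(tiny_cohort_config)
        s3 = generate_subject(tiny_cohort_config, 3, "VMCI")
        assert s3.bold.data.tobytes() == cohort[3].bold.data.tobytes()

    def test_different_seed_differs(self, tiny_cohort_config):
        import dataclasses

        other = dataclasses.replace(tiny_cohort_config, seed=99)
        a = generate_subject(tiny_cohort_config, 0, "NC")
        b = generate_subject(other, 0, "NC")
        assert a.bold.data.tobytes() != b.bold.data.tobytes()


class TestPhenotypeTable:
    def test_group_sizes_match_study_cohort(self):
        cfg = CohortConfig(n_per_group=(100, 90, 53), grid_shape=(8, 8, 8),
                           n_timepoints=16, band_hz=(0.03, 0.1), seed=5)
        _, pheno = generate_cohort(cfg)
        assert len(pheno) == 243
        counts = pheno["group"].value_counts()
        assert counts["NC"] == 100 and counts["VMCI"] == 90 and counts["MCI"] == 53
        assert set(pheno.columns) == {"subject", "group", "age", "gender",
                                      "education", "mmse", "cdr"}
        assert dict(pheno.groupby("group")["cdr"].first()) == {
            "NC": 0.0, "VMCI": 0.5, "MCI": 1.0}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=(1, 3, 3))
        with pytest.raises(ValueError):
            CohortConfig(grid_shape=(6, 8, 8))
        with pytest.raises(ValueError):
            CohortConfig(tr_s=-1.0)
        with pytest.raises(ValueError):
            CohortConfig(band_hz=(0.01, 0.3))  # above Nyquist for TR 2.2
        with pytest.raises(ValueError):
            CohortConfig(effect_regions=[
                EffectRegion((50, 50, 50), 2, "alff", (0, 0, 0))])

    def test_config_json_roundtrip(self):
        cfg = CohortConfig(
            n_per_group=(4, 4, 4), grid_shape=(10, 10, 10),
            effect_regions=[EffectRegion((5, 5, 5), 2.0, "coupling", (0, 0.1, 0.2))],
            mmse_model=MMSEModel(slope=-3.0, residual_sd=1.5), seed=42)
        assert CohortConfig.from_json(cfg.to_json()) == cfg


class TestBoldTimeseries:
    def test_zero_amplitude_zero_noise_gives_zeros(self):
        y = generate_bold_timeseries(64, 2.2, band_amplitude=0.0, noise_sd=0.0)
        assert np.abs(y).max() == 0.0

    def test_amplitude_linearity(self):
        y1 = generate_bold_timeseries(164, 2.2, 1.0, noise_sd=0.0, seed=7)
        y2 = generate_bold_timeseries(164, 2.2, 2.0, noise_sd=0.0, seed=7)
        np.testing.assert_allclose(y2, 2.0 * y1, atol=1e-12)

    def test_alff_recovers_configured_amplitude(self, make_vol):
        # every in-band bin carries the configured amplitude, so ALFF (and
        # the brute-force DFT oracle) return it exactly
        target = 1.37
        y = generate_bold_timeseries(164, 2.2, target, noise_sd=0.0, seed=3)
        vol = make_vol(y.reshape(1, 1, 1, -1), tr_s=2.2)
        assert compute_alff(vol).data[0, 0, 0] == pytest.approx(target, rel=0.01)
        assert dft_alff_oracle(y, 2.2) == pytest.approx(target, rel=0.01)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            generate_bold_timeseries(64, 2.2, 1.0, band_hz=(0.01, 0.25))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            generate_bold_timeseries(8, 2.2, 1.0)


class TestMotion:
    def test_no_spikes_keeps_fd_below_threshold(self):
        trace = generate_motion(164, spike_rate=0.0, seed=1)
        assert trace.fd.max() < 1.0
        assert not trace.flagged.any()

    def test_forced_spike_flags_exactly_that_frame(self):
        # deterministic construction: a persistent 2 mm step at one frame
        params = np.zeros((50, 6))
        params[20:, 0] += 2.0
        fd = compute_fd(params)
        assert (fd > 1.0).nonzero()[0].tolist() == [20]

    def test_spike_rate_matches_binomial_expectation(self):
        rate, n, reps = 0.05, 164, 100
        flagged = sum(generate_motion(n, rate, seed=s).flagged.sum()
                      for s in range(reps))
        frames = reps * (n - 1)  # frame 0 can never be flagged
        se = np.sqrt(rate * (1 - rate) / frames)
        assert abs(flagged / frames - rate) < 3 * se

    def test_subthreshold_spike_magnitude_rejected(self):
        with pytest.raises(ValueError):
            generate_motion(64, 0.1, spike_magnitude_mm=0.5)


class TestInjectedEffects:
    def test_null_effect_gives_null_group_difference(self):
        # delta = 0 everywhere: regional ALFF group difference ~ 0 over replicates
        region = EffectRegion((4, 4, 4), 2.0, "alff", (0.0, 0.0, 0.0))
        diffs = []
        for rep in range(50):
            cfg = CohortConfig(n_per_group=(2, 2, 2), grid_shape=(8, 8, 8),
                               n_timepoints=32, effect_regions=[region],
                               noise_sd=0.1, seed=1000 + rep)
            cohort, pheno = generate_cohort(cfg)
            m = region.mask(cfg.grid_shape)
            vals = [compute_alff(s.bold, m, cfg.band_hz).data[m].mean()
                    for s in cohort]
            vals = np.asarray(vals)
            g = pheno["group"].to_numpy()
            diffs.append(vals[g == "MCI"].mean() - vals[g == "NC"].mean())
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_alff_effect_realized_as_group_difference(self):
        # noiseless cohort: group difference of regional ALFF equals delta
        delta = 0.25
        region = EffectRegion((4, 4, 4), 2.0, "alff", (0.0, 0.1, delta))
        cfg = CohortConfig(n_per_group=(4, 4, 4), grid_shape=(8, 8, 8),
                           n_timepoints=64, effect_regions=[region],
                           noise_sd=0.0, subject_amplitude_sd=0.0, seed=3)
        cohort, pheno = generate_cohort(cfg)
        m = region.mask(cfg.grid_shape)
        vals = np.asarray([compute_alff(s.bold, m, cfg.band_hz).data[m].mean()
                           for s in cohort])
        g = pheno["group"].to_numpy()
        gap = vals[g == "MCI"].mean() - vals[g == "NC"].mean()
        assert gap == pytest.approx(delta, rel=0.02)

    def test_vbm_effect_reduces_density(self):
        delta = 0.2
        region = default_wm_effect_region((12, 12, 12), (0.0, 0.1, delta),
                                          modality="vbm", radius_vox=1.5)
        cfg = CohortConfig(n_per_group=(2, 2, 2), grid_shape=(12, 12, 12),
                           n_timepoints=16, band_hz=(0.03, 0.1),
                           effect_regions=[region], seed=8)
        nc = generate_subject(cfg, 0, "NC")
        mci = generate_subject(cfg, 0, "MCI")  # same stream, different group
        m = region.mask(cfg.grid_shape) & (nc.tpm_wm > delta)  # no clipping
        assert m.any()
        np.testing.assert_allclose(mci.tpm_wm[m], nc.tpm_wm[m] - delta,
                                   atol=1e-12)

    def test_mmse_tracks_latent_coupling(self):
        # with a strong configured link, corr(latent coupling, MMSE) matches
        # the model-implied correlation
        region = default_wm_effect_region((8, 8, 8), (0.0, 0.0, 0.0))
        model = MMSEModel(slope=-30.0, residual_sd=1.0,
                          group_means={"NC": 25.0, "VMCI": 25.0, "MCI": 25.0})
        cfg = CohortConfig(n_per_group=(500, 2, 2), grid_shape=(8, 8, 8),
                           n_timepoints=16, band_hz=(0.03, 0.1),
                           effect_regions=[region], mmse_model=model, seed=21)
        cohort, pheno = generate_cohort(cfg)
        sel = pheno["group"] == "NC"
        latent = np.asarray([s.latent["regional_coupling"] for s in cohort])[sel]
        mmse = pheno.loc[sel, "mmse"].to_numpy()
        sd_c = latent.std(ddof=1)
        implied = model.slope * sd_c / np.hypot(model.slope * sd_c, model.residual_sd)
        observed = np.corrcoef(latent, mmse)[0, 1]
        assert observed == pytest.approx(implied, abs=0.05)


class TestCohortIO:
    def test_write_load_roundtrip(self, tmp_path, tiny_cohort_config):
        cohort, pheno = generate_cohort(tiny_cohort_config)
        write_cohort(cohort, pheno, tiny_cohort_config, tmp_path / "cohort")
        loaded, pheno2, cfg2 = load_cohort(tmp_path / "cohort")
        assert cfg2 == tiny_cohort_config
        assert len(loaded) == len(cohort)
        np.testing.assert_allclose(loaded[0].bold.data, cohort[0].bold.data,
                                   rtol=1e-6)
        np.testing.assert_allclose(loaded[2].tpm_gm, cohort[2].tpm_gm, atol=1e-6)
        np.testing.assert_allclose(loaded[1].motion.params, cohort[1].motion.params)
        pd.testing.assert_frame_equal(
            pheno2, pheno, check_exact=False, rtol=1e-6)
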
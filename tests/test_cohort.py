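import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from asymvbm.asymmetry import compute_ai, flip_lr, make_right_mask
from asymvbm.cohort import (
    CohortConfig,
    EffectSpec,
    GroundTruthManifest,
    default_template_blobs,
    effect_region_mask,
    generate_phenotypes,
    generate_subject_volume,
    generate_template,
    latent_ai,
    simulate_cohort,
)


class TestConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(subgroup_proportions=(0.5, 0.3, 0.3))

    def test_odd_midline_grid_rejected(self):
        with pytest.raises(ValueError, match="even"):
            CohortConfig(grid_shape=(15, 14, 14))

    def test_effect_outside_grid_rejected(self, tiny_config):
        eff = EffectSpec(region_center=(100.0, 0.0, 0.0), region_radius=9.0, delta=0.1)
        with pytest.raises(ValueError, match="outside"):
            eff.validate_against(tiny_config)

    def test_effect_delta_bound(self):
        with pytest.raises(ValueError):
            EffectSpec(region_center=(10, 0, 0), region_radius=9.0, delta=1.5)


class TestPhenotypes:
    def test_deterministic(self, tiny_config):
        a = generate_phenotypes(tiny_config)
        b = generate_phenotypes(tiny_config)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_proportions_all_si(self):
        cfg = CohortConfig(n_asd=25, n_td=0, subgroup_proportions=(1.0, 0.0, 0.0))
        pheno = generate_phenotypes(cfg)
        assert (pheno["TRUE_SUBGROUP"] == "SI").all()

    def test_empirical_fractions_near_target(self):
        # binomial check: n=200 draws from (0.635, 0.187, 0.178); each
        # empirical fraction within +/- 5 percentage points
        cfg = CohortConfig(n_asd=200, n_td=0, seed=0)
        pheno = generate_phenotypes(cfg)
        fractions = pheno["TRUE_SUBGROUP"].value_counts(normalize=True)
        for label, target in zip(("SI", "VA", "RRB"), cfg.subgroup_proportions):
            assert abs(fractions.get(label, 0.0) - target) < 0.05

    def test_td_rows_carry_no_adir(self, tiny_config):
        pheno = generate_phenotypes(tiny_config)
        td = pheno[pheno["DX_GROUP"] == 2]
        assert td["ADI_R_SOCIAL_TOTAL_A"].isna().all()
        assert td["ADI_R_VERBAL_TOTAL_BV"].isna().all()
        assert td["ADI_RRB_TOTAL_C"].isna().all()

    def test_asd_scores_within_instrument_ranges(self, tiny_config):
        pheno = generate_phenotypes(tiny_config)
        asd = pheno[pheno["DX_GROUP"] == 1]
        for col, mx in zip(
            ("ADI_R_SOCIAL_TOTAL_A", "ADI_R_VERBAL_TOTAL_BV", "ADI_RRB_TOTAL_C"),
            tiny_config.max_scores,
        ):
            assert (asd[col] >= 0).all() and (asd[col] <= mx).all()
            assert (asd[col] == asd[col].round()).all()

    def test_sites_unequal(self):
        cfg = CohortConfig(n_asd=120, n_td=120, n_sites=5, seed=5)
        counts = generate_phenotypes(cfg)["SITE_ID"].value_counts()
        assert len(counts) == 5
        assert counts.nunique() > 1


class TestTemplate:
    def test_template_equals_own_flip(self, tiny_config):
        template = generate_template(tiny_config, default_template_blobs(tiny_config))
        assert np.array_equal(flip_lr(template).data, template.data)

    def test_empty_blobs_all_zero(self, tiny_config):
        template = generate_template(tiny_config, [])
        assert np.all(template.data == 0.0)

    def test_gaussian_peak_value(self):
        # blob centered exactly on a voxel center (13.5, 1.5, 1.5 are all
        # column centers on a 16-wide 3 mm grid): the value there is the
        # amplitude; the mirrored blob's contribution is ~1e-10
        cfg = CohortConfig(grid_shape=(16, 16, 16), voxel_size=3.0)
        blob = {"center": (13.5, 1.5, 1.5), "sigma": 4.0, "amplitude": 0.8}
        template = generate_template(cfg, [blob])
        xs = cfg.affine[0, 0] * np.arange(16) + cfg.affine[0, 3]
        i = int(np.flatnonzero(xs == 13.5)[0])
        j = int(np.flatnonzero(xs == 1.5)[0])
        assert template.data[i, j, j] == pytest.approx(0.8, abs=1e-6)

    def test_blob_outside_grid_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="outside"):
            generate_template(
                tiny_config,
                [{"center": (500.0, 0, 0), "sigma": 5.0, "amplitude": 0.5}],
            )

    def test_values_clipped(self, tiny_config):
        blobs = [
            {"center": (6.0, 0, 0), "sigma": 50.0, "amplitude": 3.0},
        ]
        template = generate_template(tiny_config, blobs)
        assert template.data.max() <= 1.0


class TestSubjectVolume:
    def test_no_effects_no_noise_equals_template(self, tiny_config):
        cohort = simulate_cohort(tiny_config, [])
        sid = cohort.phenotypes["SUB_ID"].iloc[0]
        vol = cohort.subject_volume(sid)
        assert np.array_equal(vol.data, cohort.template.data)

    def test_rightward_delta_raises_right_regional_mean(self, tiny_config):
        eff = EffectSpec(region_center=(9.0, 0.0, 0.0), region_radius=6.0, delta=0.2)
        cohort = simulate_cohort(tiny_config, [eff])
        asd_id = cohort.phenotypes.loc[
            cohort.phenotypes["DX_GROUP"] == 1, "SUB_ID"
        ].iloc[0]
        vol = cohort.subject_volume(asd_id)
        right = effect_region_mask(tiny_config, eff)
        left = effect_region_mask(tiny_config, dataclasses.replace(eff, side="left"))
        assert vol.data[right].mean() > vol.data[left].mean()

    def test_regional_ai_matches_analytic_value(self):
        # plug the multiplicative effect into the AI formula: scaling one
        # hemisphere by (1+delta) gives AI = 2*delta/(2+delta); the sample
        # mean over subjects with default noise must land within +/- 20%
        delta = 0.2
        cfg = CohortConfig(
            n_asd=40, n_td=0, n_sites=2, grid_shape=(16, 18, 16), seed=21,
        )
        eff = EffectSpec(
            region_center=(12.0, 0.0, 0.0), region_radius=9.0, delta=delta,
            subject_sd=0.0,
        )
        cohort = simulate_cohort(cfg, [eff])
        mask = make_right_mask(cohort.template, 0.2)
        region = effect_region_mask(cfg, eff) & mask.data
        means = []
        for _, vol in cohort.iter_volumes():
            ai = compute_ai(vol, flip_lr(vol), mask)  # raw (unsmoothed) AI
            means.append(ai.data[region].mean())
        analytic = 2 * delta / (2 + delta)
        assert np.mean(means) == pytest.approx(analytic, rel=0.20)

    def test_null_mean_ai_near_zero(self):
        # no injected effects: mean AI in a 5 mm ball within 3 SE of 0
        cfg = CohortConfig(
            n_asd=50, n_td=50, n_sites=2, grid_shape=(16, 18, 16), seed=31,
        )
        cohort = simulate_cohort(cfg, [])
        mask = make_right_mask(cohort.template, 0.2)
        probe = EffectSpec(region_center=(12.0, 0.0, 0.0), region_radius=5.0,
                           delta=0.0)
        ball = effect_region_mask(cfg, probe) & mask.data
        means = [
            compute_ai(v, flip_lr(v), mask).data[ball].mean()
            for _, v in cohort.iter_volumes()
        ]
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se


class TestManifest:
    def test_manifest_bit_exact_reproduction(self, small_config):
        eff = EffectSpec(
            region_center=(12.0, 0.0, 0.0), region_radius=9.0, delta=0.15,
            subject_sd=0.05,
        )
        a = simulate_cohort(small_config, [eff]).manifest
        b = simulate_cohort(small_config, [eff]).manifest
        assert a.latents == b.latents
        assert a.deltas == b.deltas

    def test_manifest_roundtrip(self, small_config, tmp_path):
        eff = EffectSpec(
            region_center=(12.0, 0.0, 0.0), region_radius=9.0, delta=0.15,
            subject_sd=0.05, behavior_coupling=("ADOS_SOCIAL", -0.2),
        )
        manifest = simulate_cohort(small_config, [eff]).manifest
        path = tmp_path / "gt.json"
        manifest.to_json(str(path))
        loaded = GroundTruthManifest.from_json(str(path))
        assert loaded.latents == manifest.latents
        assert loaded.effects[0].behavior_coupling == ("ADOS_SOCIAL", -0.2)

    def test_latent_matches_delta_formula(self, small_config):
        eff = EffectSpec(region_center=(12.0, 0.0, 0.0), region_radius=9.0,
                         delta=0.15)
        manifest = simulate_cohort(small_config, [eff]).manifest
        for sid, latmap in manifest.latents.items():
            for name, lat in latmap.items():
                d = manifest.deltas[sid][name]
                assert lat == pytest.approx(latent_ai(d))

    def test_ados_coupling_sign(self):
        cfg = CohortConfig(n_asd=80, n_td=0, n_sites=2, grid_shape=(12, 14, 12),
                           ados_fraction=1.0, seed=17)
        eff = EffectSpec(
            region_center=(9.0, 0.0, 0.0), region_radius=6.0, delta=0.1,
            subject_sd=0.08, behavior_coupling=("ADOS_SOCIAL", -0.5),
        )
        cohort = simulate_cohort(cfg, [eff])
        lat = np.array(
            [cohort.manifest.latents[s][eff.name]
             for s in cohort.phenotypes["SUB_ID"]]
        )
        ados = cohort.phenotypes["ADOS_SOCIAL"].to_numpy(float)
        r = np.corrcoef(lat, ados)[0, 1]
        assert r < 0
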
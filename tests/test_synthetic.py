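import numpy as np
import pytest
from scipy import special

from cytodmri.biexp import BiexpParams, predict_signal
from cytodmri.errors import ConfigurationError, PackingError
from cytodmri.regional import grid_cell_area_density
from cytodmri.synthetic import (
    CouplingSpec,
    RegionSpec,
    StudyConfig,
    _rasterize_ellipse,
    default_region_specs,
    generate_diffusion_region,
    generate_histology_section,
    generate_study,
    make_protocol,
    reduced_protocol,
    reduced_study_config,
    rician_noise,
    study_protocol,
)


def spec(**kw):
    base = dict(name="toy", region_class="cortical", mean_cell_radius_um=10.0,
                radius_cv=0.3, target_density=0.2, density_gradient=1.0)
    base.update(kw)
    return RegionSpec(**base)


class TestProtocols:
    def test_study_protocol_shape(self):
        gt = study_protocol()
        assert len(gt) == 191
        assert int(gt.b0_mask.sum()) == 11
        np.testing.assert_allclose(gt.shells(), [1000.0, 2000.0, 3000.0])
        norms = np.linalg.norm(gt.bvecs[~gt.b0_mask], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_directions_well_spread(self):
        gt = make_protocol(1, 60, shells=(1000.0,))
        dirs = gt.bvecs[1:]
        gram = np.abs(dirs @ dirs.T) - np.eye(60)
        # no two of the 60 directions nearly parallel (or antiparallel)
        assert gram.max() < 0.99


class TestSectionGenerator:
    def test_zero_density_blank(self):
        sec = generate_histology_section(spec(target_density=0.0), shape=(64, 64), seed=0)
        assert sec.cell_mask.sum() == 0
        assert sec.density_true == 0.0

    def test_density_close_to_target(self):
        for target in (0.05, 0.15, 0.30):
            sec = generate_histology_section(
                spec(target_density=target), shape=(256, 256), seed=1
            )
            assert sec.density_true == pytest.approx(target, rel=0.10)

    def test_rasterized_disk_area_within_perimeter_bound(self):
        for r in (3.0, 5.0, 9.5):
            mask = np.zeros((64, 64), bool)
            count = _rasterize_ellipse(mask, 32.0, 32.0, r, r, 0.0)
            assert abs(count - np.pi * r**2) <= 4 * r

    def test_determinism(self):
        s1 = generate_histology_section(spec(), shape=(96, 96), seed=42)
        s2 = generate_histology_section(spec(), shape=(96, 96), seed=42)
        np.testing.assert_array_equal(s1.image, s2.image)
        np.testing.assert_array_equal(s1.cell_mask, s2.cell_mask)

    def test_gradient_raises_grid_variance(self):
        """Patchy placement must raise grid-square density variance."""
        hets = {0.0: [], 5.0: []}
        for g in hets:
            for seed in range(20):
                sec = generate_histology_section(
                    spec(density_gradient=g), shape=(240, 240), seed=seed,
                    field_corr_px=80.0,
                )
                _, het, _ = grid_cell_area_density(
                    sec.cell_mask, sec.roi_mask, sec.pixel_size_um, grid_size_mm=0.32
                )
                hets[g].append(het)
        assert np.mean(hets[5.0]) > np.mean(hets[0.0])

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_histology_section(
                spec(target_density=0.6, mean_cell_radius_um=24.0, radius_cv=0.0),
                shape=(64, 64), seed=0, max_attempt_factor=1,
            )


class TestDiffusionGenerator:
    def test_noise_free_matches_forward_model(self):
        """Generator signals equal the voxel-wise closed-form prediction."""
        coup = CouplingSpec(noise_snr=np.inf)
        gt = reduced_protocol()
        sig, truth = generate_diffusion_region(spec(), coup, gt, (2, 2, 2), seed=0)
        for v in range(sig.shape[0]):
            p = BiexpParams(
                s0=truth["s0"][v], f_iso=truth["f_iso"][v], w=truth["w"][v],
                lam_f=np.full(3, truth["md_fast"][v]),
                lam_s=np.full(3, truth["md_slow"][v]),
                d_iso=coup.d_iso,
            )
            np.testing.assert_allclose(sig[v], predict_signal(p, gt), rtol=1e-12)

    def test_rician_mean_closed_form(self):
        """Sample mean of |S + e1 + i e2| matches the analytic Rician mean."""
        s0, snr = 100.0, 20.0
        sigma = s0 / snr
        rng = np.random.default_rng(7)
        draws = rician_noise(np.full(10_000, s0), sigma, rng)
        # E|X| = sigma sqrt(pi/2) L_{1/2}(-snr^2/2), L via Kummer's function
        analytic = sigma * np.sqrt(np.pi / 2) * special.hyp1f1(-0.5, 1.0, -(snr**2) / 2)
        assert draws.mean() == pytest.approx(analytic, rel=0.005)

    def test_nonpositive_diffusivity_rejected(self):
        coup = CouplingSpec(kappa=30.0)  # MD(d) < 0 at low density
        with pytest.raises(ConfigurationError):
            generate_diffusion_region(
                spec(target_density=0.05, density_gradient=3.0),
                coup, reduced_protocol(), (3, 3, 3), seed=0,
            )


class TestStudyGenerator:
    def test_default_specs_cover_study_design(self):
        specs = default_region_specs()
        assert len(specs) == 9
        assert sum(s.region_class == "cortical" for s in specs) == 6
        assert sum(s.region_class == "subcortical" for s in specs) == 3

    def test_determinism_and_subject_independence(self):
        cfg = StudyConfig(n_subjects=2, block_shape=(2, 2, 2),
                          grid_squares=(2, 2), grid_size_mm=0.16)
        specs = default_region_specs()[:2]
        a = generate_study(9, region_specs=specs, gtab=reduced_protocol(), config=cfg)
        b = generate_study(9, region_specs=specs, gtab=reduced_protocol(), config=cfg)
        for s in a.subjects:
            np.testing.assert_array_equal(a.volumes[s].signal, b.volumes[s].signal)
        assert not np.array_equal(
            a.volumes["sub-01"].signal, a.volumes["sub-02"].signal
        )

    def test_minimal_study_accepted(self):
        cfg = StudyConfig(n_subjects=1, block_shape=(2, 2, 2),
                          grid_squares=(2, 2), grid_size_mm=0.16)
        study = generate_study(3, region_specs=default_region_specs()[:1],
                               gtab=reduced_protocol(), config=cfg)
        assert study.subjects == ["sub-01"]
        assert study.labels["sub-01"].region_labels == [1]

    def test_round_trip_on_disk(self, tmp_path):
        from cytodmri.io import read_gradient_table, read_label_volume, read_region_spec
        from cytodmri.synthetic import write_study

        cfg = StudyConfig(n_subjects=1, block_shape=(2, 2, 2),
                          grid_squares=(2, 2), grid_size_mm=0.16)
        study = generate_study(3, region_specs=default_region_specs()[:2],
                               gtab=reduced_protocol(), config=cfg)
        write_study(study, tmp_path)
        gt = read_gradient_table(tmp_path / "protocol.bval", tmp_path / "protocol.bvec")
        np.testing.assert_allclose(gt.bvals, study.gtab.bvals)
        table = read_region_spec(tmp_path / "regions.csv")
        lv = read_label_volume(tmp_path / "sub-01_labels.nii.gz", table)
        np.testing.assert_array_equal(lv.labels, study.labels["sub-01"].labels)
        assert (tmp_path / "generator_config.json").exists()


class TestReducedConfig:
    def test_reduced_config_shapes(self):
        cfg = reduced_study_config()
        assert cfg.block_shape == (3, 3, 3)
        side = int(round(cfg.grid_mm * 1000 / cfg.pixel_size_um))
        assert cfg.section_shape == (3 * side, 3 * side)
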
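"""Phantom generator: presets, geometry ledger, imaging model."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from wallfibril3d.phantom import (GroundTruth, PhantomSpec, apply_imaging_model,
                                  compute_pair_table, generate_wall_phantom,
                                  make_preset, write_ground_truth)
from tests.conftest import straight_fibril


class TestPresets:
    # printed study measurements the presets must carry (nm)
    @pytest.mark.parametrize("name,diam,gap,xlink", [
        ("chem", (4.3, 1.3), (17.0, 4.3), (5.6, 2.1)),
        ("hpf", (4.9, 1.4), (6.9, 2.1), (4.6, 1.5)),
        ("cryo", (5.0, 1.5), (6.4, 1.2), (5.0, 1.5)),
        ("wt_hypocotyl", (4.5, 0.9), (5.2, 2.0), (4.2, 0.8)),
        ("cob6", (4.6, 0.8), (8.9, 3.8), (4.7, 0.8)),
    ])
    def test_preset_values(self, name, diam, gap, xlink):
        s = make_preset(name)
        assert (s.fibril_diameter_mean, s.fibril_diameter_sd) == diam
        assert (s.edge_gap_mean, s.edge_gap_sd) == gap
        assert (s.crosslink_length_mean, s.crosslink_length_sd) == xlink
        assert s.voxel_size == 0.87
        assert s.shape_voxels == (500, 500, 75)

    def test_cryo_contrast_mode(self):
        assert make_preset("cryo").contrast_mode == "cryo"
        assert make_preset("hpf").contrast_mode == "stained"

    def test_extracted_has_no_crosslinks(self):
        assert make_preset("extracted").crosslink_density == 0

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset.*cryo"):
            make_preset("bogus")

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            make_preset("cryo", voxel_size=-1)
        with pytest.raises(ValueError):
            make_preset("cryo", missing_wedge_halfangle_deg=120)


class TestGeometry:
    def test_two_fibril_pair_row(self):
        # analytic cylinder pair: centres 10 nm apart, radii 2.5 nm
        fa = straight_fibril(0, 10.0, 10.0, 2.5, 0, 50.0)
        fb = straight_fibril(1, 10.0, 20.0, 2.5, 0, 50.0)
        table = compute_pair_table([fa, fb], (0.0, 50.0))
        row = table.iloc[0]
        assert row["kind"] == "within_layer"
        assert row["center_nm"] == pytest.approx(10.0, abs=1e-9)
        assert row["edge_nm"] == pytest.approx(5.0, abs=1e-9)

    def test_determinism(self):
        spec = make_preset("cryo", shape_voxels=(96, 96, 40), seed=7)
        v1, t1 = generate_wall_phantom(spec)
        v2, t2 = generate_wall_phantom(make_preset("cryo", shape_voxels=(96, 96, 40), seed=7))
        assert np.array_equal(v1.data, v2.data)
        assert len(t1.fibrils) == len(t2.fibrils)
        assert np.allclose(t1.pair_table["center_nm"], t2.pair_table["center_nm"])

    def test_pair_identity_everywhere(self, small_cryo_phantom):
        _, truth, _ = small_cryo_phantom
        radius = {f.fibril_id: f.radius for f in truth.fibrils}
        t = truth.pair_table
        resid = (t["center_nm"] - t["edge_nm"]
                 - t["fibril_i"].map(radius) - t["fibril_j"].map(radius))
        assert np.abs(resid).max() < 1e-6

    def test_diameter_moments(self, small_cryo_phantom):
        # CLT bound on the generator's own truncated-normal draws
        _, truth, spec = small_cryo_phantom
        d = truth.diameters()
        a = (2.2 - spec.fibril_diameter_mean) / spec.fibril_diameter_sd
        expected = sps.truncnorm.mean(a, np.inf, loc=spec.fibril_diameter_mean,
                                      scale=spec.fibril_diameter_sd)
        se = spec.fibril_diameter_sd / np.sqrt(len(d))
        assert abs(d.mean() - expected) < 3 * se

    def test_gap_moments(self, small_cryo_phantom):
        _, truth, spec = small_cryo_phantom
        g = truth.drawn_gaps
        a = (2.0 - spec.edge_gap_mean) / spec.edge_gap_sd
        expected = sps.truncnorm.mean(a, np.inf, loc=spec.edge_gap_mean,
                                      scale=spec.edge_gap_sd)
        se = spec.edge_gap_sd / np.sqrt(len(g))
        assert abs(g.mean() - expected) < 3 * se

    def test_crosslink_endpoints_on_surfaces(self, small_cryo_phantom):
        _, truth, spec = small_cryo_phantom
        assert len(truth.crosslinks) > 0
        worst = 0.0
        for c in truth.crosslinks:
            for fid, p in ((c.fibril_i, c.point_i), (c.fibril_j, c.point_j)):
                f = truth.fibrils[fid]
                w = p - f.vertices[0]
                perp = w - (w @ f.direction) * f.direction
                worst = max(worst, abs(np.linalg.norm(perp) - f.radius))
        assert worst < 0.25 * spec.voxel_size

    def test_crosslink_length_matches_endpoints(self, small_cryo_phantom):
        _, truth, _ = small_cryo_phantom
        for c in truth.crosslinks:
            assert c.length == pytest.approx(np.linalg.norm(c.point_j - c.point_i), abs=1e-9)

    def test_zero_density_empty_crosslinks(self):
        spec = make_preset("extracted", shape_voxels=(96, 96, 40), seed=3)
        _, truth = generate_wall_phantom(spec)
        assert truth.crosslinks == []

    def test_fibrils_do_not_interpenetrate(self, small_cryo_phantom):
        _, truth, _ = small_cryo_phantom
        assert (truth.pair_table["edge_nm"] > 0).all()

    def test_truth_written_as_csv(self, small_cryo_phantom, tmp_path):
        _, truth, spec = small_cryo_phantom
        out = write_ground_truth(truth, spec, tmp_path)
        for name in ("fibrils.csv", "crosslinks.csv", "pairs.csv", "phantom_spec.json"):
            assert (out / name).exists()


class TestImagingModel:
    def test_identity_limit(self):
        spec = PhantomSpec(shape_voxels=(32, 32, 32), psf_sigma=0.0,
                           snr=np.inf, missing_wedge_halfangle_deg=90.0,
                           contrast_mode="stained", seed=1)
        vol, truth = generate_wall_phantom(spec)
        out = apply_imaging_model(vol, spec, truth)
        assert np.allclose(out.data, vol.data, atol=1e-6)

    def test_cryo_mode_inverts_contrast(self):
        spec = make_preset("cryo", shape_voxels=(48, 48, 32), seed=1,
                           psf_sigma=0.0, snr=np.inf,
                           missing_wedge_halfangle_deg=90.0)
        vol, truth = generate_wall_phantom(spec)
        out = apply_imaging_model(vol, spec, truth)
        assert np.allclose(out.data, -vol.data, atol=1e-6)

    def test_noise_level(self):
        # snr = 3 on a flat background: sd within 5% of contrast/3
        spec = PhantomSpec(shape_voxels=(48, 48, 48), psf_sigma=0.0, snr=3.0,
                           missing_wedge_halfangle_deg=90.0,
                           contrast_mode="stained", seed=5)
        flat = np.zeros((48, 48, 48), np.float32)
        from wallfibril3d.volume import DensityVolume
        out = apply_imaging_model(DensityVolume(flat, spec.voxel_size), spec)
        assert out.data.std() == pytest.approx(1.0 / 3.0, rel=0.05)

    def test_missing_wedge_elongates_axially(self):
        # sphere phantom: axial (z) half-max width grows past lateral (x)
        from wallfibril3d.volume import DensityVolume
        z, y, x = np.mgrid[0:48, 0:48, 0:48].astype(float)
        r = np.sqrt((z - 24) ** 2 + (y - 24) ** 2 + (x - 24) ** 2)
        sphere = (r <= 6).astype(np.float32)
        spec = PhantomSpec(shape_voxels=(48, 48, 48), psf_sigma=0.0, snr=np.inf,
                           missing_wedge_halfangle_deg=60.0,
                           contrast_mode="stained", seed=0)
        out = np.clip(apply_imaging_model(DensityVolume(sphere, 1.0), spec).data, 0, None)

        def rms_width(profile):
            w = profile / profile.sum()
            c = np.arange(len(profile))
            mu = (w * c).sum()
            return np.sqrt((w * (c - mu) ** 2).sum())

        axial = rms_width(out[:, 24, 24])
        lateral = rms_width(out[24, 24, :])
        assert axial / lateral > 1.05

    def test_stained_mode_plants_blobs(self):
        spec = PhantomSpec(shape_voxels=(64, 64, 48), contrast_mode="stained",
                           artifact_blob_rate=0.05, psf_sigma=0.0, snr=np.inf,
                           missing_wedge_halfangle_deg=90.0, seed=2)
        vol, truth = generate_wall_phantom(spec)
        out = apply_imaging_model(vol, spec, truth)
        assert len(truth.artifacts) > 0
        assert not np.allclose(out.data, vol.data)

    def test_nonfinite_input_rejected(self):
        spec = PhantomSpec(shape_voxels=(16, 16, 16), seed=0)
        from wallfibril3d.volume import DensityVolume
        bad = DensityVolume(np.full((16, 16, 16), np.nan, np.float32), 0.87)
        with pytest.raises(ValueError):
            apply_imaging_model(bad, spec)
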
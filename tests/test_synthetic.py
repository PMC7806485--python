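"""Simulator contracts: geometry, channel rendering, attenuation, noise."""

import json
import math

import numpy as np
import pytest

from shgmorph import (
    NoiseModel,
    SimulationConfig,
    apply_attenuation_and_noise,
    generate_fiber_geometry,
    preset_config,
    render_channels,
    sham_twin,
    simulate,
)
from shgmorph.synthetic import GroundTruth

NOISELESS = NoiseModel(poisson=False, read_noise_sd=0.0, offset=0.0)


def small_config(**kw):
    base = dict(
        volume_shape=(96, 96, 12),
        voxel_size=(0.7, 0.7, 4.0),
        seed=3,
        noise=NOISELESS,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGeometry:
    def test_single_fiber_spans_small_volume(self):
        cfg = small_config(volume_shape=(48, 48, 6), fiber_diameter_mean=400.0,
                           fiber_diameter_sd=0.0)
        truth = generate_fiber_geometry(cfg)
        labels = np.unique(truth.fiber_label_map)
        assert list(labels) == [1]
        assert truth.tissue_mask.all()

    def test_zero_radius_necrosis_is_empty(self):
        cfg = small_config(necrosis_mask_spec={"radii_um": (0, 0, 0)})
        truth = generate_fiber_geometry(cfg)
        assert not truth.necrosis_mask.any()

    def test_target_fraction_hit_by_voxel_count(self):
        cfg = preset_config("ctx", seed=2, volume_shape=(128, 128, 60))
        truth = generate_fiber_geometry(cfg)
        assert truth.necrotic_fraction == pytest.approx(0.30, abs=0.02)

    def test_undersampled_fiber_diameter_rejected(self):
        cfg = small_config(fiber_diameter_mean=1.2)
        with pytest.raises(ValueError, match="undersampled"):
            generate_fiber_geometry(cfg)

    def test_fibers_separated_by_extracellular_gap(self):
        truth = generate_fiber_geometry(small_config(volume_shape=(128, 128, 24)))
        # every voxel either extracellular or adjacent only to its own fiber
        lab = truth.fiber_label_map
        for shift_axis in (1, 2):
            a = np.take(lab, range(lab.shape[shift_axis] - 1), axis=shift_axis)
            b = np.take(lab, range(1, lab.shape[shift_axis]), axis=shift_axis)
            touching = (a > 0) & (b > 0) & (a != b)
            assert not touching.any()

    def test_truth_invariants_enforced(self):
        bad_necrosis = np.ones((2, 4, 4), bool)
        with pytest.raises(ValueError, match="subset"):
            GroundTruth(
                fiber_label_map=np.zeros((2, 4, 4), np.int32),
                necrosis_mask=bad_necrosis,
                tissue_mask=np.zeros((2, 4, 4), bool),
                sarcomere_length_true=2.2,
                attenuation_depth_constant_true={"AF": math.inf, "bSHG": math.inf, "fSHG": math.inf},
            )


class TestRendering:
    def test_zero_contrast_gives_flat_fshg_inside_fibers(self):
        cfg = small_config(sarcomere_contrast=0.0, psf_sigma_um=0.0)
        truth = generate_fiber_geometry(cfg)
        stack = render_channels(truth, cfg)
        inside = stack.channel("fSHG")[truth.fiber_label_map > 0]
        assert inside.size
        assert np.allclose(inside, cfg.channel_gains["fSHG"])

    def test_necrosis_ablates_only_fshg(self):
        # many small fibers so the two half-volumes have matched composition
        cfg = small_config(
            volume_shape=(128, 128, 40), fiber_diameter_mean=16.0,
            fiber_diameter_sd=2.0, collagen_sheath_thickness=1.5,
        )
        truth = generate_fiber_geometry(cfg)
        half = np.zeros((40, 128, 128), bool)
        half[:20] = True
        truth = GroundTruth(
            truth.fiber_label_map, half & truth.tissue_mask, truth.tissue_mask,
            truth.sarcomere_length_true, truth.attenuation_depth_constant_true,
        )
        stack = render_channels(truth, cfg)
        nec, ok = truth.necrosis_mask, truth.tissue_mask & ~truth.necrosis_mask
        fshg = stack.channel("fSHG")
        assert fshg[nec].mean() <= 0.05 * fshg[ok].mean()
        for name in ("AF", "bSHG"):
            chan = stack.channel(name)
            rel = abs(chan[nec].mean() - chan[ok].mean()) / chan[ok].mean()
            assert rel < 0.02, name

    def test_axial_autocorrelation_peaks_at_sarcomere_length(self):
        cfg = small_config(
            volume_shape=(256, 128, 2), voxel_size=(0.4, 0.4, 4.0),
            sarcomere_length=2.2, fiber_axis_angle=0.0,
            sarcomere_length_jitter=0.0, psf_sigma_um=0.0,
        )
        truth = generate_fiber_geometry(cfg)
        stack = render_channels(truth, cfg)
        row = np.where(truth.fiber_label_map[0] > 0, stack.channel("fSHG")[0], np.nan)
        # pick the fiber row with the most voxels, subtract its mean
        counts = np.sum(np.isfinite(row), axis=1)
        prof = row[np.argmax(counts)]
        prof = prof[np.isfinite(prof)] - np.nanmean(prof)
        ac = np.correlate(prof, prof, mode="full")[prof.size - 1 :]
        lags_um = np.arange(ac.size) * cfg.voxel_size[0]
        search = (lags_um > 1.0) & (lags_um < 4.0)
        peak_lag = lags_um[search][np.argmax(ac[search])]
        assert peak_lag == pytest.approx(2.2, abs=cfg.voxel_size[0])


class TestAttenuationAndNoise:
    def test_infinite_depth_constant_zero_noise_is_identity(self):
        cfg = small_config()
        truth = generate_fiber_geometry(cfg)
        stack = render_channels(truth, cfg)
        out = apply_attenuation_and_noise(stack, cfg)
        assert np.array_equal(out.data, stack.data)

    def test_closed_form_slice_ratio(self):
        cfg = small_config(
            volume_shape=(32, 32, 51), attenuation_depth_constant=200.0
        )
        truth = generate_fiber_geometry(cfg)
        stack = render_channels(truth, cfg)
        out = apply_attenuation_and_noise(stack, cfg)
        fshg_in = stack.channel("fSHG").astype(np.float64)
        fshg_out = out.channel("fSHG").astype(np.float64)
        # slice 50 sits at depth 50*4 = 200 µm = d: scaling factor e^-1
        ratio = fshg_out[50].sum() / fshg_in[50].sum()
        assert ratio == pytest.approx(math.exp(-1.0), rel=1e-6)
        assert fshg_out[0].sum() == pytest.approx(fshg_in[0].sum(), rel=1e-6)

    def test_attenuation_composition_law(self):
        cfg = small_config()
        truth = generate_fiber_geometry(cfg)
        stack = render_channels(truth, cfg)
        two_step = apply_attenuation_and_noise(
            apply_attenuation_and_noise(stack, cfg.replace(attenuation_depth_constant=300.0)),
            cfg.replace(attenuation_depth_constant=150.0),
        )
        combined = 1.0 / (1.0 / 300.0 + 1.0 / 150.0)
        one_step = apply_attenuation_and_noise(
            stack, cfg.replace(attenuation_depth_constant=combined)
        )
        np.testing.assert_allclose(two_step.data, one_step.data, rtol=1e-6, atol=1e-6)

    def test_noise_is_seed_deterministic(self):
        cfg = small_config(noise=NoiseModel(poisson=True, read_noise_sd=1.0))
        a, ta = simulate(cfg)
        b, tb = simulate(cfg)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ta.fiber_label_map, tb.fiber_label_map)
        c, _ = simulate(cfg.replace(seed=4))
        assert not np.array_equal(a.data, c.data)

    def test_negative_noise_parameters_rejected(self):
        with pytest.raises(ValueError):
            small_config(noise=NoiseModel(read_noise_sd=-1.0))

    def test_sham_twin_shares_af_and_bshg(self, ctx_pair):
        ctx_stack, _ = ctx_pair["ctx"]
        sham_stack, _ = ctx_pair["sham"]
        assert np.array_equal(ctx_stack.channel("AF"), sham_stack.channel("AF"))
        assert np.array_equal(ctx_stack.channel("bSHG"), sham_stack.channel("bSHG"))
        assert not np.array_equal(ctx_stack.channel("fSHG"), sham_stack.channel("fSHG"))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"sarcomere_length": 0.8},
            {"sarcomere_length": 5.5},
            {"sarcomere_contrast": 1.4},
            {"necrosis_ablation": {"AF": 1.0, "bSHG": 1.0, "fSHG": 1.2}},
            {"voxel_size": (0.7, 0.7, 0.0)},
            {"attenuation_depth_constant": -50.0},
            {"psf_sigma_um": -0.2},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_config_dict_round_trip(self):
        cfg = preset_config("ctx", seed=9)
        back = SimulationConfig.from_dict(json.loads(json.dumps(cfg.to_dict())))
        assert back.attenuation_depth_constant == cfg.attenuation_depth_constant
        assert back.volume_shape == cfg.volume_shape
        assert back.noise == cfg.noise


class TestPresets:
    def test_cleared_healthy_preset(self, cleared_sim):
        _, truth, _ = cleared_sim
        assert truth.tissue_fraction > 0.5
        assert truth.necrotic_fraction == 0.0

    def test_simulate_writes_products(self, tmp_path):
        cfg = small_config(noise=NoiseModel())
        simulate(cfg, out_dir=tmp_path)
        for name in ("stack.ome.tif", "fiber_labels.tif", "necrosis_mask.tif",
                     "tissue_mask.tif", "simulation.json"):
            assert (tmp_path / name).exists(), name
        sidecar = json.loads((tmp_path / "simulation.json").read_text())
        assert sidecar["truth_summary"]["tissue_fraction"] > 0
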
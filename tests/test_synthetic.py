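import numpy as np
import pytest

from dcerepro import (HeterogeneityConfig, fit_vfa_t1, make_phantom,
                      perturb_mask, simulate_series, spgr_signal,
                      to_concentration, tofts_forward, AIFModel)
from dcerepro.synthetic import TruthPhantom


class TestPhantom:
    def test_range_containment(self):
        het = HeterogeneityConfig(ktrans_range=(0.2, 0.6))
        ph = make_phantom((32, 32), het, seed=1)
        inside = ph.ktrans_map[ph.roi_mask]
        assert 0.2 <= inside.mean() <= 0.6
        assert inside.min() >= 0.2 and inside.max() <= 0.6

    def test_determinism(self):
        a = make_phantom((32, 32), seed=1)
        b = make_phantom((32, 32), seed=1)
        for name in ("ktrans_map", "ve_map", "vp_map", "t10_map", "m0_map"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_degenerate_ranges_give_constant_reference_maps(self):
        het = HeterogeneityConfig(ktrans_range=(0.335, 0.335),
                                  ve_range=(0.531, 0.531))
        ph = make_phantom((16, 16), het, seed=0)
        assert np.allclose(ph.ktrans_map[ph.roi_mask], 0.335)
        assert np.allclose(ph.ve_map[ph.roi_mask], 0.531)

    def test_background_is_nearly_non_enhancing(self):
        ph = make_phantom((32, 32), seed=2)
        assert ph.ktrans_map[~ph.roi_mask].max() < 0.01

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_phantom((4, 4))

    def test_invariant_violations_rejected(self):
        good = make_phantom((16, 16), seed=0)
        with pytest.raises(ValueError):
            TruthPhantom(ktrans_map=good.ktrans_map, ve_map=good.ve_map + 2,
                         vp_map=good.vp_map, t10_map=good.t10_map,
                         m0_map=good.m0_map, roi_mask=good.roi_mask)
        with pytest.raises(ValueError):
            TruthPhantom(ktrans_map=good.ktrans_map, ve_map=good.ve_map,
                         vp_map=good.vp_map, t10_map=good.t10_map,
                         m0_map=good.m0_map,
                         roi_mask=np.zeros_like(good.roi_mask))


class TestSimulate:
    def test_no_exchange_means_flat_signal(self, meta):
        shape = (8, 8)
        ph = TruthPhantom(ktrans_map=np.zeros(shape),
                          ve_map=np.full(shape, 0.5),
                          vp_map=np.zeros(shape),
                          t10_map=np.full(shape, 1.4),
                          m0_map=np.full(shape, 1000.0),
                          roi_mask=np.ones(shape, bool))
        series = simulate_series(ph, meta, 0.0, "none")
        assert np.allclose(series.frames, series.frames[..., :1], rtol=1e-12)

    def test_prebolus_frames_are_baseline_spgr(self, meta, phantom16,
                                               noiseless_series):
        base = spgr_signal(phantom16.m0_map, phantom16.t10_map,
                           meta.dynamic_flip_deg, meta.tr)
        for f in range(meta.bolus_frame_index):
            assert np.allclose(noiseless_series.frames[..., f], base, rtol=1e-12)

    def test_vfa_signals_follow_spgr_at_each_angle(self, meta, phantom16,
                                                   noiseless_series):
        for k, ang in enumerate(meta.flip_angles_deg):
            expect = spgr_signal(phantom16.m0_map, phantom16.t10_map, ang, meta.tr)
            assert np.allclose(noiseless_series.vfa_signals[..., k], expect,
                               rtol=1e-12)

    def test_rician_noise_keeps_signal_nonnegative(self, meta, phantom16):
        series = simulate_series(phantom16, meta, 5.0, "rician", seed=4)
        assert np.all(series.frames >= 0)
        assert np.all(series.vfa_signals >= 0)

    def test_determinism(self, meta, phantom16):
        a = simulate_series(phantom16, meta, 1.0, "rician", seed=9)
        b = simulate_series(phantom16, meta, 1.0, "rician", seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_rician_approaches_gaussian_at_high_snr(self, meta, phantom16):
        clean = simulate_series(phantom16, meta, 0.0, "none")
        base = clean.frames[..., 0]
        sigma = float(base.mean()) / 20.0
        noisy = simulate_series(phantom16, meta, sigma, "rician", seed=21)
        ratio = noisy.frames[..., :2].mean() / base.mean()
        assert abs(ratio - 1.0) < 0.02


class TestPerturbMask:
    def test_zero_magnitude_is_identity(self):
        ph = make_phantom((32, 32), seed=0)
        out = perturb_mask(ph.roi_mask, 0.0, seed=1)
        assert np.array_equal(out, ph.roi_mask)

    def test_jaccard_stays_high_on_disc(self):
        yy, xx = np.indices((64, 64))
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2
        out = perturb_mask(disc, 1.0, seed=5)
        inter = np.count_nonzero(disc & out)
        union = np.count_nonzero(disc | out)
        assert inter / union >= 0.8

    def test_changes_confined_to_boundary_band(self):
        yy, xx = np.indices((64, 64))
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2
        out = perturb_mask(disc, 3.0, seed=6)
        changed = disc ^ out
        from scipy import ndimage
        inside = ndimage.distance_transform_edt(disc)
        outside = ndimage.distance_transform_edt(~disc)
        signed = np.where(disc, inside, -outside)
        assert np.all(np.abs(signed[changed]) <= 3.0 + 1e-9)

    def test_determinism(self):
        ph = make_phantom((32, 32), seed=0)
        a = perturb_mask(ph.roi_mask, 3.0, seed=8)
        b = perturb_mask(ph.roi_mask, 3.0, seed=8)
        assert np.array_equal(a, b)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            perturb_mask(np.zeros((8, 8), bool), 1.0)


def test_noiseless_pipeline_identity_small(meta, phantom16, noiseless_series, aif):
    """Simulate -> T1 fit -> concentration -> Tofts fit recovers the truth."""
    from dcerepro import fit_map
    t1map = fit_vfa_t1(noiseless_series.vfa_signals, meta)
    cs = to_concentration(noiseless_series, t1map)
    pmap = fit_map(cs, phantom16.roi_mask, aif)
    m = phantom16.roi_mask
    for name, truth in (("ktrans", phantom16.ktrans_map),
                        ("ve", phantom16.ve_map), ("vp", phantom16.vp_map)):
        est = getattr(pmap, name)[m]
        rel = np.abs(est - truth[m]) / np.maximum(np.abs(truth[m]), 1e-12)
        assert rel.max() < 1e-4
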
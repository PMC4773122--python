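import math

import numpy as np
import pytest
from scipy import stats

from dwiphantom.compartments import attenuation_isotropic
from dwiphantom.fibermap import assign_segments
from dwiphantom.relaxometry import SequenceTiming, s0_volume
from dwiphantom.scanner import (
    GradientScheme,
    Protocol,
    add_kspace_noise,
    degrade,
    electrostatic_energy,
    generate_directions,
    ideal_dw_volumes,
    simulate_acquisition,
)

TIMING = SequenceTiming(te_ms=57.0, tr_ms=8800.0, b0_T=3.0)


def make_protocol(scheme=None, **kw):
    if scheme is None:
        scheme = GradientScheme(bvals=np.array([0.0]),
                                bvecs=np.zeros((1, 3)))
    defaults = dict(scheme=scheme, delta_s=12.9e-3, Delta_s=21.8e-3,
                    timing=TIMING, native_voxel_mm=(1.0, 1.0, 1.0))
    defaults.update(kw)
    return Protocol(**defaults)


class TestDirections:
    def test_minimum_count(self):
        with pytest.raises(ValueError):
            generate_directions(3)

    def test_determinism(self):
        a = generate_directions(12, seed=4)
        b = generate_directions(12, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_unit_and_distinct(self):
        d = generate_directions(20, seed=1)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        assert np.degrees(np.arccos(np.clip(dots.max(), -1, 1))) > 0.0

    def test_n6_matches_multistart_oracle(self):
        from oracles import multistart_direction_energy

        d = generate_directions(6, seed=0)
        best = multistart_direction_energy(6, n_restarts=20, seed=3)
        assert electrostatic_energy(d) == pytest.approx(best, abs=1e-4)


class TestScheme:
    def test_needs_b0(self):
        with pytest.raises(ValueError, match="b = 0"):
            GradientScheme(bvals=np.array([1000.0]),
                           bvecs=np.array([[1.0, 0.0, 0.0]]))

    def test_multishell_layout(self):
        s = GradientScheme.multishell(10, [1000.0, 2500.0], n_b0=3, seed=0)
        assert len(s) == 3 + 20
        assert s.n_b0 == 3
        np.testing.assert_array_equal(s.shells, [1000.0, 2500.0])
        # same direction set reused per shell
        np.testing.assert_array_equal(s.bvecs[3:13], s.bvecs[13:23])


@pytest.fixture(scope="module")
def setup(default_substrate, models, mrparams_3t):
    _, vf, tractogram = default_substrate
    field = assign_segments(tractogram, vf)
    scheme = GradientScheme.multishell(6, [1000.0], n_b0=1, seed=2)
    protocol = make_protocol(scheme=scheme)
    ideal = ideal_dw_volumes(vf, field, models, protocol, mrparams_3t)
    return vf, field, scheme, protocol, ideal


class TestIdealVolumes:
    def test_b0_equals_s0(self, setup, mrparams_3t):
        vf, _, _, protocol, ideal = setup
        s0 = s0_volume(vf, mrparams_3t, protocol.timing)
        np.testing.assert_array_equal(ideal[..., 0], s0)

    def test_dw_bounded_by_s0(self, setup):
        _, _, _, _, ideal = setup
        assert np.all(ideal.min(axis=-1) >= 0.0)
        assert np.all(ideal.max(axis=-1) <= ideal[..., 0] + 1e-12)

    def test_pure_csf_voxel(self, setup, models):
        vf, _, scheme, _, ideal = setup
        csf = np.argwhere(vf.tissue("CSF") == 1.0)
        assert len(csf)
        v = tuple(csf[0])
        expected = ideal[v][0] * attenuation_isotropic(models.CSF.md, 1e9)
        np.testing.assert_allclose(ideal[v][1:], expected, rtol=1e-10)


class TestDegrade:
    def test_constant_image_preserved(self):
        p = make_protocol(downsample=(2, 2, 2))
        vol = np.full((16, 16, 16), 3.7)
        out = degrade(vol, p)
        assert out.shape == (8, 8, 8)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_identity_at_factor_one(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0.5, 1.5, (12, 12, 4))
        out = degrade(vol, make_protocol())
        np.testing.assert_allclose(out, vol, rtol=1e-10)

    def test_non_divisible_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            degrade(np.ones((15, 16, 16)), make_protocol(downsample=(2, 2, 2)))

    def test_voxel_size_bookkeeping(self):
        p = make_protocol(native_voxel_mm=(0.7, 0.7, 0.7), downsample=(2, 2, 2))
        assert p.target_voxel_mm == (1.4, 1.4, 1.4)
        p3 = make_protocol(native_voxel_mm=(0.7, 0.7, 0.7), downsample=(3, 3, 3))
        assert p3.target_voxel_mm == pytest.approx((2.1, 2.1, 2.1))

    def test_rms_never_increases(self, rng):
        """Parseval: central k-space crop cannot increase the image RMS."""
        vol = rng.uniform(0.0, 2.0, (16, 16, 8))
        for factors in [(2, 2, 1), (4, 4, 2), (2, 2, 2)]:
            out = degrade(vol, make_protocol(downsample=factors))
            assert np.sqrt((out**2).mean()) <= np.sqrt((vol**2).mean()) + 1e-12

    def test_gibbs_oscillation_at_edge(self):
        """Truncating a sharp edge produces alternating over/undershoot
        within 3 output voxels of the edge."""
        vol = np.ones((32, 8, 4))
        vol[16:] = 0.2
        for f in (2, 3):
            shape = (30, 6, 3) if f == 3 else (32, 8, 4)
            v = vol[: shape[0], : shape[1], : shape[2]]
            out = degrade(v, make_protocol(downsample=(f, 1, 1)))
            profile = out[:, 3, 1]
            edge = 16 // f  # native edge index mapped to the output grid
            near = profile[max(edge - 3, 0) : edge]
            assert near.max() > 1.0 + 1e-3  # overshoot above the plateau
            resid = near - 1.0
            assert resid.max() > 0 and resid.min() < 0  # alternation

    def test_matches_dirichlet_oracle(self):
        from oracles import dirichlet_truncation

        profile = np.ones(32)
        profile[16:] = 0.2
        vol = np.tile(profile[:, None, None], (1, 4, 2))
        out = degrade(vol, make_protocol(downsample=(2, 1, 1)))
        oracle = dirichlet_truncation(profile, 16)
        np.testing.assert_allclose(out[:, 2, 1], oracle, rtol=1e-2, atol=1e-4)

    def test_fermi_hamming_smooth_ringing(self):
        # apodization reduces the ringing energy on the bright plateau
        vol = np.ones((32, 8, 4))
        vol[16:] = 0.2
        def plateau_ripple(out):
            return np.sum((out[2:7, 3, 1] - 1.0) ** 2)
        none = plateau_ripple(degrade(vol, make_protocol(downsample=(2, 1, 1))))
        for filt in ("fermi", "hamming"):
            smoothed = plateau_ripple(
                degrade(vol, make_protocol(downsample=(2, 1, 1),
                                           filter_name=filt))
            )
            assert smoothed < none


class TestNoise:
    def test_infinite_snr_identity(self, rng):
        k = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        out = add_kspace_noise(k, math.inf, 1.0, rng)
        np.testing.assert_array_equal(out, k)

    def test_background_rayleigh(self):
        """Zero image + finite SNR -> magnitude is Rayleigh distributed."""
        p = make_protocol(snr=20.0, noise_seed=9)
        vol = np.zeros((40, 40, 8))
        out = degrade(vol, p, reference_signal=1.0)
        sigma = 1.0 / 20.0
        stat = stats.kstest(out.ravel(), "rayleigh", args=(0.0, sigma))
        assert stat.pvalue > 0.01

    def test_bright_region_rician_moments(self):
        """Uniform signal at SNR 20 -> Rician(nu=signal, sigma=signal/20)."""
        signal, snr = 2.0, 20.0
        p = make_protocol(snr=snr, noise_seed=11)
        vol = np.full((40, 40, 8), signal)
        out = degrade(vol, p, reference_signal=signal)
        sigma = signal / snr
        rice = stats.rice(signal / sigma, scale=sigma)
        n = out.size
        assert out.mean() == pytest.approx(
            rice.mean(), abs=3.0 * rice.std() / math.sqrt(n)
        )
        assert out.std() == pytest.approx(rice.std(), rel=0.05)

    def test_noise_seed_determinism(self):
        p = make_protocol(snr=15.0, noise_seed=3)
        vol = np.ones((16, 16, 4))
        a = degrade(vol, p, reference_signal=1.0)
        b = degrade(vol, p, reference_signal=1.0)
        np.testing.assert_array_equal(a, b)

    def test_volume3d_mode_statistics(self):
        p = make_protocol(snr=20.0, noise_seed=9, noise_mode="volume3d")
        vol = np.zeros((32, 32, 8))
        out = degrade(vol, p, reference_signal=1.0)
        sigma = 1.0 / 20.0
        stat = stats.kstest(out.ravel(), "rayleigh", args=(0.0, sigma))
        assert stat.pvalue > 0.01


class TestSimulateAcquisition:
    def test_volume_count_and_determinism(self, default_substrate, models,
                                          mrparams_3t):
        _, vf, tractogram = default_substrate
        scheme = GradientScheme.multishell(6, [1000.0], n_b0=2, seed=1)
        p = make_protocol(scheme=scheme, downsample=(2, 2, 2), snr=25.0,
                          noise_seed=4)
        acq1 = simulate_acquisition(vf, tractogram, models, mrparams_3t, p)
        acq2 = simulate_acquisition(vf, tractogram, models, mrparams_3t, p)
        assert acq1.data.shape == (20, 20, 20, 8)
        np.testing.assert_array_equal(acq1.data, acq2.data)
        assert acq1.provenance["snr_reference"] > 0

    def test_noiseless_identity(self, default_substrate, models, mrparams_3t):
        _, vf, tractogram = default_substrate
        scheme = GradientScheme.multishell(6, [1000.0], n_b0=1, seed=1)
        p = make_protocol(scheme=scheme)
        field = assign_segments(tractogram, vf)
        ideal = ideal_dw_volumes(vf, field, models, p, mrparams_3t)
        acq = simulate_acquisition(vf, tractogram, models, mrparams_3t, p)
        rel = np.abs(acq.data - ideal).max() / ideal.max()
        assert rel <= 1e-10
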
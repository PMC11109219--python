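"""LCMV beamformer: covariance, orientation reduction, weights, alignment."""

import numpy as np
import pytest

from seqmeg import beamformer, simulate
from seqmeg.datatypes import (BeamformerWeights, Leadfield, SensorCovariance,
                              SensorEpochs, SourceGrid, SourceTimeSeries)


def _epochs(data, ch_types=None, time_zero=5):
    n_ch = data.shape[1]
    if ch_types is None:
        ch_types = np.array(["mag"] * n_ch, dtype=object)
    labels = np.array(["M"] * data.shape[0], dtype=object)
    return SensorEpochs(data=data, labels=labels, sfreq=250.0,
                        baseline_window=(0, time_zero),
                        channel_types=ch_types, time_zero=time_zero)


class TestCovariance:
    def test_duplicated_channel(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 1, 200))
        data = np.concatenate([x, x], axis=1)
        cov = beamformer.compute_covariance(_epochs(data), reg=0)
        assert cov.C[0, 1] == pytest.approx(cov.C[0, 0])
        assert cov.C[0, 1] == pytest.approx(cov.C[1, 1])

    def test_white_noise_diagonal(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((40, 5, 500)) * np.array(
            [1.0, 2.0, 3.0, 4.0, 5.0])[None, :, None]
        cov = beamformer.compute_covariance(_epochs(data), reg=0)
        off = cov.C - np.diag(np.diag(cov.C))
        assert np.allclose(np.diag(cov.C), np.arange(1, 6.) ** 2, rtol=0.05)
        assert np.max(np.abs(off)) < 0.5

    def test_diagonal_loading(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 3, 100))
        raw = beamformer.compute_covariance(_epochs(data), reg=0)
        loaded = beamformer.compute_covariance(_epochs(data), reg=0.05)
        delta = np.diag(loaded.C) - np.diag(raw.C)
        assert np.allclose(delta, 0.05 * np.mean(np.diag(raw.C)))

    def test_needs_trials(self):
        with pytest.raises(ValueError):
            beamformer.compute_covariance(
                _epochs(np.zeros((1, 3, 10))), reg=0)


def _random_case(n_src=8, n_ch=12, seed=0):
    rng = np.random.default_rng(seed)
    grid = SourceGrid(coords=rng.standard_normal((n_src, 3)), spacing_mm=8.0,
                      parcel_label=np.array(["other"] * n_src, dtype=object))
    gain = rng.standard_normal((n_src, 3, n_ch))
    A = rng.standard_normal((n_ch, n_ch))
    C = A @ A.T + n_ch * np.eye(n_ch)
    return (Leadfield(gain=gain, grid=grid),
            SensorCovariance(C=C, n_samples=1000, regularization=0.0))


class TestOrientationReduction:
    def test_single_orientation_degenerate(self):
        lf, cov = _random_case()
        gain = np.zeros_like(lf.gain)
        gain[:, 0, :] = lf.gain[:, 0, :]
        red = beamformer.reduce_orientation(
            Leadfield(gain=gain, grid=lf.grid), cov)
        for q in range(gain.shape[0]):
            r = red.reduced[q] / np.linalg.norm(red.reduced[q])
            g = gain[q, 0] / np.linalg.norm(gain[q, 0])
            assert np.allclose(np.abs(r @ g), 1.0, atol=1e-10)

    def test_identity_covariance_svd_oracle(self):
        """With C = I the max-output-power orientation is the gain's
        weakest left-singular direction (independent SVD oracle): the
        unit-gain constraint amplifies the direction the array sees least,
        maximising the constrained variance estimate."""
        lf, _ = _random_case(seed=3)
        cov = SensorCovariance(C=np.eye(lf.n_channels), n_samples=1,
                               regularization=0.0)
        red = beamformer.reduce_orientation(lf, cov)
        for q in range(lf.n_sources):
            U, s, Vt = np.linalg.svd(lf.gain[q], full_matrices=False)
            expected = U[:, -1] @ lf.gain[q]
            r = red.reduced[q]
            cos = (r @ expected) / (np.linalg.norm(r)
                                    * np.linalg.norm(expected))
            assert abs(cos) == pytest.approx(1.0, abs=1e-8)

    def test_shape(self):
        lf, cov = _random_case()
        red = beamformer.reduce_orientation(lf, cov)
        assert red.reduced.shape == (lf.n_sources, lf.n_channels)


def _reduced(L, C):
    L = np.asarray(L, dtype=float)
    lf = Leadfield(gain=np.zeros((L.shape[0], 3, L.shape[1])),
                   grid=SourceGrid(coords=np.zeros((L.shape[0], 3)),
                                   spacing_mm=8.0,
                                   parcel_label=np.array(
                                       ["other"] * L.shape[0], dtype=object)),
                   reduced=np.asarray(L, dtype=float))
    cov = SensorCovariance(C=np.asarray(C, dtype=float), n_samples=100,
                           regularization=0.0)
    return lf, cov


class TestWeights:
    def test_identity_covariance(self):
        lf, cov = _reduced([[1.0, 0.0]], np.eye(2))
        w = beamformer.compute_weights(lf, cov)
        assert np.allclose(w.W, [[1.0, 0.0]])

    def test_hand_example(self):
        """L = (1, 1), C = diag(1, 4): (L' C^-1 L)^-1 = 0.8, W = (0.8, 0.2)."""
        lf, cov = _reduced([[1.0, 1.0]], np.diag([1.0, 4.0]))
        w = beamformer.compute_weights(lf, cov)
        assert np.allclose(w.W, [[0.8, 0.2]], atol=1e-12)

    def test_unit_gain(self):
        lf, cov = _random_case(seed=9)
        red = beamformer.reduce_orientation(lf, cov)
        w = beamformer.compute_weights(red, cov)
        gains = np.einsum("qc,qc->q", w.W, red.reduced)
        assert np.allclose(gains, 1.0, atol=1e-8)

    def test_matches_bruteforce_solve(self):
        """Per-voxel generic linear solve (no pooled inverse) agrees to
        1e-10 with the vectorised implementation."""
        lf, cov = _random_case(n_src=20, n_ch=15, seed=4)
        red = beamformer.reduce_orientation(lf, cov)
        w = beamformer.compute_weights(red, cov)
        for q in range(red.n_sources):
            Lq = red.reduced[q]
            x = np.linalg.solve(cov.C, Lq)  # C^-1 L_q
            wq = x / (Lq @ x)
            assert np.allclose(w.W[q], wq, atol=1e-10)

    def test_zero_row_rejected(self):
        lf, cov = _reduced([[0.0, 0.0]], np.eye(2))
        with pytest.raises(ValueError, match="voxel 0"):
            beamformer.compute_weights(lf, cov)


class TestNormalize:
    def test_row_example(self):
        w = BeamformerWeights(W=np.array([[3.0, 4.0]]))
        out = beamformer.normalize_weights(w)
        assert np.allclose(out.W, [[0.6, 0.8]])
        assert out.normalized

    def test_unit_norms(self):
        rng = np.random.default_rng(0)
        out = beamformer.normalize_weights(
            BeamformerWeights(W=rng.standard_normal((7, 5))))
        assert np.allclose(np.linalg.norm(out.W, axis=1), 1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            beamformer.normalize_weights(BeamformerWeights(W=np.zeros((1, 3))))


class TestApplyWeights:
    def test_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((6, 4, 30))
        w = BeamformerWeights(W=np.eye(4))
        src = beamformer.apply_weights(w, _epochs(data), mode="evoked")
        assert np.allclose(src.data["M"], data.mean(axis=0))

    def test_linearity(self):
        rng = np.random.default_rng(1)
        d1 = rng.standard_normal((4, 3, 20))
        d2 = rng.standard_normal((4, 3, 20))
        W = rng.standard_normal((5, 3))
        w = BeamformerWeights(W=W)
        s1 = beamformer.apply_weights(w, _epochs(d1), "induced").data
        s2 = beamformer.apply_weights(w, _epochs(d2), "induced").data
        s12 = beamformer.apply_weights(
            w, _epochs(2.0 * d1 - 3.0 * d2), "induced").data
        assert np.allclose(s12, 2.0 * s1 - 3.0 * s2, atol=1e-10)

    def test_zero_input(self):
        w = BeamformerWeights(W=np.ones((2, 3)))
        src = beamformer.apply_weights(w, _epochs(np.zeros((3, 3, 10))),
                                       "evoked")
        assert np.all(src.data["M"] == 0)

    def test_channel_mismatch(self):
        w = BeamformerWeights(W=np.ones((2, 4)))
        with pytest.raises(ValueError, match="channels"):
            beamformer.apply_weights(w, _epochs(np.zeros((3, 3, 10))),
                                     "evoked")

    def test_bad_mode(self):
        w = BeamformerWeights(W=np.ones((2, 3)))
        with pytest.raises(ValueError):
            beamformer.apply_weights(w, _epochs(np.zeros((3, 3, 10))), "avg")


class TestAlignSign:
    def _src(self, series):
        return SourceTimeSeries(data={"M": np.asarray(series, dtype=float)},
                                mode="evoked", grid=None, sfreq=250.0,
                                time_zero=0)

    def test_positive_window_flipped(self):
        src = self._src(np.full((1, 100), 2.0))
        out, flips = beamformer.align_sign(src, (0.1, 0.2))
        assert flips[0] == -1
        assert np.all(out.data["M"] == -2.0)

    def test_negative_window_unchanged(self):
        src = self._src(np.full((1, 100), -2.0))
        out, flips = beamformer.align_sign(src, (0.1, 0.2))
        assert flips[0] == 1
        assert np.all(out.data["M"] == -2.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        src = self._src(rng.standard_normal((6, 100)))
        once, _ = beamformer.align_sign(src, (0.1, 0.2))
        twice, flips = beamformer.align_sign(once, (0.1, 0.2))
        assert np.all(flips == 1)
        assert np.array_equal(once.data["M"], twice.data["M"])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            beamformer.align_sign(self._src(np.zeros((1, 10))), (0.1, 0.1))


def dipole_recovery_rate(n_runs, seed0=0, n_ch=30, noise_sd=0.3):
    """Fraction of runs where the voxel with maximal normalised activity
    power is the simulated dipole or a grid neighbour."""
    grid = simulate.make_grid((5, 5, 4), spacing_mm=12.0)
    lf = simulate.make_leadfield(n_ch, grid, rng=123)
    hits = 0
    for i in range(n_runs):
        rng = np.random.default_rng(seed0 + i)
        v = int(rng.integers(grid.n_voxels))
        orient = rng.standard_normal(3)
        orient /= np.linalg.norm(orient)
        sig = np.sin(2 * np.pi * 7 * np.arange(250) / 250.0)
        data = (sig[None, None, :] * (orient @ lf.gain[v])[None, :, None]
                + noise_sd * rng.standard_normal((20, n_ch, 250)))
        ep = SensorEpochs(data=data,
                          labels=np.array(["M"] * 20, dtype=object),
                          sfreq=250.0, baseline_window=(0, 5),
                          channel_types=np.array(["mag"] * n_ch,
                                                 dtype=object),
                          time_zero=5)
        cov = beamformer.compute_covariance(ep)
        red = beamformer.reduce_orientation(lf, cov)
        w = beamformer.normalize_weights(beamformer.compute_weights(red, cov))
        src = beamformer.apply_weights(w, ep, "evoked")
        power = (src.data["M"] ** 2).sum(axis=1)
        best = int(np.argmax(power))
        d = np.linalg.norm(grid.coords[best] - grid.coords[v])
        hits += d <= grid.spacing_mm * 1.01
    return hits / n_runs


def test_dipole_recovery_smoke():
    """A simulated dipole is localised to its voxel or a neighbour."""
    assert dipole_recovery_rate(20) >= 0.9
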
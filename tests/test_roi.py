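"""Channel selection, parcel aggregation, orthogonalization, peaks, ANOVAs."""

import numpy as np
import pytest

from seqmeg import roi
from seqmeg.datatypes import (ROI_NAMES, ROITimeSeries, SensorEpochs,
                              SourceGrid, SourceTimeSeries)


class TestSelectTopChannels:
    def test_all_equal_selects_none(self):
        assert len(roi.select_top_channels(np.ones(8))) == 0

    def test_single_outlier(self):
        """mean 2.5, sample SD 5 -> threshold 7.5 -> only channel 3."""
        sel = roi.select_top_channels(np.array([0.0, 0.0, 0.0, 10.0]))
        assert sel.tolist() == [3]

    def test_per_channel_type(self):
        mags = np.array([0.0, 0.0, 0.0, 10.0])
        grads = np.array([100.0, 100.0, 100.0, 200.0])
        types = np.array(["mag"] * 4 + ["grad"] * 4, dtype=object)
        sel = roi.select_top_channels(np.r_[mags, grads], types)
        assert sel.tolist() == [3, 7]

    def test_too_few(self):
        with pytest.raises(ValueError):
            roi.select_top_channels(np.array([1.0]))


class TestGroupByPolarity:
    def _epochs(self, data):
        labels = np.array(["M"] * data.shape[0], dtype=object)
        return SensorEpochs(data=data, labels=labels, sfreq=250.0,
                            baseline_window=(0, 10),
                            channel_types=np.array(
                                ["mag"] * data.shape[1], dtype=object),
                            time_zero=10)

    def test_mirrored_dipolar_channels(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(100)
        s[27:42] = -3.0  # negative N100 window content
        data = np.stack([s, s, -s, -s])[None].repeat(4, axis=0)
        groups = roi.group_by_polarity(self._epochs(data), np.arange(4))
        assert set(groups) == {"negative", "positive"}
        assert np.allclose(groups["negative"]["M"], -groups["positive"]["M"])

    def test_single_polarity_warns(self):
        data = -np.ones((3, 4, 100))
        with pytest.warns(UserWarning, match="positive"):
            groups = roi.group_by_polarity(self._epochs(data), np.arange(4))
        assert list(groups) == ["negative"]


def _grid(labels):
    n = len(labels)
    return SourceGrid(coords=np.arange(3 * n, dtype=float).reshape(n, 3),
                      spacing_mm=8.0,
                      parcel_label=np.array(labels, dtype=object))


class TestAggregateParcels:
    def test_single_voxel_roi(self):
        grid = _grid(["LHG", "RHG", "LHP", "RHP", "ACC", "MC"])
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((6, 40))
        src = SourceTimeSeries(data={"M": arr}, mode="evoked", grid=grid,
                               sfreq=250.0, time_zero=5)
        agg = roi.aggregate_parcels(src, grid)
        assert np.array_equal(agg["M"], arr)

    def test_cancellation(self):
        grid = _grid(["LHG", "LHG", "RHG", "LHP", "RHP", "ACC", "MC"])
        x = np.sin(np.linspace(0, 5, 30))
        arr = np.vstack([x, -x] + [x] * 5)
        src = SourceTimeSeries(data={"M": arr}, mode="evoked", grid=grid,
                               sfreq=250.0, time_zero=5)
        agg = roi.aggregate_parcels(src, grid)
        assert np.allclose(agg["M"][0], 0.0)

    def test_matches_bruteforce_mean(self):
        labels = ["LHG"] * 3 + ["RHG", "LHP", "RHP", "ACC"] + ["MC"] * 2
        grid = _grid(labels)
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((len(labels), 25))
        src = SourceTimeSeries(data={"M": arr}, mode="evoked", grid=grid,
                               sfreq=250.0, time_zero=5)
        agg = roi.aggregate_parcels(src, grid)
        assert np.allclose(agg["M"][0], arr[:3].mean(axis=0), atol=1e-12)
        assert np.allclose(agg["M"][5], arr[7:].mean(axis=0), atol=1e-12)

    def test_empty_roi_rejected(self):
        grid = _grid(["LHG", "RHG", "LHP", "RHP", "ACC", "other"])
        src = SourceTimeSeries(data={"M": np.zeros((6, 10))}, mode="evoked",
                               grid=grid, sfreq=250.0, time_zero=2)
        with pytest.raises(ValueError, match="MC"):
            roi.aggregate_parcels(src, grid)


class TestSymmetricOrthogonalize:
    def test_orthogonal_fixed_point(self):
        X = np.zeros((20, 3))
        X[0, 0] = 2.0
        X[1, 1] = -1.5
        X[2, 2] = 3.0
        out = roi.symmetric_orthogonalize(X)
        assert np.allclose(out, X, atol=1e-8)

    def test_zero_correlations(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 6))
        X[:, 1] = 0.7 * X[:, 0] + 0.3 * X[:, 1]  # induce leakage
        out = roi.symmetric_orthogonalize(X)
        G = out.T @ out
        off = G[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.abs(G))

    def test_polar_decomposition_oracle(self):
        """The orthonormal factor of the output matches the polar factor
        of X diag(d): no orthonormal basis is closer in Frobenius norm."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 4))
        out = roi.symmetric_orthogonalize(X)
        d = np.linalg.norm(out, axis=0)
        O = out / d
        A = X * d
        U, _, Vt = np.linalg.svd(A, full_matrices=False)
        polar = U @ Vt
        assert np.linalg.norm(X - out) <= np.linalg.norm(X - polar * d) + 1e-9
        assert np.allclose(np.abs(np.diag(O.T @ polar)), 1.0, atol=1e-6)

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError):
            roi.symmetric_orthogonalize(X)


class TestExtractPeaks:
    def test_gaussian_peak_located(self):
        sfreq = 250.0
        t = np.arange(1125) / sfreq - 0.1
        onsets = (25 + np.round(np.arange(5) * 0.35 * sfreq)).astype(int)
        center = 0.35 + 0.35  # 350 ms after tone 2
        y = np.exp(-0.5 * ((t - center) / 0.02) ** 2)
        table = roi.extract_peaks({"M": y}, onsets, sfreq)
        row = table[(table.condition == "M") & (table.tone == 2)
                    & (table.kind == "max")].iloc[0]
        expected = 25 + int(round(center * sfreq))
        assert abs(row.peak_sample - expected) <= 1

    def test_constant_series_tie_rule(self):
        onsets = np.array([5, 10, 15, 20, 25])
        table = roi.extract_peaks({"M": np.ones(60)}, onsets, 250.0,
                                  search_ms=40.0)
        row = table[(table.tone == 2) & (table.kind == "max")].iloc[0]
        assert row.peak_sample == 10  # earliest index on ties
        assert row.amplitude == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(300)
        onsets = np.array([10, 50, 90, 130, 170])
        a = roi.extract_peaks({"M": y}, onsets, 250.0)
        b = roi.extract_peaks({"M": y.copy()}, onsets, 250.0)
        assert a.equals(b)


class TestPeakContrastSources:
    def test_identical_conditions_empty_mask(self):
        rng = np.random.default_rng(6)
        subs = []
        for _ in range(8):
            x = rng.standard_normal((30, 100))
            subs.append({"M": x, "NT1": x.copy()})
        t, p, mask = roi.peak_contrast_sources(subs, ("M", "NT1"), 50)
        assert t.shape == (30,)
        assert mask.sum() == 0

    def test_localised_effect(self):
        """An effect injected into voxels 10-14 concentrates the FDR mask
        there."""
        rng = np.random.default_rng(7)
        subs = []
        for _ in range(12):
            base = rng.standard_normal((30, 100))
            m = base.copy()
            m[10:15, 45:56] += 3.0
            subs.append({"M": m, "NT1": base})
        t, p, mask = roi.peak_contrast_sources(subs, ("M", "NT1"), 50)
        assert mask[10:15].all()
        assert mask.sum() <= 15  # not spread over the whole grid


def _pe_roi_ts(n_subjects=30, decay=(1.0, 0.5, 0.4, 0.3), hg_flat=True,
               noise=0.15, seed=0):
    """ROI series with prediction-error peaks that decay over sequential
    varied tones in HP/ACC/MC and stay flat in HG."""
    rng = np.random.default_rng(seed)
    sfreq = 250.0
    n_times = 1125
    tz = 25
    onsets = (tz + np.round(np.arange(5) * 0.35 * sfreq)).astype(int)
    t = np.arange(n_times)
    conditions = ("M", "NT1", "NT2", "NT3", "NT4")
    data = np.zeros((n_subjects, 5, 6, n_times))
    for s in range(n_subjects):
        for ci, cond in enumerate(conditions[1:], start=1):
            k = ci  # first varied tone index (1-based tone k+1)
            for j, onset in enumerate(onsets[k:]):
                amp = decay[min(j, 3)]
                for r, name in enumerate(ROI_NAMES):
                    lat = int(round(roi.PE_LATENCY_MS[name] / 1000 * sfreq))
                    a = 1.0 if (hg_flat and name in ("LHG", "RHG")) else amp
                    sign = 1.0 if name == "MC" else -1.0
                    data[s, ci, r] += sign * a * np.exp(
                        -0.5 * ((t - onset - lat) / 8.0) ** 2)
        data[s] += noise * rng.standard_normal((5, 6, n_times))
    return ROITimeSeries(data=data, roi_names=ROI_NAMES,
                         conditions=conditions, sfreq=sfreq, time_zero=tz), \
        onsets


class TestPredictionErrorAnovas:
    def test_dof_bookkeeping(self):
        rts, onsets = _pe_roi_ts(n_subjects=83, noise=0.05, seed=1)
        df = roi.prediction_error_anovas(rts, onsets)
        row = df[(df.roi == "ACC") & (df.condition == "NT1")].iloc[0]
        assert (row.df1, row.df2) == (3, 83 * 4 - 4)
        assert len(df) == 18

    def test_dissociation(self):
        """Decaying peaks make HP/ACC ANOVAs significant; flat sequential
        responses keep HG ANOVAs null."""
        rts, onsets = _pe_roi_ts(seed=2)
        df = roi.prediction_error_anovas(rts, onsets)
        hg = df[df.roi.isin(["LHG", "RHG"])]
        higher = df[df.roi.isin(["LHP", "RHP", "ACC"])
                    & df.condition.isin(["NT1", "NT2"])]
        assert not hg.significant.any()
        assert higher.significant.all()

    def test_missing_condition_rejected(self):
        rts, onsets = _pe_roi_ts(n_subjects=5)
        rts.conditions = ("M", "NT1")
        with pytest.raises(ValueError):
            roi.prediction_error_anovas(rts, onsets, conditions=("NT3",))


class TestCovariateCorrelation:
    def test_perfect_correlation(self):
        amp = np.linspace(1, 2, 20)
        df = roi.covariate_correlation(amp, amp)
        assert df.r.iloc[0] == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        rs, rejections = [], 0
        for _ in range(300):
            amps = rng.standard_normal((30, 4)) + 5
            cov = rng.standard_normal(30)
            df = roi.covariate_correlation(amps, cov)
            rs.append(df.r.mean())
            rejections += df.significant.sum()
        assert abs(np.mean(rs)) < 0.02
        assert rejections / (300 * 4) < 0.05

    def test_loading_recovery(self):
        """Amplitudes built with correlation 0.4 to the covariate recover
        r near 0.4 at n = 83."""
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            cov = rng.standard_normal(83)
            eta = rng.standard_normal(83)
            amp = 5 + 0.4 * cov + np.sqrt(1 - 0.16) * eta
            df = roi.covariate_correlation(amp, cov)
            hits += abs(df.r.iloc[0] - 0.4) < 0.15
        assert hits / 40 >= 0.85

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            roi.covariate_correlation(np.ones(10), np.ones(10))
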
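"""Channel selection, parcel aggregation, peak and prediction-error analysis.

Operations here sit between the beamformer output and the statistics:
selecting the sensors that drive the decoding, grouping them by N100
polarity, averaging voxels into the six regions of interest (LHG, RHG, LHP,
RHP, ACC, MC), removing zero-lag source leakage by symmetric
orthogonalization, extracting per-tone activity peaks, running the
prediction-error ANOVAs across sequential varied tones, and correlating
peak amplitudes with a per-subject covariate (musical training).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    ROI_NAMES,
    ROITimeSeries,
    SensorEpochs,
    SourceGrid,
    SourceTimeSeries,
)
from .stats import fdr_bh, one_way_anova, pointwise_contrast, tukey_kramer_posthoc


def select_top_channels(pattern_magnitudes: np.ndarray,
                        channel_types: np.ndarray | None = None
                        ) -> np.ndarray:
    """Channels whose pattern magnitude exceeds mean + 1 SD.

    The threshold is computed separately per channel type (magnetometers
    and gradiometers live on different scales).  Strict inequality and the
    sample SD (ddof = 1) are used, so an all-equal input selects nothing.
    Returns channel indices.
    """
    mags = np.asarray(pattern_magnitudes, dtype=float)
    if mags.size < 2:
        raise ValueError("need at least 2 channels")
    if channel_types is None:
        channel_types = np.array(["mag"] * mags.size, dtype=object)
    selected = []
    for ct in np.unique(channel_types):
        idx = np.flatnonzero(channel_types == ct)
        if len(idx) < 2:
            continue
        vals = mags[idx]
        thr = vals.mean() + vals.std(ddof=1)
        selected.extend(idx[vals > thr])
    return np.sort(np.asarray(selected, dtype=int))


def group_by_polarity(epochs: SensorEpochs,
                      channels: np.ndarray,
                      n100_window_s: tuple[float, float] = (0.070, 0.130),
                      ) -> dict[str, np.ndarray]:
    """Split selected channels by N100 polarity and average each group.

    The same neural source projects with both polarities onto different MEG
    sensors, so averaging without polarity grouping cancels the signal.
    Channels are split by the sign of the grand-average evoked value in the
    first-tone N100 window; each group is averaged into one conditions x
    time series.  Returns {'negative': ..., 'positive': ...} per-condition
    dicts; an empty group is omitted with a warning.
    """
    channels = np.asarray(channels, dtype=int)
    a = epochs.time_zero + int(round(n100_window_s[0] * epochs.sfreq))
    b = epochs.time_zero + int(round(n100_window_s[1] * epochs.sfreq))
    evoked = epochs.data.mean(axis=0)  # channels x time
    pol = evoked[channels, a:b].mean(axis=1)
    out: dict[str, dict] = {}
    for name, grp in (("negative", channels[pol < 0]),
                      ("positive", channels[pol >= 0])):
        if len(grp) == 0:
            warnings.warn(f"empty {name}-polarity group omitted",
                          stacklevel=2)
            continue
        series = {}
        for cond in np.unique(epochs.labels):
            avg = epochs.data[epochs.labels == cond][:, grp, :].mean(axis=(0, 1))
            series[str(cond)] = avg
        out[name] = series
    return out


def aggregate_parcels(src: SourceTimeSeries,
                      grid: SourceGrid | None = None,
                      roi_names: tuple[str, ...] = ROI_NAMES) -> dict:
    """Unweighted mean of member-voxel series per ROI.

    For evoked input returns {condition: ROI x time}; for induced input
    returns trials x ROI x time.
    """
    grid = grid if grid is not None else src.grid
    members = []
    for roi in roi_names:
        vox = grid.roi_voxels(roi)
        if len(vox) == 0:
            raise ValueError(f"ROI {roi} has no member voxels")
        members.append(vox)
    if src.mode == "evoked":
        return {cond: np.stack([arr[vox].mean(axis=0) for vox in members])
                for cond, arr in src.data.items()}
    return np.stack([src.data[:, vox, :].mean(axis=1) for vox in members],
                    axis=1)


def symmetric_orthogonalize(x: np.ndarray, tol: float = 1e-10,
                            max_iter: int = 200) -> np.ndarray:
    """Closest set of mutually orthogonal time series (least squares).

    Source leakage makes reconstructed ROI series spuriously correlated at
    zero lag.  This finds Y = U diag(d), U orthonormal columns, minimising
    ||X - Y||_F by alternating a polar decomposition (for U) with the
    optimal per-column scales d, so the output has exactly zero zero-lag
    correlations while staying as close as possible to the input.
    ``x`` is time x series; already-orthogonal input is a fixed point.
    """
    X = np.asarray(x, dtype=float)
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many time points as series")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient input: series are collinear")
    d = np.linalg.norm(X, axis=0)
    prev = np.inf
    for _ in range(max_iter):
        A = X * d  # X diag(d)
        U, _, Vt = np.linalg.svd(A, full_matrices=False)
        O = U @ Vt  # polar orthonormal factor, closest to A
        d = np.einsum("ts,ts->s", X, O)
        err = np.linalg.norm(X - O * d)
        if abs(prev - err) < tol * max(np.linalg.norm(X), 1.0):
            break
        prev = err
    return O * d


def orthogonalize_roi(roi_ts: ROITimeSeries) -> ROITimeSeries:
    """Apply symmetric orthogonalization per subject and condition."""
    out = np.empty_like(roi_ts.data)
    ns, nc = roi_ts.data.shape[:2]
    for s in range(ns):
        for c in range(nc):
            out[s, c] = symmetric_orthogonalize(roi_ts.data[s, c].T).T
    return ROITimeSeries(data=out, roi_names=roi_ts.roi_names,
                         conditions=roi_ts.conditions, sfreq=roi_ts.sfreq,
                         time_zero=roi_ts.time_zero, leakage_corrected=True)


def extract_peaks(series: dict[str, np.ndarray],
                  tone_onsets_samples: np.ndarray,
                  sfreq: float,
                  search_ms: float = 400.0,
                  avg_halfwidth_ms: float = 20.0) -> pd.DataFrame:
    """Per-tone maximum/minimum peaks of condition-average series.

    ``series`` maps condition -> 1D time series.  For tones 2-5 (tone 1 is
    identical across conditions and skipped), the argmax and argmin within
    the 400-ms post-onset search window are located per condition, and the
    amplitude is averaged over +-20 ms around each peak.  Argmax ties break
    to the earliest sample.  Returns a tidy frame with columns condition,
    tone, kind (max|min), peak_sample, amplitude.
    """
    search = int(round(search_ms / 1000.0 * sfreq))
    half = int(round(avg_halfwidth_ms / 1000.0 * sfreq))
    rows = []
    for cond, y in series.items():
        n = len(y)
        for tone_i, onset in enumerate(tone_onsets_samples[1:], start=2):
            a, b = onset, min(onset + search, n)
            if b > n or a >= n:
                warnings.warn("search window truncated at epoch end",
                              stacklevel=2)
                b = n
            seg = y[a:b]
            for kind, rel in (("max", int(np.argmax(seg))),
                              ("min", int(np.argmin(seg)))):
                peak = a + rel
                lo, hi = max(peak - half, 0), min(peak + half + 1, n)
                rows.append({"condition": cond, "tone": tone_i,
                             "kind": kind, "peak_sample": peak,
                             "amplitude": float(y[lo:hi].mean())})
    return pd.DataFrame(rows)


def peak_contrast_sources(src_per_subject: list[dict],
                          pair: tuple[str, str],
                          peak_sample: int,
                          halfwidth_samples: int = 5,
                          alpha: float = 0.05
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise paired contrast of window-averaged absolute activity.

    For each subject's evoked source reconstruction, the absolute activity
    is averaged over +-halfwidth samples around the peak; a two-sided
    paired t-test per voxel is BH-FDR corrected.  Returns (t map, p map,
    FDR mask), each of length n_voxels.
    """
    a = peak_sample - halfwidth_samples
    b = peak_sample + halfwidth_samples + 1

    def windowed(sub: dict, cond: str) -> np.ndarray:
        return np.abs(sub[cond][:, a:b]).mean(axis=1)

    va = np.stack([windowed(s, pair[0]) for s in src_per_subject])
    vb = np.stack([windowed(s, pair[1]) for s in src_per_subject])
    t, p = pointwise_contrast(va, vb)
    mask, _ = fdr_bh(p, alpha)
    return t, p, mask


# prediction-error peak latencies: late N100 in auditory cortex, slower
# responses in hippocampus and cingulate
PE_LATENCY_MS = {"LHG": 150.0, "RHG": 150.0, "LHP": 250.0, "RHP": 250.0,
                 "ACC": 250.0, "MC": 250.0}


def prediction_error_peak_amplitudes(roi_ts: ROITimeSeries,
                                     tone_onsets_samples: np.ndarray,
                                     condition: str,
                                     avg_halfwidth_ms: float = 20.0,
                                     latency_ms: dict | None = None
                                     ) -> dict[str, np.ndarray]:
    """Per-subject windowed amplitudes at each sequential varied-tone peak.

    For NTk the varied tones are k+1..5.  Returns {roi: subjects x n_peaks}.
    """
    lat = dict(PE_LATENCY_MS)
    if latency_ms:
        lat.update(latency_ms)
    k = int(condition[2:])
    varied = tone_onsets_samples[k:]  # onsets of tones k+1..5
    half = int(round(avg_halfwidth_ms / 1000.0 * roi_ts.sfreq))
    cidx = roi_ts.conditions.index(condition)
    out = {}
    n_times = roi_ts.data.shape[-1]
    for r, roi in enumerate(roi_ts.roi_names):
        shift = int(round(lat[roi] / 1000.0 * roi_ts.sfreq))
        cols = []
        for onset in varied:
            c = onset + shift
            lo, hi = max(c - half, 0), min(c + half + 1, n_times)
            if lo >= n_times:
                raise ValueError("peak window outside the epoch")
            cols.append(roi_ts.data[:, cidx, r, lo:hi].mean(axis=1))
        out[roi] = np.stack(cols, axis=1)
    return out


def prediction_error_anovas(roi_ts: ROITimeSeries,
                            tone_onsets_samples: np.ndarray,
                            conditions: tuple[str, ...] = ("NT1", "NT2", "NT3"),
                            rois: tuple[str, ...] = ROI_NAMES,
                            alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVAs over sequential varied-tone peaks, per ROI x condition.

    Six ROIs x (NT1, NT2, NT3) = 18 ANOVAs; NT4 has a single varied tone
    and no within-condition comparison.  The 18 p-values are BH-FDR
    corrected and Tukey-Kramer pairwise post-hocs are attached per ANOVA.
    Columns: roi, condition, F, df1, df2, p, p_fdr, significant, posthoc.
    """
    rows = []
    for cond in conditions:
        amps = prediction_error_peak_amplitudes(roi_ts, tone_onsets_samples,
                                                cond)
        for roi in rois:
            if roi not in amps:
                raise ValueError(f"missing peak columns for ROI {roi}")
            groups = [amps[roi][:, j] for j in range(amps[roi].shape[1])]
            F, dof, p = one_way_anova(*groups)
            rows.append({"roi": roi, "condition": cond, "F": F,
                         "df1": dof[0], "df2": dof[1], "p": p,
                         "posthoc": tukey_kramer_posthoc(*groups)})
    df = pd.DataFrame(rows)
    mask, p_adj = fdr_bh(df["p"].to_numpy(), alpha)
    df["p_fdr"] = p_adj
    df["significant"] = mask
    return df


def covariate_correlation(peak_amplitudes: np.ndarray,
                          covariate: np.ndarray,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of per-subject |peak amplitude| with a covariate.

    ``peak_amplitudes`` is subjects x n_peaks (absolute values are taken
    here); the n_peaks p-values form one BH-FDR family, mirroring a
    per-hemisphere peak table.  Columns: peak, r, p, p_fdr, significant.
    """
    amps = np.abs(np.asarray(peak_amplitudes, dtype=float))
    cov = np.asarray(covariate, dtype=float)
    if np.std(cov) == 0:
        raise ValueError("zero-variance covariate")
    if amps.ndim == 1:
        amps = amps[:, None]
    rows = []
    for j in range(amps.shape[1]):
        if np.std(amps[:, j]) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = sps.pearsonr(amps[:, j], cov)
        rows.append({"peak": j, "r": float(r), "p": float(p)})
    df = pd.DataFrame(rows)
    mask, p_adj = fdr_bh(df["p"].to_numpy(), alpha)
    df["p_fdr"] = p_adj
    df["significant"] = mask
    return df
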
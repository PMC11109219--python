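"""Synthetic cohort generator for the five-condition sequence-recognition design.

The generator emulates an old/new auditory recognition experiment: subjects
memorise three five-tone melodies ("M" sequences) and are then presented with
memorised and systematically varied ("novel", NT1-NT4) sequences while MEG is
recorded.  NTk sequences copy the first k tones of a memorised sequence and
change every tone afterwards, so the first varied tone occurs at tone k+1.

Everything downstream (beamforming, decoding, cluster statistics, ROI and
time-frequency analysis, model comparison) is exercised on this output; the
injected effects are recorded in :class:`~seqmeg.datatypes.GroundTruth` so
recovery can be asserted.

Amplitudes are in arbitrary field units.  Signals are defined in the
"sign-aligned" convention (first-tone onset response negative in every ROI);
the beamformer's N100 sign alignment restores this convention after source
reconstruction, where mixing through the leadfield scrambles per-voxel signs.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITIONS,
    ROI_NAMES,
    GroundTruth,
    Leadfield,
    ModelSpec,
    ROITimeSeries,
    SensorEpochs,
    SequenceDesign,
    SourceGrid,
)

# --------------------------------------------------------------------------
# defaults: these ARE the study conditions the generator emulates
# --------------------------------------------------------------------------

DEFAULT_DESIGN = {
    "n_trials_per_condition": 27,
    "tone_duration_ms": 350.0,
    "n_tones": 5,
    "epoch_ms": 4500.0,
    "baseline_ms": 100.0,
    "sfreq": 250.0,
}

# three memorised base melodies (integer pitches, 12-tone chromatic set)
BASE_SEQUENCES = (
    (60, 63, 67, 63, 60),
    (62, 65, 68, 65, 62),
    (59, 62, 67, 62, 59),
)

# per base sequence and novel category: 2 inverted contours, 3 tone
# scrambles, 3 same-tone variants, 1 interval scramble = 9 variations
STRATEGY_SCHEDULE = (
    "inverted_contour",
    "inverted_contour",
    "scrambled_tones",
    "scrambled_tones",
    "scrambled_tones",
    "same_tone",
    "same_tone",
    "same_tone",
    "scrambled_intervals",
)

DEFAULT_EFFECTS = {
    # tone-onset response in auditory cortex, every tone / condition
    "n100": {"latency_ms": 100.0, "width_ms": 30.0,
             "amplitude": {"LHG": -1.0, "RHG": -1.0}},
    # widespread response to the first tone: the sign-alignment anchor
    "onset_anchor": {"latency_ms": 100.0, "width_ms": 40.0,
                     "amplitude": {"LHP": -0.5, "RHP": -0.5,
                                   "ACC": -0.5, "MC": -0.5}},
    # recognition peak ~350 ms after tones 2-5, memorised sequences only
    "m_peak": {"latency_ms": 350.0, "width_ms": 40.0,
               "amplitude": {"RHG": 0.5, "LHP": 0.5, "RHP": 0.5,
                             "ACC": 0.5, "MC": -0.5}},
    # prediction error ~250 ms after each varied tone, novel sequences;
    # strongest for the first varied tone, decaying over subsequent ones
    "prediction_error": {"latency_ms": 250.0, "width_ms": 40.0,
                         "amplitude": {"LHP": -0.5, "RHP": -0.5,
                                       "ACC": -0.5, "MC": 0.5},
                         "sequential_scale": (1.0, 0.55, 0.45, 0.40)},
    # late N100 in Heschl's gyrus, ~150 ms after every varied tone,
    # constant across sequential varied tones
    "late_n100": {"latency_ms": 150.0, "width_ms": 30.0,
                  "amplitude": {"LHG": -0.6, "RHG": -0.6},
                  "sequential_scale": (1.0, 1.0, 1.0, 1.0)},
    # induced (non-phase-locked) band-limited bursts, 1.0-3.0 s
    "induced_low": {"band_hz": (2.0, 20.0), "window_s": (1.0, 3.0),
                    "amplitude": 0.5, "conditions": "N"},
    "induced_high": {"band_hz": (30.0, 60.0), "window_s": (1.0, 3.0),
                     "amplitude": 0.5, "conditions": "M"},
    # per-subject, per-ROI timing variability of the evoked deflections
    "latency_jitter_ms": 10.0,
    # between-subject amplitude variability and covariate coupling
    "subject_sd": 0.2,
    "covariate_loading": 0.4,
    "covariate_rel_sd": 0.3,
}

DEFAULT_NOISE = {
    "white_sd": 0.2,      # per-channel white sensor noise
    "pink_sd": 0.2,       # 1/f sensor noise
    "pink_exponent": 1.0,
    "source_sd": 0.3,     # ongoing 1/f activity per ROI source, per trial
    "background_sd": 0.1,  # ongoing 1/f activity in every non-ROI voxel
}

# per-condition accuracy probabilities and reaction-time parameters,
# matching the observed condition means (27 trials/condition); NT4 shows
# the behavioural deficit
DEFAULT_BEHAVIOR = {
    "p_correct": {"M": 22.33 / 27, "NT1": 22.36 / 27, "NT2": 21.58 / 27,
                  "NT3": 21.66 / 27, "NT4": 17.04 / 27},
    "rt_mean_ms": {"M": 2426.0, "NT1": 2407.0, "NT2": 2431.0,
                   "NT3": 2415.0, "NT4": 2578.0},
    "rt_sd_ms": {"M": 226.0, "NT1": 284.0, "NT2": 282.0,
                 "NT3": 272.0, "NT4": 259.0},
    "ability_sd": 0.15,   # between-subject shift of p_correct
}

DEFAULT_DYNAMICS = {
    # coupling kept below the self-decay (diagonal dominance) so every
    # architecture in the model space is stable under subject jitter
    "forward_weight": 2.0,    # s^-1
    "backward_weight": 1.0,   # s^-1
    "self_decay": -6.0,       # s^-1
    "input_gain": 30.0,
    "drive_peak_s": 0.06,
    "drive_width_s": 0.025,
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


# --------------------------------------------------------------------------
# sequence design
# --------------------------------------------------------------------------

def _invert_contour(base: np.ndarray, v: int, rng: np.random.Generator) -> np.ndarray:
    """Mirror the melodic intervals from the first varied tone onward."""
    out = base.copy()
    for j in range(v, len(base)):
        out[j] = out[j - 1] - (base[j] - base[j - 1])
    if out[v] == base[v]:  # flat interval: inversion is a no-op, nudge
        out[v:] += int(rng.choice([-2, 2]))
    return out

def _scramble_tones(base: np.ndarray, v: int, rng: np.random.Generator) -> np.ndarray:
    """Permute the remaining tones; single remaining tone is replaced."""
    out = base.copy()
    tail = base[v:]
    if len(set(tail.tolist())) < 2:
        # cannot differ by permutation: substitute a random different tone
        choices = [p for p in range(base.min() - 5, base.max() + 6)
                   if p != base[v]]
        out[v] = int(rng.choice(choices))
        return out
    for _ in range(100):
        perm = rng.permutation(tail)
        if perm[0] != base[v]:
            out[v:] = perm
            return out
    out[v] = tail[tail != base[v]][0]  # deterministic fallback
    return out

def _same_tone(base: np.ndarray, v: int, rng: np.random.Generator) -> np.ndarray:
    """Repeat one tone, varying only the octave (+-12 semitones)."""
    out = base.copy()
    t = int(base[v] + rng.choice([-12, 12]))
    out[v] = t  # first varied tone must differ from the original
    for j in range(v + 1, len(base)):
        out[j] = t + int(rng.choice([-12, 0, 0]))
    return out

def _scramble_intervals(base: np.ndarray, v: int, rng: np.random.Generator) -> np.ndarray:
    """Permute the melodic intervals of the remaining segment."""
    out = base.copy()
    ivs = np.diff(base[v - 1:])
    if len(ivs) == 1 or len(set(ivs.tolist())) < 2:
        out[v:] = base[v - 1] - np.cumsum(ivs)  # invert instead
        if out[v] == base[v]:
            out[v:] += int(rng.choice([-2, 2]))
        return out
    for _ in range(100):
        perm = rng.permutation(ivs)
        if perm[0] != ivs[0]:
            out[v:] = base[v - 1] + np.cumsum(perm)
            return out
    out[v:] = base[v - 1] + np.cumsum(ivs[::-1])
    if out[v] == base[v]:
        out[v:] += int(rng.choice([-2, 2]))
    return out


_STRATEGY_FN = {
    "inverted_contour": _invert_contour,
    "scrambled_tones": _scramble_tones,
    "same_tone": _same_tone,
    "scrambled_intervals": _scramble_intervals,
}


def build_design(config: dict | None = None,
                 rng: np.random.Generator | int | None = 0) -> SequenceDesign:
    """Build the five-condition sequence design.

    Defaults give 27 trials per condition (135 total, 108 novel): each of the
    3 memorised base melodies is presented 9 times, and for each novel
    category the 9 variations per base melody follow the fixed strategy
    schedule (2 inverted contours, 3 tone scrambles, 3 same-tone variants,
    1 interval scramble).
    """
    cfg = dict(DEFAULT_DESIGN)
    if config:
        cfg.update(config)
    rng = np.random.default_rng(rng)

    n_per = int(cfg["n_trials_per_condition"])
    tone_ms = float(cfg["tone_duration_ms"])
    n_tones = int(cfg["n_tones"])
    epoch_ms = float(cfg["epoch_ms"])
    baseline_ms = float(cfg["baseline_ms"])
    if n_per <= 0 or tone_ms <= 0 or epoch_ms <= 0 or cfg["sfreq"] <= 0:
        raise ConfigurationError("counts and durations must be positive")
    if baseline_ms < 0:
        raise ConfigurationError("baseline must be non-negative")
    if baseline_ms + n_tones * tone_ms > epoch_ms:
        raise ConfigurationError("epoch too short for the tone sequence")

    bases = [np.asarray(b, dtype=int) for b in BASE_SEQUENCES]
    n_bases = len(bases)
    reps, rem = divmod(n_per, n_bases)
    if rem:
        raise ConfigurationError(
            f"n_trials_per_condition={n_per} not divisible by the "
            f"{n_bases} base sequences")

    conditions, pitches, varied_from, strategy = [], [], [], []
    # memorised trials: each base repeated
    for b in bases:
        for _ in range(reps):
            conditions.append("M")
            pitches.append(b.copy())
            varied_from.append(0)
            strategy.append("")
    # novel trials
    schedule = (STRATEGY_SCHEDULE * ((reps // len(STRATEGY_SCHEDULE)) + 1))[:reps]
    for k in range(1, 5):  # NT1..NT4, first varied tone = k+1 (1-based)
        v = k  # 0-based index of first varied tone
        for b in bases:
            for strat in schedule:
                seq = _STRATEGY_FN[strat](b, v, rng)
                assert np.array_equal(seq[:v], b[:v])
                assert seq[v] != b[v]
                conditions.append(f"NT{k}")
                pitches.append(seq)
                varied_from.append(k + 1)
                strategy.append(strat)

    return SequenceDesign(
        n_trials_per_condition=n_per,
        conditions=np.array(conditions, dtype=object),
        tone_onsets_ms=np.arange(n_tones) * tone_ms,
        tone_duration_ms=tone_ms,
        epoch_ms=epoch_ms,
        baseline_ms=baseline_ms,
        sfreq=float(cfg["sfreq"]),
        pitch_sequences=np.vstack(pitches),
        varied_from=np.asarray(varied_from, dtype=int),
        variation_strategy=np.array(strategy, dtype=object),
    )


# --------------------------------------------------------------------------
# source grid and leadfield
# --------------------------------------------------------------------------

_ROI_CENTERS = {  # grid-index coordinates on the default (8, 8, 5) box
    "LHG": (1, 2, 1), "RHG": (6, 2, 1),
    "LHP": (1, 5, 1), "RHP": (6, 5, 1),
    "ACC": (3, 6, 3), "MC": (4, 2, 4),
}


def make_grid(shape: tuple[int, int, int] = (8, 8, 5),
              spacing_mm: float = 8.0,
              roi_radius_mm: float | None = None) -> SourceGrid:
    """Regular box grid with six non-overlapping spherical ROIs.

    Voxels within ``roi_radius_mm`` (default 1.01 * spacing, i.e. the voxel
    and its face neighbours) of an ROI centre get that ROI's label; all
    remaining voxels are labelled ``other``.
    """
    if roi_radius_mm is None:
        roi_radius_mm = 1.01 * spacing_mm
    ii = np.indices(shape).reshape(3, -1).T
    coords = ii * spacing_mm
    labels = np.full(coords.shape[0], "other", dtype=object)
    scale = np.array([shape[0] / 8.0, shape[1] / 8.0, shape[2] / 5.0])
    for roi, c in _ROI_CENTERS.items():
        center = np.asarray(c) * scale * spacing_mm
        d = np.linalg.norm(coords - center, axis=1)
        labels[d <= roi_radius_mm] = roi
    for roi in ROI_NAMES:
        if not np.any(labels == roi):
            # guarantee non-empty ROIs on tiny grids: claim nearest voxel
            center = np.asarray(_ROI_CENTERS[roi]) * scale * spacing_mm
            free = np.flatnonzero(labels == "other")
            if len(free) == 0:
                raise ConfigurationError("grid too small for six ROIs")
            d = np.linalg.norm(coords[free] - center, axis=1)
            labels[free[np.argmin(d)]] = roi
    return SourceGrid(coords=coords.astype(float), spacing_mm=spacing_mm,
                      parcel_label=labels)


def make_leadfield(n_channels: int,
                   grid: SourceGrid | tuple | None = None,
                   rng: np.random.Generator | int | None = 0,
                   corr_length_mm: float = 16.0) -> Leadfield:
    """Seeded smooth random gain tensor (sources x 3 orientations x channels).

    Gains are drawn from a Gaussian random field over voxel positions with
    squared-exponential spatial covariance, so nearby voxels see correlated
    sensor patterns, as any physical forward model produces.  The inverse
    solution is leadfield-agnostic, so a full-rank random gain exercises it.
    """
    if n_channels < 2:
        raise ConfigurationError("need at least 2 channels")
    if grid is None:
        grid = make_grid()
    elif isinstance(grid, tuple):
        grid = make_grid(shape=grid)
    rng = np.random.default_rng(rng)
    d = np.linalg.norm(grid.coords[:, None, :] - grid.coords[None, :, :], axis=2)
    K = np.exp(-0.5 * (d / corr_length_mm) ** 2)
    K[np.diag_indices_from(K)] += 1e-8
    chol = np.linalg.cholesky(K)
    gain = chol @ rng.standard_normal((grid.n_voxels, 3 * n_channels))
    gain = gain.reshape(grid.n_voxels, 3, n_channels)
    norms = np.linalg.norm(gain.reshape(grid.n_voxels, -1), axis=1)
    if np.any(norms == 0):
        raise ConfigurationError("degenerate leadfield: all-zero source row")
    return Leadfield(gain=gain, grid=grid)


# --------------------------------------------------------------------------
# noise and burst helpers
# --------------------------------------------------------------------------

def pink_noise(shape: tuple, sfreq: float, rng: np.random.Generator,
               exponent: float = 1.0) -> np.ndarray:
    """1/f noise: spectrally shaped white noise, unit SD, over the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / sfreq)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _band_burst(n_times: int, sfreq: float, band: tuple[float, float],
                window: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-SD band-limited noise burst with random phase, Hann-windowed."""
    white = rng.standard_normal(n_times)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    sig = np.fft.irfft(spec, n=n_times)
    env = np.zeros(n_times)
    a, b = window
    env[a:b] = np.hanning(b - a)
    sig = sig * env
    sd = sig[a:b].std()
    return sig / sd if sd > 0 else sig


def _gauss_bump(times_s: np.ndarray, center_s: float, width_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_s - center_s) / width_s) ** 2)


# --------------------------------------------------------------------------
# subject simulation
# --------------------------------------------------------------------------

def default_channel_types(n_channels: int) -> np.ndarray:
    """1/3 magnetometers, 2/3 gradiometers, matching a 306-channel layout."""
    n_mag = max(n_channels // 3, 1)
    return np.array(["mag"] * n_mag + ["grad"] * (n_channels - n_mag),
                    dtype=object)


def simulate_subject(design: SequenceDesign,
                     leadfield: Leadfield,
                     effect_params: dict | None = None,
                     noise_params: dict | None = None,
                     rng: np.random.Generator | int | None = None,
                     covariate: float | None = None,
                     channel_types: np.ndarray | None = None,
                     ) -> tuple[SensorEpochs, GroundTruth]:
    """Simulate one subject's epoched sensor data.

    ROI source signals are sums of Gaussian-windowed evoked deflections and
    band-limited induced bursts (random phase per trial, so they vanish from
    the evoked average); they are mixed to the sensors through the leadfield
    with a fixed random dipole orientation per voxel, and 1/f + white sensor
    noise is added.  All injected effects are recorded in the returned
    :class:`GroundTruth`.
    """
    eff = copy.deepcopy(DEFAULT_EFFECTS)
    if effect_params is not None:
        for k, v in effect_params.items():
            if isinstance(v, dict) and k in eff and isinstance(eff[k], dict):
                eff[k].update(v)
            else:
                eff[k] = v
    noise = dict(DEFAULT_NOISE)
    if noise_params:
        noise.update(noise_params)
    rng = np.random.default_rng(rng)
    subject_seed = int(rng.integers(2 ** 31))
    rng = np.random.default_rng(subject_seed)

    n_times = design.n_times
    times = design.times_s()
    onsets_s = design.tone_onsets_ms / 1000.0
    epoch_end_s = times[-1]
    n_trials = design.n_trials
    n_rois = len(ROI_NAMES)
    roi_idx = {r: i for i, r in enumerate(ROI_NAMES)}

    if covariate is None:
        covariate = float(rng.standard_normal())
    subj_gain = max(0.2, 1.0 + eff["subject_sd"] * rng.standard_normal())
    # covariate-coupled multiplier for prediction-error peaks: correlation
    # with the covariate equals `covariate_loading` by construction
    load = float(eff["covariate_loading"])
    eta = float(rng.standard_normal())
    pe_gain = max(
        0.1,
        1.0 + eff["covariate_rel_sd"]
        * (load * covariate + np.sqrt(max(1 - load ** 2, 0.0)) * eta),
    )

    def _check_latency(lat_ms: float, name: str) -> None:
        if lat_ms / 1000.0 + onsets_s[-1] > epoch_end_s or lat_ms < 0:
            raise ConfigurationError(f"{name} latency outside the epoch")

    for name in ("n100", "onset_anchor", "m_peak", "prediction_error",
                 "late_n100"):
        _check_latency(eff[name]["latency_ms"], name)

    # subject-level timing variability, independent per ROI: evoked shapes
    # then differ across regions instead of being exact scaled copies
    jitter_s = {
        roi: eff["latency_jitter_ms"] / 1000.0 * rng.standard_normal()
        for roi in ROI_NAMES
    }

    effect_windows: dict = {"conditions": {}, "covariate_loading": load}

    # evoked templates per condition (identical across that condition's
    # trials); induced bursts and ongoing activity are then added per trial
    templates: dict[str, np.ndarray] = {}
    cond_vfrom = {"M": 0, "NT1": 2, "NT2": 3, "NT3": 4, "NT4": 5}
    for cond, vfrom in cond_vfrom.items():
        tpl = np.zeros((n_rois, n_times))
        # N100 on every tone in auditory cortex
        p = eff["n100"]
        for onset in onsets_s:
            for roi, amp in p["amplitude"].items():
                tpl[roi_idx[roi]] += subj_gain * amp * _gauss_bump(
                    times, onset + p["latency_ms"] / 1000.0 + jitter_s[roi],
                    p["width_ms"] / 1000.0)
        # widespread first-tone response (sign anchor)
        p = eff["onset_anchor"]
        for roi, amp in p["amplitude"].items():
            tpl[roi_idx[roi]] += subj_gain * amp * _gauss_bump(
                times,
                onsets_s[0] + p["latency_ms"] / 1000.0 + jitter_s[roi],
                p["width_ms"] / 1000.0)
        if cond == "M":
            p = eff["m_peak"]
            for onset in onsets_s[1:]:
                for roi, amp in p["amplitude"].items():
                    tpl[roi_idx[roi]] += subj_gain * amp * _gauss_bump(
                        times,
                        onset + p["latency_ms"] / 1000.0 + jitter_s[roi],
                        p["width_ms"] / 1000.0)
        else:
            varied = onsets_s[vfrom - 1:]
            for name in ("prediction_error", "late_n100"):
                p = eff[name]
                gain = pe_gain if name == "prediction_error" else 1.0
                for j, onset in enumerate(varied):
                    scale = p["sequential_scale"][min(j, 3)]
                    for roi, amp in p["amplitude"].items():
                        tpl[roi_idx[roi]] += (
                            subj_gain * gain * amp * scale * _gauss_bump(
                                times,
                                onset + p["latency_ms"] / 1000.0
                                + jitter_s[roi],
                                p["width_ms"] / 1000.0))
        templates[cond] = tpl

    src = np.stack([templates[c] for c in design.conditions])
    # induced bursts: random phase per trial, so they cancel in the evoked
    # average and appear only in per-trial power
    for name in ("induced_low", "induced_high"):
        p = eff[name]
        a = int(round((p["window_s"][0] - times[0]) * design.sfreq))
        b = int(round((p["window_s"][1] - times[0]) * design.sfreq))
        if not (0 <= a < b <= n_times):
            raise ConfigurationError(f"{name} window outside the epoch")
        if p["amplitude"] == 0:
            continue
        want_n = p["conditions"] == "N"
        for t in range(n_trials):
            if (design.conditions[t] != "M") != want_n:
                continue
            for r in range(n_rois):
                src[t, r] += subj_gain * p["amplitude"] * _band_burst(
                    n_times, design.sfreq, p["band_hz"], (a, b), rng)

    # mix to sensors: fixed random orientation per voxel, shared across trials
    grid = leadfield.grid
    n_channels = leadfield.n_channels
    orients = rng.standard_normal((grid.n_voxels, 3))
    orients /= np.linalg.norm(orients, axis=1, keepdims=True)
    vox_gain = np.einsum("vo,voc->vc", orients, leadfield.gain)

    # ongoing (non-task) source activity decorrelates the ROI signals at
    # the trial level, as real background brain activity does; without it
    # the injected anticorrelated sources would defeat any spatial filter
    src_mixed = src
    if noise["source_sd"] > 0:
        src_mixed = src + noise["source_sd"] * pink_noise(
            src.shape, design.sfreq, rng, noise["pink_exponent"])

    data = np.zeros((n_trials, n_channels, n_times))
    for r, roi in enumerate(ROI_NAMES):
        vox = grid.roi_voxels(roi)
        mix = vox_gain[vox].sum(axis=0) / max(len(vox), 1)  # channels
        data += src_mixed[:, r, None, :] * mix[None, :, None]

    if noise["background_sd"] > 0:
        other = grid.roi_voxels("other")
        if len(other):
            bg = noise["background_sd"] * pink_noise(
                (n_trials, len(other), n_times), design.sfreq, rng,
                noise["pink_exponent"])
            data += np.einsum("tvn,vc->tcn", bg, vox_gain[other])

    if noise["white_sd"] > 0:
        data += noise["white_sd"] * rng.standard_normal(data.shape)
    if noise["pink_sd"] > 0:
        data += noise["pink_sd"] * pink_noise(
            data.shape, design.sfreq, rng, noise["pink_exponent"])

    if channel_types is None:
        channel_types = default_channel_types(n_channels)
    epochs = SensorEpochs(
        data=data,
        labels=design.conditions.copy(),
        sfreq=design.sfreq,
        baseline_window=(0, design.time_zero),
        channel_types=np.asarray(channel_types, dtype=object),
        time_zero=design.time_zero,
    )
    effect_windows["effects"] = eff
    truth = GroundTruth(source_ts=src, effect_windows=effect_windows,
                        true_model_id=0, covariate=covariate,
                        subject_seed=subject_seed)
    return epochs, truth


def simulate_cohort(n_subjects: int,
                    design: SequenceDesign,
                    leadfield: Leadfield,
                    effect_params: dict | None = None,
                    noise_params: dict | None = None,
                    rng: np.random.Generator | int | None = 0,
                    ) -> list[tuple[SensorEpochs, GroundTruth]]:
    """Simulate ``n_subjects`` independent subjects from one master seed."""
    rng = np.random.default_rng(rng)
    return [simulate_subject(design, leadfield, effect_params, noise_params,
                             rng=rng)
            for _ in range(n_subjects)]


# --------------------------------------------------------------------------
# behaviour
# --------------------------------------------------------------------------

def simulate_behavior(design: SequenceDesign,
                      behav_params: dict | None = None,
                      n_subjects: int = 83,
                      rng: np.random.Generator | int | None = 0,
                      ) -> pd.DataFrame:
    """Simulate per-subject accuracy and reaction times.

    Correct counts are binomial draws around per-condition probabilities
    (with a subject-level ability shift); reaction times are normal draws.
    Defaults carry the NT4 deficit: lower accuracy and slower responses.
    Columns: subject, condition, n_correct, mean_rt_ms.
    """
    par = copy.deepcopy(DEFAULT_BEHAVIOR)
    if behav_params:
        for k, v in behav_params.items():
            if isinstance(v, dict) and k in par:
                par[k].update(v)
            else:
                par[k] = v
    for c, p in par["p_correct"].items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"p_correct[{c}]={p} outside [0, 1]")
    rng = np.random.default_rng(rng)
    n = design.n_trials_per_condition
    rows = []
    for s in range(n_subjects):
        ability = par["ability_sd"] * rng.standard_normal()
        for cond in CONDITIONS:
            p = float(np.clip(par["p_correct"][cond] + ability, 0.0, 1.0))
            rt = par["rt_mean_ms"][cond] + par["rt_sd_ms"][cond] \
                * rng.standard_normal()
            rows.append({"subject": s, "condition": cond,
                         "n_correct": int(rng.binomial(n, p)),
                         "mean_rt_ms": float(max(rt, 1.0))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# network dynamics (ground truth for model comparison)
# --------------------------------------------------------------------------

def make_drive(sfreq: float, duration_s: float = 0.35,
               peak_s: float | None = None,
               width_s: float | None = None) -> np.ndarray:
    """Gaussian stimulus drive entering the input nodes (bump at 60 ms)."""
    if peak_s is None:
        peak_s = DEFAULT_DYNAMICS["drive_peak_s"]
    if width_s is None:
        width_s = DEFAULT_DYNAMICS["drive_width_s"]
    t = np.arange(int(round(duration_s * sfreq))) / sfreq
    return np.exp(-0.5 * ((t - peak_s) / width_s) ** 2)


def build_connectivity(model: ModelSpec, params: dict | None = None) -> np.ndarray:
    """State matrix A (s^-1) for a model: decay on the diagonal, coupling on
    the architecture's edges only."""
    par = dict(DEFAULT_DYNAMICS)
    if params:
        par.update(params)
    idx = {n: i for i, n in enumerate(model.nodes)}
    A = np.eye(len(model.nodes)) * par["self_decay"]
    for src_node, dst in model.forward_edges:
        A[idx[dst], idx[src_node]] = par["forward_weight"]
    for src_node, dst in model.backward_edges:
        A[idx[dst], idx[src_node]] = par["backward_weight"]
    return A


def simulate_network_dynamics(model: ModelSpec,
                              drive: np.ndarray,
                              params: dict | None = None,
                              sfreq: float = 250.0,
                              input_nodes: tuple[str, ...] | None = None,
                              A: np.ndarray | None = None) -> np.ndarray:
    """Integrate the linear network x' = A x + c * drive over one tone window.

    Exact integration under piecewise-constant input via the matrix
    exponential.  Raises if A is unstable (an eigenvalue with positive real
    part), since such a system cannot model a transient evoked response.
    Returns nodes x time.
    """
    from scipy.linalg import expm

    par = dict(DEFAULT_DYNAMICS)
    if params:
        par.update(params)
    if A is None:
        A = build_connectivity(model, par)
    if np.any(np.linalg.eigvals(A).real > 0):
        raise ValueError("unstable connectivity matrix A")
    if input_nodes is None:
        input_nodes = model.input_nodes
    idx = {n: i for i, n in enumerate(model.nodes)}
    c = np.zeros(len(model.nodes))
    for n in input_nodes:
        c[idx[n]] = par["input_gain"]

    dt = 1.0 / sfreq
    E = expm(A * dt)
    # integral of expm(A s) ds over one step, applied to the held input
    M = np.linalg.solve(A, E - np.eye(A.shape[0]))
    x = np.zeros((len(model.nodes), len(drive)))
    for k in range(1, len(drive)):
        x[:, k] = E @ x[:, k - 1] + M @ (c * drive[k - 1])
    return x


def simulate_roi_cohort(n_subjects: int,
                        design: SequenceDesign,
                        model_for_tone: dict[int, int],
                        params: dict | None = None,
                        noise_sd: float = 0.05,
                        weight_jitter: float = 0.1,
                        rng: np.random.Generator | int | None = 0,
                        ) -> ROITimeSeries:
    """ROI-level evoked cohort whose per-tone dynamics follow known models.

    For each tone (1-based keys of ``model_for_tone``) the 350-ms post-onset
    window carries the response of the mapped architecture, with per-subject
    multiplicative jitter of the coupling weights.  Used for model-recovery
    tests of the free-energy comparison.  Output is in the sign-aligned
    evoked convention expected by :func:`seqmeg.bms.run_dcm_suite`.
    """
    from .bms import build_model_space

    rng = np.random.default_rng(rng)
    par = dict(DEFAULT_DYNAMICS)
    if params:
        par.update(params)
    space = {m.id: m for m in build_model_space()}
    onsets = design.tone_onset_samples()
    n_rois = len(ROI_NAMES)
    data = np.zeros((n_subjects, len(CONDITIONS), n_rois, design.n_times))
    for s in range(n_subjects):
        jit = dict(par)
        jit["forward_weight"] = par["forward_weight"] * max(
            0.2, 1 + weight_jitter * rng.standard_normal())
        jit["backward_weight"] = par["backward_weight"] * max(
            0.2, 1 + weight_jitter * rng.standard_normal())
        for tone, mid in model_for_tone.items():
            a = onsets[tone - 1]
            # integrate to the end of the epoch: responses decay naturally
            # and later windows see a superposition that still obeys the
            # same state equation (no artificial truncation edges)
            span_s = (design.n_times - a) / design.sfreq
            dr = make_drive(design.sfreq, span_s, jit["drive_peak_s"],
                            jit["drive_width_s"])
            x = simulate_network_dynamics(space[mid], dr, jit,
                                          sfreq=design.sfreq)
            data[s, :, :, a:] += x[None, :, :]
        data[s] += noise_sd * rng.standard_normal(data[s].shape)
    return ROITimeSeries(data=data, roi_names=ROI_NAMES,
                         conditions=CONDITIONS, sfreq=design.sfreq,
                         time_zero=design.time_zero)
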
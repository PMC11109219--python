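"""Complex Morlet wavelet induced-power analysis.

Per-trial time-frequency decomposition (1-60 Hz, 1-Hz steps by default)
separates induced (non-phase-locked) power from the evoked response: power
is computed trial by trial and only then averaged, so activity with random
phase across trials survives while it cancels in the evoked mean.  Baseline
correction subtracts, per frequency, the mean pre-stimulus power from all
time points.  Condition contrasts over the time x frequency plane are
corrected with the 2D cluster-based Monte-Carlo machinery.

The wavelets are the standard complex Morlets w(t, f) = exp(2*pi*i*f*t) *
exp(-t^2 / (2*sigma_t^2)) with sigma_t = n_cycles / (2*pi*f), L2-normalised;
the number of cycles grows linearly with frequency (f/2, minimum 3) so
temporal resolution tightens at high frequencies.  Convolution uses mirror
padding; samples within half a wavelet of the epoch edge are flagged.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .datatypes import ClusterResult, TFRepresentation
from .stats import mcs_correct, paired_sign_flip_permuter, pointwise_contrast

DEFAULT_FREQS = np.arange(1.0, 61.0)


def _n_cycles(freqs: np.ndarray, n_cycles: float | np.ndarray | None) -> np.ndarray:
    if n_cycles is None:
        return np.maximum(freqs / 2.0, 3.0)
    return np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)


def _morlet_kernel(freq: float, n_cyc: float, sfreq: float) -> np.ndarray:
    sigma_t = n_cyc / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return w / np.linalg.norm(w)


def morlet_tfr(data: np.ndarray,
               sfreq: float,
               freqs: np.ndarray = DEFAULT_FREQS,
               n_cycles: float | np.ndarray | None = None
               ) -> TFRepresentation:
    """Morlet-wavelet power of (trials x) time series.

    ``data`` is 1D (time) or 2D (trials x time); power is the squared
    modulus of the wavelet convolution, shape (trials x) freqs x time.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= sfreq / 2):
        raise ValueError("frequency at or above Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    cycles = _n_cycles(freqs, n_cycles)
    n_times = x.shape[-1]
    power = np.empty((x.shape[0], len(freqs), n_times))
    edge = np.zeros((len(freqs), n_times), dtype=bool)
    for i, (f, nc) in enumerate(zip(freqs, cycles)):
        kern = _morlet_kernel(f, nc, sfreq)
        half = len(kern) // 2
        if half >= n_times:
            raise ValueError(
                f"series shorter than the {f:g} Hz wavelet ({len(kern)} "
                f"samples)")
        padded = np.concatenate(
            [x[:, half:0:-1], x, x[:, -2:-2 - half:-1]], axis=1)
        conv = fftconvolve(padded, kern[None, :], mode="same", axes=1)
        power[:, i, :] = np.abs(conv[:, half:half + n_times]) ** 2
        edge[i, :half] = True
        edge[i, n_times - half:] = True
    power = power[0] if np.asarray(data).ndim == 1 else power
    return TFRepresentation(power=power, freqs=freqs, sfreq=sfreq,
                            edge_mask=edge)


def baseline_correct(tfr: TFRepresentation,
                     baseline_window: tuple[int, int]) -> TFRepresentation:
    """Subtract, per frequency, the mean baseline power from all times.

    ``baseline_window`` is a half-open sample range in the pre-stimulus
    period.  Idempotent up to the (re-zeroed) baseline mean.
    """
    a, b = baseline_window
    if b <= a:
        raise ValueError("empty baseline window")
    base = tfr.power[..., a:b].mean(axis=-1, keepdims=True)
    return TFRepresentation(power=tfr.power - base, freqs=tfr.freqs,
                            sfreq=tfr.sfreq, baseline_window=(a, b),
                            corrected=True, edge_mask=tfr.edge_mask)


def induced_power(trials: np.ndarray,
                  sfreq: float,
                  baseline_window: tuple[int, int],
                  freqs: np.ndarray = DEFAULT_FREQS,
                  n_cycles: float | np.ndarray | None = None) -> np.ndarray:
    """Trial-averaged baseline-corrected power (freqs x time) of one series
    set: the induced-response estimate for one subject/condition/ROI."""
    tfr = morlet_tfr(trials, sfreq, freqs, n_cycles)
    tfr = baseline_correct(tfr, baseline_window)
    return tfr.power.mean(axis=0)


def tfr_contrast(power_a: np.ndarray,
                 power_b: np.ndarray,
                 alpha: float = 0.05,
                 n_perm: int = 1000,
                 mcs_p: float = 0.001,
                 rng: np.random.Generator | int | None = 0,
                 mode: str = "permute_map"
                 ) -> tuple[np.ndarray, np.ndarray, ClusterResult]:
    """Paired contrast of subjects x freqs x time induced power.

    Two-sided t-test per time-frequency point, then 2D cluster-based MCS.
    The default null shuffles the binarized significance map itself
    (``permute_map``), the procedure used for time-frequency contrasts in
    this analysis tradition; ``permute_labels`` switches to subject-level
    sign-flip permutations.  Returns (t map, p map, ClusterResult);
    positive clusters mean condition a > b.
    """
    t, p = pointwise_contrast(power_a, power_b)
    permuter = (None if mode == "permute_map"
                else paired_sign_flip_permuter(power_a, power_b))
    clusters = mcs_correct(t, p, alpha=alpha, n_perm=n_perm, mcs_p=mcs_p,
                           permuter=permuter, rng=rng, mode=mode)
    return t, p, clusters
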
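"""LCMV beamformer inverse solution.

The sensor data B(t) are modelled as B(t) = L Q(t) + noise, with L the
single-orientation leadfield.  For each source q the spatial-filter weights

    W_q = (L_q^T C^-1 L_q)^-1 L_q^T C^-1

minimise output variance subject to unit gain at the source (W_q L_q = 1),
where C is the sensor covariance computed on the concatenated trials of all
conditions.  The three free dipole orientations are reduced to one
beforehand by taking the dominant singular vector of the source-space
projection (l^T C^-1 l)^-1, the standard SVD orientation reduction.  Weight
rows are Euclidean-normalised afterwards to counteract the depth bias of the
unnormalised activity index, and evoked source series are sign-aligned on
the N100 window of the first tone.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    BeamformerWeights,
    Leadfield,
    SensorCovariance,
    SensorEpochs,
    SourceTimeSeries,
)

DEFAULT_REGULARIZATION = 0.05  # diagonal loading, fraction of mean(diag(C))
DEFAULT_N100_WINDOW_S = (0.070, 0.130)  # after first tone onset


def compute_covariance(epochs: SensorEpochs,
                       reg: float = DEFAULT_REGULARIZATION) -> SensorCovariance:
    """Sensor covariance of the trial-concatenated data, diagonally loaded.

    Trials of all conditions are concatenated along time (one filter serves
    every condition); ``reg * mean(diag(C))`` is added to the diagonal.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials for a covariance estimate")
    if reg < 0:
        raise ValueError("regularization must be non-negative")
    # trials x channels x time -> channels x (trials * time)
    x = np.transpose(epochs.data, (1, 0, 2)).reshape(epochs.n_channels, -1)
    x = x - x.mean(axis=1, keepdims=True)
    n = x.shape[1]
    C = (x @ x.T) / (n - 1)
    C = C + reg * np.mean(np.diag(C)) * np.eye(C.shape[0])
    return SensorCovariance(C=C, n_samples=n, regularization=reg)


def reduce_orientation(leadfield: Leadfield,
                       cov: SensorCovariance) -> Leadfield:
    """Reduce the 3-orientation gain to one orientation per source.

    Per source, the dominant singular vector of (l C^-1 l^T)^-1 (the 3 x 3
    inverse source-space projection; pseudo-inverse when the gain spans
    fewer than three directions) selects the dipole orientation u1, and the
    reduced row is L_q = u1^T l_q.  This is the orientation maximising the
    beamformer output power (the unit-gain-constrained source-variance
    estimate), the standard scalar-beamformer choice; it is what makes
    single-dipole simulations localise to the generating voxel.
    """
    gain = leadfield.gain
    Cinv = np.linalg.inv(cov.C)
    n_src = gain.shape[0]
    reduced = np.empty((n_src, gain.shape[2]))
    for q in range(n_src):
        l = gain[q]  # 3 x channels
        S = l @ Cinv @ l.T  # 3 x 3 source-space projection
        if not np.any(S):
            raise np.linalg.LinAlgError(
                f"zero source-space projection at voxel {q}")
        # symmetric PSD: dominant singular vector of the (pseudo-)inverse
        # = eigenvector of the smallest non-null eigenvalue of S
        U, _, _ = np.linalg.svd(np.linalg.pinv(S))
        u1 = U[:, 0]
        reduced[q] = u1 @ l
    return Leadfield(gain=gain, grid=leadfield.grid, reduced=reduced)


def compute_weights(leadfield: Leadfield,
                    cov: SensorCovariance) -> BeamformerWeights:
    """LCMV weights W_q = (L_q^T C^-1 L_q)^-1 L_q^T C^-1 per source."""
    if leadfield.reduced is None:
        raise ValueError("orientation-reduced leadfield required; "
                         "run reduce_orientation first")
    L = leadfield.reduced  # sources x channels
    zero_rows = np.flatnonzero(np.all(L == 0, axis=1))
    if zero_rows.size:
        raise ValueError(f"all-zero leadfield row at voxel {zero_rows[0]}")
    LCinv = np.linalg.solve(cov.C, L.T).T  # rows L_q^T C^-1
    denom = np.einsum("qc,qc->q", LCinv, L)  # L_q^T C^-1 L_q
    W = LCinv / denom[:, None]
    return BeamformerWeights(W=W, normalized=False)


def normalize_weights(weights: BeamformerWeights) -> BeamformerWeights:
    """Divide each weight row by its Euclidean norm (depth-bias correction)."""
    norms = np.linalg.norm(weights.W, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm weight row")
    return BeamformerWeights(W=weights.W / norms[:, None], normalized=True,
                             sign_flip=weights.sign_flip)


def apply_weights(weights: BeamformerWeights,
                  epochs: SensorEpochs,
                  mode: str = "evoked",
                  grid=None) -> SourceTimeSeries:
    """Project sensor epochs to source space.

    ``evoked`` averages trials within each condition first (one sources x
    time array per condition); ``induced`` projects every trial, keeping the
    trial axis and labels for per-trial time-frequency analysis.
    """
    if mode not in ("evoked", "induced"):
        raise ValueError(f"unknown mode {mode!r}")
    W = weights.W
    if W.shape[1] != epochs.n_channels:
        raise ValueError(
            f"weights expect {W.shape[1]} channels, epochs have "
            f"{epochs.n_channels}")
    if mode == "evoked":
        data = {}
        for cond in np.unique(epochs.labels):
            avg = epochs.data[epochs.labels == cond].mean(axis=0)
            data[str(cond)] = W @ avg
        labels = None
    else:
        data = np.einsum("sc,tcn->tsn", W, epochs.data)
        labels = epochs.labels
    return SourceTimeSeries(data=data, mode=mode, grid=grid,
                            sfreq=epochs.sfreq, time_zero=epochs.time_zero,
                            labels=labels)


def align_sign(src: SourceTimeSeries,
               n100_window_s: tuple[float, float] = DEFAULT_N100_WINDOW_S,
               ) -> tuple[SourceTimeSeries, np.ndarray]:
    """Resolve the beamformer sign ambiguity via the first-tone N100.

    Per source, the sign is flipped so the mean over the N100 window (times
    relative to the first tone onset) is negative.  The same flip is applied
    to every condition so relative signs are preserved.  Idempotent.
    Returns the aligned series and the per-source flip vector.
    """
    if src.mode != "evoked":
        raise ValueError("sign alignment is defined for evoked series")
    a = src.time_zero + int(round(n100_window_s[0] * src.sfreq))
    b = src.time_zero + int(round(n100_window_s[1] * src.sfreq))
    if b <= a:
        raise ValueError("empty N100 window")
    # anchor on the grand mean across conditions
    stack = np.mean([v for v in src.data.values()], axis=0)
    win_mean = stack[:, a:b].mean(axis=1)
    flips = np.where(win_mean > 0, -1.0, 1.0)
    data = {c: v * flips[:, None] for c, v in src.data.items()}
    out = SourceTimeSeries(data=data, mode="evoked", grid=src.grid,
                           sfreq=src.sfreq, time_zero=src.time_zero)
    return out, flips


def reconstruct_evoked(epochs: SensorEpochs,
                       leadfield: Leadfield,
                       reg: float = DEFAULT_REGULARIZATION,
                       picks: str | None = "mag",
                       n100_window_s: tuple[float, float] = DEFAULT_N100_WINDOW_S,
                       ) -> SourceTimeSeries:
    """Full evoked pipeline: covariance -> orientation reduction -> weights
    -> normalisation -> projection -> sign alignment.

    ``picks='mag'`` reconstructs from magnetometers only (the default, as
    deep sources are better seen by magnetometers); ``picks=None`` uses all
    channels.
    """
    lf_in = leadfield
    if picks is not None and np.any(epochs.channel_types == picks):
        mask = epochs.channel_types == picks
        epochs = epochs.pick(picks)
        if leadfield.n_channels != epochs.n_channels:
            lf_in = Leadfield(gain=leadfield.gain[:, :, mask],
                              grid=leadfield.grid)
    cov = compute_covariance(epochs, reg)
    lf = reduce_orientation(lf_in, cov)
    w = normalize_weights(compute_weights(lf, cov))
    src = apply_weights(w, epochs, mode="evoked", grid=leadfield.grid)
    aligned, _ = align_sign(src, n100_window_s)
    return aligned
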
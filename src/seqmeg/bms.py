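"""Hierarchical network-model comparison via Laplace free energy and RFX BMS.

Six directed architectures over the six ROIs (auditory cortex LHG/RHG at
the bottom; hippocampus LHP/RHP, anterior cingulate ACC and medial
cingulate MC above) are compared on 350-ms per-tone windows of the evoked
ROI series.  The generative model is a linear state-space surrogate

    x'(t) = A(theta) x(t) + c * drive(t)

whose coupling matrix A has free entries only where an architecture allows
an edge (plus a self-decay diagonal), with auditory input entering LHG and
RHG.  Fitting is Bayesian linear regression of the (smoothed) temporal
derivative on the observed states and the drive, which makes the Laplace
posterior exact and gives the variational free energy in closed form:

    F = E_q[ln p(y | theta, m)] - KL[q(theta | y, m) || p(theta | m)]

i.e. accuracy minus complexity.  Subject-wise free energies are combined
with random-effects Bayesian model selection (variational Dirichlet scheme)
yielding posterior model probabilities, exceedance probabilities (EP),
the Bayesian omnibus risk (BOR: posterior probability that model
frequencies are uniform) and protected exceedance probabilities
PXP = EP * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from scipy.special import digamma, gammaln, logsumexp

from .datatypes import BMSResult, ModelFit, ModelSpec, ROITimeSeries

ROIS = ("LHG", "RHG", "LHP", "RHP", "ACC", "MC")
_HIGH = ("LHP", "RHP", "ACC", "MC")

DEFAULT_PRIORS = {
    "edge_mean": 0.0, "edge_sd": 1.0,      # coupling weights (s^-1)
    "self_mean": -5.0, "self_sd": 1.0,     # self-decay (s^-1)
    "input_mean": 0.0, "input_sd": 30.0,   # stimulus input gain
}


def _cross(srcs, dsts):
    return tuple((s, d) for s in srcs for d in dsts)


def build_model_space() -> list[ModelSpec]:
    """The six alternative network architectures.

    1: HG -> {HP, ACC, MC} with reciprocal feedback (the hypothesised
       two-level hierarchy); 2: feedforward-only variant of 1;
    3: HG -> HP -> {ACC, MC}; 4: HG -> {ACC, MC} -> HP;
    5: HG -> MC -> {ACC, HP}; 6: HG -> {ACC, HP} -> MC;
    3-6 with full reciprocal feedback.  Input always enters LHG and RHG.
    """
    hg = ("LHG", "RHG")
    hp = ("LHP", "RHP")
    specs = [
        ModelSpec(id=1, nodes=ROIS,
                  forward_edges=_cross(hg, _HIGH),
                  backward_edges=_cross(_HIGH, hg)),
        ModelSpec(id=2, nodes=ROIS,
                  forward_edges=_cross(hg, _HIGH),
                  backward_edges=()),
        ModelSpec(id=3, nodes=ROIS,
                  forward_edges=_cross(hg, hp) + _cross(hp, ("ACC", "MC")),
                  backward_edges=_cross(("ACC", "MC"), hp) + _cross(hp, hg)),
        ModelSpec(id=4, nodes=ROIS,
                  forward_edges=_cross(hg, ("ACC", "MC")) + _cross(("ACC", "MC"), hp),
                  backward_edges=_cross(hp, ("ACC", "MC")) + _cross(("ACC", "MC"), hg)),
        ModelSpec(id=5, nodes=ROIS,
                  forward_edges=_cross(hg, ("MC",)) + _cross(("MC",), ("ACC",) + hp),
                  backward_edges=_cross(("ACC",) + hp, ("MC",)) + _cross(("MC",), hg)),
        ModelSpec(id=6, nodes=ROIS,
                  forward_edges=_cross(hg, ("ACC",) + hp) + _cross(("ACC",) + hp, ("MC",)),
                  backward_edges=_cross(("MC",), ("ACC",) + hp) + _cross(("ACC",) + hp, hg)),
    ]
    return specs


def _smooth_derivative(y: np.ndarray, sfreq: float,
                       window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay derivative along the last axis (tempers the noise
    amplification of naive differencing)."""
    window = min(window, y.shape[-1] - (1 - y.shape[-1] % 2))
    if window <= polyorder:
        return np.gradient(y, 1.0 / sfreq, axis=-1)
    return savgol_filter(y, window, polyorder, deriv=1, delta=1.0 / sfreq,
                         axis=-1)


def fit_model(roi_window: np.ndarray,
              model: ModelSpec,
              drive: np.ndarray,
              sfreq: float,
              priors: dict | None = None,
              tone: int = 0,
              n_sigma_iter: int = 10) -> ModelFit:
    """Laplace fit of one architecture to one 6 x T ROI window.

    The derivative of each node is regressed on the node states (columns
    allowed by the architecture), its own state (self-decay) and the drive
    (input nodes only), under Gaussian priors.  The observation noise
    variance is estimated by evidence maximisation (restricted maximum of
    the Gaussian likelihood).  F, accuracy and complexity are exact for
    this Gaussian model.
    """
    y = np.asarray(roi_window, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite data in ROI window")
    pri = dict(DEFAULT_PRIORS)
    if priors:
        pri.update(priors)
    n_nodes, T = y.shape
    idx = {n: i for i, n in enumerate(model.nodes)}
    dy = _smooth_derivative(y, sfreq)

    # assemble parameters: self-decays, allowed edges, input gains
    names: list[str] = [f"self:{n}" for n in model.nodes]
    m0 = [pri["self_mean"]] * n_nodes
    s0 = [pri["self_sd"]] * n_nodes
    cols: list[tuple[int, np.ndarray]] = [(i, y[i]) for i in range(n_nodes)]
    for src, dst in model.edges:
        names.append(f"edge:{src}->{dst}")
        m0.append(pri["edge_mean"])
        s0.append(pri["edge_sd"])
        cols.append((idx[dst], y[idx[src]]))
    for n in model.input_nodes:
        names.append(f"input:{n}")
        m0.append(pri["input_mean"])
        s0.append(pri["input_sd"])
        cols.append((idx[n], np.asarray(drive, dtype=float)[:T]))

    d = len(names)
    # block design: rows ordered node-major (node 0 times, node 1 times, ...)
    X = np.zeros((n_nodes * T, d))
    for j, (node, regressor) in enumerate(cols):
        X[node * T:(node + 1) * T, j] = regressor
    r = dy.ravel()

    m0 = np.asarray(m0)
    P0 = np.diag(1.0 / np.square(s0))  # prior precision
    XtX = X.T @ X
    Xtr = X.T @ r
    n_obs = len(r)

    sigma2 = max(float(np.var(r)), 1e-12)
    for _ in range(n_sigma_iter):
        S = np.linalg.inv(P0 + XtX / sigma2)
        m = S @ (P0 @ m0 + Xtr / sigma2)
        resid = r - X @ m
        sigma2_new = (resid @ resid + np.einsum("ij,ji->", XtX, S)) / n_obs
        sigma2_new = max(float(sigma2_new), 1e-12)
        if abs(sigma2_new - sigma2) < 1e-10 * sigma2:
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new

    cond = np.linalg.cond(P0 + XtX / sigma2)
    if cond > 1e12:
        import warnings
        warnings.warn("ill-conditioned posterior; regularized", stacklevel=2)
        S = np.linalg.inv(P0 + XtX / sigma2 + 1e-8 * np.eye(d))

    resid = r - X @ m
    accuracy = (-0.5 * n_obs * np.log(2 * np.pi * sigma2)
                - (resid @ resid + np.einsum("ij,ji->", XtX, S))
                / (2 * sigma2))
    dm = m - m0
    sign, logdet_S = np.linalg.slogdet(S)
    logdet_S0 = float(np.sum(np.log(np.square(s0))))
    complexity = 0.5 * (np.trace(P0 @ S) + dm @ P0 @ dm - d
                        + logdet_S0 - logdet_S)
    complexity = max(float(complexity), 0.0)
    F = float(accuracy) - complexity
    return ModelFit(m=model.id, theta_mean=m, theta_cov=S, F=F,
                    accuracy_term=float(accuracy),
                    complexity_term=complexity,
                    window=(tone, 0, T), sigma2=sigma2, param_names=names)


# --------------------------------------------------------------------------
# random-effects Bayesian model selection
# --------------------------------------------------------------------------

def _dirichlet_vb(F: np.ndarray, alpha0: np.ndarray,
                  max_iter: int = 200, tol: float = 1e-8):
    """Variational Dirichlet scheme over model frequencies."""
    n, K = F.shape
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        logu = logu - logsumexp(logu, axis=1, keepdims=True)
        b = np.exp(logu)
        alpha_new = alpha0 + b.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, b


def _rfx_free_energy(F: np.ndarray, alpha0: np.ndarray,
                     alpha: np.ndarray, b: np.ndarray) -> float:
    """Free energy of the random-effects (alternative) model."""
    Elogr = digamma(alpha) - digamma(alpha.sum())
    # entropy of q(r) plus cross terms: standard Dirichlet-multinomial VB
    Sqf = (np.sum(gammaln(alpha)) - gammaln(alpha.sum())
           - np.sum((alpha - 1) * Elogr))
    with np.errstate(divide="ignore", invalid="ignore"):
        Sqm = -np.sum(np.where(b > 0, b * np.log(b), 0.0))
    ELJ = (gammaln(alpha0.sum()) - np.sum(gammaln(alpha0))
           + np.sum((alpha0 - 1) * Elogr)
           + np.sum(b * (Elogr[None, :] + F)))
    return float(ELJ + Sqf + Sqm)


def rfx_bms(F: np.ndarray,
            n_samples: int = 1_000_000,
            rng: np.random.Generator | int | None = 0) -> BMSResult:
    """Random-effects BMS over a subjects x models free-energy matrix.

    Returns expected posterior model frequencies, exceedance probabilities
    (by Dirichlet sampling), the Bayesian omnibus risk (posterior
    probability of the null that all model frequencies are equal) and the
    protected exceedance probabilities.  Adding a constant to every F entry
    leaves all outputs unchanged (evidence is relative).
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    if F.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite free energies")
    n, K = F.shape
    F = F - F.max(axis=1, keepdims=True)  # stabilise; invariant to shifts
    alpha0 = np.ones(K)
    alpha, b = _dirichlet_vb(F, alpha0)
    posterior = alpha / alpha.sum()

    rng = np.random.default_rng(rng)
    draws = rng.dirichlet(alpha, size=n_samples)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_samples

    F1 = _rfx_free_energy(F, alpha0, alpha, b)
    # null: all frequencies exactly equal (fixed uniform prior over models)
    F0 = float(np.sum(logsumexp(F - np.log(K), axis=1)))
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))
    pxp = xp * (1.0 - bor) + bor / K
    return BMSResult(posterior_prob=posterior, xp=xp, pxp=pxp, bor=bor,
                     dirichlet_alpha=alpha)


# --------------------------------------------------------------------------
# per-tone suite
# --------------------------------------------------------------------------

def run_dcm_suite(roi_ts: ROITimeSeries,
                  tone_onsets_samples: np.ndarray,
                  window_s: float = 0.350,
                  priors: dict | None = None,
                  drive: np.ndarray | None = None,
                  n_samples: int = 1_000_000,
                  rng: np.random.Generator | int | None = 0
                  ) -> dict[tuple[str, int], BMSResult]:
    """Eight per-tone model comparisons: M at tones 2-5, each novel
    condition at its first varied tone (NT1@2, NT2@3, NT3@4, NT4@5).

    Each analysis fits the six architectures to every subject's 350-ms ROI
    window and runs RFX BMS on the subjects x models free-energy matrix.
    """
    from .simulate import make_drive

    space = build_model_space()
    order = list(roi_ts.roi_names)
    if tuple(order[:6]) != ROIS:
        raise ValueError(f"ROI order must start with {ROIS}")
    win = int(round(window_s * roi_ts.sfreq))
    if drive is None:
        drive = make_drive(roi_ts.sfreq, window_s)
    analyses = [("M", tone) for tone in (2, 3, 4, 5)]
    analyses += [(f"NT{k}", k + 1) for k in (1, 2, 3, 4)]
    rng = np.random.default_rng(rng)
    n_subj = roi_ts.data.shape[0]
    results: dict[tuple[str, int], BMSResult] = {}
    for cond, tone in analyses:
        if cond not in roi_ts.conditions:
            raise ValueError(f"condition {cond} missing from ROI series")
        ci = roi_ts.conditions.index(cond)
        a = tone_onsets_samples[tone - 1]
        bnd = min(a + win, roi_ts.data.shape[-1])
        Fmat = np.empty((n_subj, len(space)))
        for s in range(n_subj):
            window = roi_ts.data[s, ci, :6, a:bnd]
            for j, spec in enumerate(space):
                Fmat[s, j] = fit_model(window, spec, drive, roi_ts.sfreq,
                                       priors=priors, tone=tone).F
        results[(cond, tone)] = rfx_bms(Fmat, n_samples=n_samples, rng=rng)
    return results
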
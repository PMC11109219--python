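"""Multiple-comparison machinery and the pointwise tests it corrects.

Two corrections are used throughout the pipeline:

* Benjamini-Hochberg FDR for families of independent tests (decoding time
  series, voxelwise contrasts, covariate correlations, ANOVA families);
* cluster-based Monte-Carlo simulation (MCS) for smooth 1D (time) and 2D
  (time x frequency, train-time x test-time) maps: p-values are binarized
  at ``alpha``, maximal contiguous clusters are found (runs in 1D,
  4-connected components in 2D), and an original cluster is kept when its
  size exceeds the (1 - mcs_p) quantile of the permutation distribution of
  maximum cluster sizes.

Cluster extent is measured as SIZE (number of contiguous significant
points); cluster mass is available as an option.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import ClusterResult


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------

def fdr_bh(pvals: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (rejection mask, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha,
                                        method="fdr_bh")
    return reject.reshape(p.shape), p_adj.reshape(p.shape)


# --------------------------------------------------------------------------
# clusters
# --------------------------------------------------------------------------

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def find_clusters(mask: np.ndarray,
                  signs: np.ndarray | None = None,
                  connectivity: int = 4) -> list[dict]:
    """Maximal connected components of a boolean 1D/2D map.

    1D clusters are runs of consecutive True entries; 2D clusters use
    4-connectivity by default (diagonally touching cells are separate).
    When ``signs`` is given, positive and negative entries form separate
    clusters.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim not in (1, 2):
        raise ValueError("only 1D and 2D maps are supported")
    structure = (np.ones(3, dtype=bool) if mask.ndim == 1
                 else _STRUCTURES[connectivity])
    pieces = []
    if signs is None:
        pieces.append((mask, 0))
    else:
        signs = np.sign(np.asarray(signs))
        pieces.append((mask & (signs > 0), 1))
        pieces.append((mask & (signs < 0), -1))
    clusters = []
    for m, sgn in pieces:
        lab, n = ndimage.label(m, structure=structure)
        for i in range(1, n + 1):
            idx = np.argwhere(lab == i)
            if mask.ndim == 1:
                idx = idx[:, 0]
            clusters.append({"indices": idx, "size": len(idx), "sign": sgn})
    clusters.sort(key=lambda c: -c["size"])
    return clusters


def _max_cluster_size(mask: np.ndarray, connectivity: int) -> int:
    if not mask.any():
        return 0
    structure = (np.ones(3, dtype=bool) if mask.ndim == 1
                 else _STRUCTURES[connectivity])
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def mcs_correct(stat_map: np.ndarray,
                pval_map: np.ndarray,
                alpha: float = 0.05,
                n_perm: int = 1000,
                mcs_p: float = 0.001,
                permuter: Callable[[np.random.Generator], np.ndarray] | None = None,
                rng: np.random.Generator | int | None = 0,
                mode: str = "permute_labels",
                connectivity: int = 4,
                use_mass: bool = False) -> ClusterResult:
    """Cluster-based Monte-Carlo multiple-comparison correction.

    Binarizes ``pval_map < alpha``, finds sign-split clusters of the
    original map, and builds the null distribution of maximum cluster sizes
    from ``n_perm`` permutations.  In ``permute_labels`` mode (default) the
    ``permuter`` callback regenerates a p-value map under label permutation,
    preserving the autocorrelation of the data; ``permute_map`` shuffles the
    binarized entries themselves (anticonservative for smooth maps, kept for
    comparability).  A cluster is significant when its size strictly exceeds
    the (1 - mcs_p) quantile of the null maxima; its ``mcs_p`` value is the
    fraction of null maxima at least as large.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    pval_map = np.asarray(pval_map, dtype=float)
    if n_perm < 100:
        warnings.warn("n_perm < 100: null quantile will be unstable",
                      stacklevel=2)
    if mode == "permute_labels" and permuter is None:
        raise ValueError("permute_labels mode requires a permuter callback")
    rng = np.random.default_rng(rng)

    mask = pval_map < alpha
    clusters = find_clusters(mask, signs=stat_map, connectivity=connectivity)
    if use_mass:
        for c in clusters:
            idx = c["indices"]
            vals = (np.abs(stat_map[idx]) if stat_map.ndim == 1
                    else np.abs(stat_map[idx[:, 0], idx[:, 1]]))
            c["mass"] = float(vals.sum())

    null_max = np.empty(n_perm)
    flat_mask = mask.ravel()
    for i in range(n_perm):
        if mode == "permute_map":
            perm_mask = rng.permutation(flat_mask).reshape(mask.shape)
        else:
            perm_mask = np.asarray(permuter(rng)) < alpha
        null_max[i] = _max_cluster_size(perm_mask, connectivity)

    threshold = np.quantile(null_max, 1.0 - mcs_p)
    for c in clusters:
        c["mcs_p"] = float(np.mean(null_max >= c["size"]))
        c["significant"] = bool(c["size"] > threshold)
    return ClusterResult(clusters=clusters, null_max_sizes=null_max,
                         alpha_binarize=alpha, n_perm=n_perm,
                         mcs_p_level=mcs_p)


# --------------------------------------------------------------------------
# pointwise and group tests
# --------------------------------------------------------------------------

_TINY = np.finfo(float).tiny


def pointwise_contrast(series_a: np.ndarray,
                       series_b: np.ndarray,
                       paired: bool = True
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided t-test per entry along the leading subject axis.

    Inputs are subjects x (time | time x frequency | time x time) arrays.
    Degenerate zero-variance entries with a nonzero mean difference map to
    the smallest positive p-value rather than 0/NaN.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between conditions")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        if paired:
            t, p = sps.ttest_rel(a, b, axis=0)
        else:
            t, p = sps.ttest_ind(a, b, axis=0)
    d = (a - b).mean(axis=0)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, np.where(d > 0, np.inf,
                                      np.where(d < 0, -np.inf, 0.0)), t)
    p = np.where(degenerate, np.where(d == 0, 1.0, _TINY), p)
    p = np.clip(p, _TINY, 1.0)
    return t, p


def paired_sign_flip_permuter(a: np.ndarray, b: np.ndarray
                              ) -> Callable[[np.random.Generator], np.ndarray]:
    """Null p-value maps for a paired contrast by random per-subject
    condition-label flips (the exchangeability unit is the subject)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b

    def permuter(rng: np.random.Generator) -> np.ndarray:
        signs = rng.choice([-1.0, 1.0], size=d.shape[0])
        flipped = d * signs.reshape((-1,) + (1,) * (d.ndim - 1))
        zeros = np.zeros_like(flipped)
        _, p = pointwise_contrast(flipped, zeros, paired=True)
        return p

    return permuter


def test_vs_chance(values: np.ndarray, chance: float = 0.5,
                   method: str = "wilcoxon") -> np.ndarray:
    """One-sided test of subjects x grid values against a chance level.

    Wilcoxon signed-rank (default) or sign test per entry; alternative is
    'greater'.  Output has the grid's shape.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 5:
        warnings.warn("fewer than 5 subjects: test is degenerate",
                      stacklevel=2)
    grid_shape = x.shape[1:]
    flat = x.reshape(x.shape[0], -1) - chance
    out = np.ones(flat.shape[1])
    for j in range(flat.shape[1]):
        col = flat[:, j]
        if np.all(col == 0):
            out[j] = 1.0
            continue
        if method == "wilcoxon":
            res = sps.wilcoxon(col, alternative="greater",
                               zero_method="wilcox")
            out[j] = res.pvalue
        else:
            n_pos = int(np.sum(col > 0))
            n = int(np.sum(col != 0))
            out[j] = sps.binomtest(n_pos, n, 0.5,
                                   alternative="greater").pvalue
    return out.reshape(grid_shape) if grid_shape else float(out[0])


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H with mid-rank tie correction; returns (H, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    allv = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(allv == allv[0]):
        raise ValueError("all observations identical: H undefined")
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def tukey_kramer_posthoc(*groups: np.ndarray) -> np.ndarray:
    """Tukey-Kramer studentized-range pairwise comparisons.

    Returns the k x k matrix of adjusted p-values (diagonal = 1), valid for
    unequal group sizes.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    res = sps.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    return np.asarray(res.pvalue)


def one_way_anova(*groups: np.ndarray
                  ) -> tuple[float, tuple[int, int], float]:
    """Fixed-effects one-way ANOVA: (F, (df_between, df_within), p).

    The F test is inherently upper-tailed, so this is the "one-sided"
    analysis of variance.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    dof = (k - 1, n_total - k)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else float(_TINY)
        return F, dof, p
    F = (ss_between / dof[0]) / (ss_within / dof[1])
    p = float(sps.f.sf(F, *dof))
    return float(F), dof, p
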
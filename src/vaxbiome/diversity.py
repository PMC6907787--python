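"""Alpha diversity, Bray-Curtis dissimilarity and NMDS ordination.

Alpha estimators follow the standard definitions: observed richness, the
bias-corrected Chao1 estimator S_obs + F1(F1-1)/(2(F2+1)) built from
singleton/doubleton counts, Shannon entropy in nats, and inverse Simpson
1 / sum p_i^2.

NMDS minimizes Kruskal stress-1 by gradient descent with step halving.  Each
iteration refits the monotone disparities by weighted isotonic regression
(pool-adjacent-violators) of the configuration distances on the rank order
of the observed dissimilarities, with tied observed values pooled into one
block.  The default start is the classical metric-scaling configuration
(eigendecomposition of the doubly centered squared-distance matrix);
additional starts are random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
import skbio

from ._rng import substream
from .errors import DataError, ConfigError

__all__ = [
    "observed_richness",
    "chao1",
    "shannon",
    "inv_simpson",
    "alpha_table",
    "bray_curtis",
    "isotonic_fit",
    "nmds",
    "OrdinationResult",
    "group_summary",
    "GroupEllipsoid",
]


def _as_counts(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    if v.ndim != 1:
        raise DataError("expected a 1-D count vector")
    if (v < 0).any():
        raise DataError("counts must be non-negative")
    if v.sum() == 0:
        raise DataError("all-zero count vector")
    return v


def observed_richness(counts) -> int:
    """Number of OTUs with a positive count."""
    return int((_as_counts(counts) > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate.

    Uses the (F2+1) denominator so samples without doubletons are defined;
    equals observed richness when there are no singletons.
    """
    v = _as_counts(counts)
    s_obs = float((v > 0).sum())
    f1 = float((v == 1).sum())
    f2 = float((v == 2).sum())
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p over nonzero proportions (nats)."""
    v = _as_counts(counts)
    p = v[v > 0] / v.sum()
    return float(-(p * np.log(p)).sum())


def inv_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum p_i^2."""
    v = _as_counts(counts)
    p = v / v.sum()
    return float(1.0 / (p**2).sum())


def alpha_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha-diversity table for a samples x OTUs count table."""
    rows = {
        sid: (
            observed_richness(row.values),
            chao1(row.values),
            shannon(row.values),
            inv_simpson(row.values),
        )
        for sid, row in table.iterrows()
    }
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["observed", "chao1", "shannon", "inv_simpson"]
    )
    out.index.name = table.index.name
    return out


def bray_curtis(table: pd.DataFrame) -> skbio.DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y)."""
    values = np.asarray(table, dtype=float)
    if values.shape[0] < 2:
        raise DataError("need at least two samples for a distance matrix")
    if (values.sum(axis=1) == 0).any():
        sid = table.index[np.flatnonzero(values.sum(axis=1) == 0)[0]]
        raise DataError(f"sample {sid!r} is all-zero; Bray-Curtis undefined")
    condensed = pdist(values, metric="braycurtis")
    return skbio.DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


# ----------------------------------------------------------------------
def isotonic_fit(dhat: np.ndarray, order: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit of ``dhat`` along ``order``.

    ``order`` sorts the observed dissimilarities ascending and ``blocks``
    assigns each sorted position to a tie block (equal observed values share
    a block and therefore a common fitted disparity).  Returns the monotone
    disparities in the original (unsorted) element order.
    """
    sorted_vals = dhat[order]
    n_blocks = int(blocks[-1]) + 1 if len(blocks) else 0
    sums = np.bincount(blocks, weights=sorted_vals, minlength=n_blocks)
    weights = np.bincount(blocks, minlength=n_blocks).astype(float)
    means = sums / weights

    # stack-based PAVA over the tie blocks
    level_mean = np.empty(n_blocks)
    level_weight = np.empty(n_blocks)
    level_end = np.empty(n_blocks, dtype=int)
    top = -1
    for b in range(n_blocks):
        top += 1
        level_mean[top] = means[b]
        level_weight[top] = weights[b]
        level_end[top] = b
        while top > 0 and level_mean[top - 1] > level_mean[top]:
            w = level_weight[top - 1] + level_weight[top]
            level_mean[top - 1] = (
                level_weight[top - 1] * level_mean[top - 1]
                + level_weight[top] * level_mean[top]
            ) / w
            level_weight[top - 1] = w
            level_end[top - 1] = level_end[top]
            top -= 1
    fitted_block = np.empty(n_blocks)
    start = 0
    for lev in range(top + 1):
        fitted_block[start : level_end[lev] + 1] = level_mean[lev]
        start = level_end[lev] + 1

    out = np.empty_like(dhat)
    out[order] = fitted_block[blocks]
    return out


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k, column-centered
    stress: float  # final Kruskal stress-1
    n_iter: int
    converged: bool
    sample_ids: list


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _stress_and_disparities(x, dobs_cond, order, blocks, eps=1e-12):
    dhat = pdist(x)
    disp = isotonic_fit(dhat, order, blocks)
    denom = (dhat**2).sum()
    if denom < eps:
        return np.inf, dhat, disp
    stress = np.sqrt(((dhat - disp) ** 2).sum() / denom)
    return stress, dhat, disp


def _stress_gradient(x, dhat, disp):
    n, k = x.shape
    a = ((dhat - disp) ** 2).sum()
    b = (dhat**2).sum()
    s = np.sqrt(a / b) if b > 0 else 0.0
    if s == 0.0:
        return np.zeros_like(x), 0.0
    safe = np.where(dhat > 1e-12, dhat, 1e-12)
    # coefficient on (x_i - x_j) for dA/dx and dB/dx in condensed form
    ca = 2.0 * (dhat - disp) / safe
    cb = 2.0 * np.ones_like(dhat)
    coeff = (ca - (a / b) * cb) / (2.0 * s * b)
    w = squareform(coeff)
    grad = (w.sum(axis=1)[:, None] * x) - w @ x
    return grad, s


def nmds(
    dist,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling minimizing Kruskal stress-1.

    The first start is the classical metric-scaling configuration; the
    remaining ``n_starts - 1`` are random.  Within a run the stress is
    non-increasing (gradient steps are only accepted when they lower it).
    Returns the best configuration, column-centered.
    """
    if isinstance(dist, skbio.DistanceMatrix):
        d = dist.data.copy()
        ids = list(dist.ids)
    else:
        d = np.asarray(dist, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise DataError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if k >= n:
        raise ConfigError("embedding dimension must be smaller than the sample count")

    dobs = squareform(d, checks=False)
    order = np.argsort(dobs, kind="stable")
    sorted_obs = dobs[order]
    blocks = np.zeros(len(order), dtype=int)
    if len(order) > 1:
        blocks[1:] = np.cumsum(sorted_obs[1:] > sorted_obs[:-1])

    rng = substream(seed, "nmds")
    scale = dobs.mean() if dobs.size else 1.0
    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            x = _classical_scaling(d, k)
        else:
            x = rng.normal(0.0, scale, size=(n, k))
        stress, dhat, disp = _stress_and_disparities(x, dobs, order, blocks)
        step = 0.1 * scale
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            if stress <= 1e-12:
                converged = True
                break
            grad, _ = _stress_gradient(x, dhat, disp)
            gnorm = np.linalg.norm(grad)
            if gnorm < 1e-14:
                converged = True
                break
            direction = grad / gnorm
            accepted = False
            trial_step = step
            for _ in range(30):
                x_new = x - trial_step * direction
                s_new, dhat_new, disp_new = _stress_and_disparities(x_new, dobs, order, blocks)
                if s_new < stress:
                    accepted = True
                    break
                trial_step /= 2.0
            if not accepted:
                converged = True
                break
            rel = (stress - s_new) / max(stress, 1e-30)
            x, stress, dhat, disp = x_new, s_new, dhat_new, disp_new
            step = trial_step * 1.5
            if rel < tol:
                converged = True
                break
        x = x - x.mean(axis=0)
        if best is None or stress < best.stress:
            best = OrdinationResult(
                coordinates=x, stress=float(stress), n_iter=it, converged=converged,
                sample_ids=ids,
            )
    return best


@dataclass
class GroupEllipsoid:
    centroid: np.ndarray
    covariance: np.ndarray
    chi2_scale: float  # squared-radius multiplier at the confidence level
    n: int
    degenerate: bool


def group_summary(ordination: OrdinationResult, grouping, level: float = 0.95):
    """Per-group centroid and confidence ellipsoid in ordination space.

    Ellipsoid axes come from the group covariance scaled by the chi-square
    quantile at ``level`` with k degrees of freedom; ``level = 0`` collapses
    the ellipsoid onto the centroid.  Groups with fewer than k+1 members get
    a degenerate-covariance flag.
    """
    if not (0 <= level < 1):
        raise ConfigError("confidence level must lie in [0, 1)")
    labels = pd.Series(list(grouping), index=ordination.sample_ids)
    if labels.isna().any():
        raise DataError("every sample must carry a group label")
    k = ordination.coordinates.shape[1]
    scale = float(chi2.ppf(level, df=k)) if level > 0 else 0.0
    out = {}
    coords = pd.DataFrame(ordination.coordinates, index=ordination.sample_ids)
    for group, sub in coords.groupby(labels):
        x = sub.to_numpy()
        degenerate = x.shape[0] < k + 1
        cov = np.zeros((k, k)) if x.shape[0] < 2 else np.cov(x, rowvar=False)
        out[group] = GroupEllipsoid(
            centroid=x.mean(axis=0),
            covariance=np.atleast_2d(cov),
            chi2_scale=scale,
            n=x.shape[0],
            degenerate=degenerate,
        )
    return out
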
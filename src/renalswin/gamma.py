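"""Three-parameter Gamma mixture statistics.

The package models region pixel intensities with a location-shifted Gamma
law: shape ``alpha`` > 0, scale ``beta`` > 0 and location ``gamma_loc``
(support y > gamma_loc), with mean ``gamma_loc + alpha*beta`` and variance
``alpha*beta**2``.  An image is treated as a K-component mixture of such
laws, one per tissue region; the component count and initial parameters come
from agglomerative clustering of a pixel subsample, and the mixture is then
refined by an EM-style loop whose M-step inverts the moment equations under
posterior responsibilities (location parameters stay fixed at their
initialized values — the joint likelihood is unbounded in the location).

Skewness is reported as ``2/sqrt(alpha)``, the standard form for this law.
A hook for right-censored observations (multiplicities ``R_j``) exists in
:class:`EMState` but is not implemented; all fitting assumes fully observed
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.special import gammaln, logsumexp
from scipy.stats import gamma as _scipy_gamma

from .io import ImageSlice, SegMask

__all__ = ["GammaParams", "GammaMoments", "GammaMixture", "EMState",
           "gamma_pdf", "gamma_moments", "fit_gamma_mom", "hierarchical_init",
           "em_fit", "posterior_responsibilities", "segment_by_mixture",
           "mixture_mean", "gamma_feature_map"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GammaParams:
    """Parameters of one three-parameter Gamma law."""

    alpha: float
    beta: float
    gamma_loc: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"alpha and beta must be positive, got ({self.alpha}, {self.beta})")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return _scipy_gamma.rvs(a=self.alpha, loc=self.gamma_loc, scale=self.beta,
                                size=size, random_state=rng)


@dataclass(frozen=True)
class GammaMoments:
    mean: float
    variance: float
    skewness: float


@dataclass
class GammaMixture:
    """K-component mixture of three-parameter Gamma laws with weights."""

    components: list[GammaParams]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.components) < 1:
            raise ValueError("mixture needs at least one component")
        if len(self.weights) != len(self.components):
            raise ValueError("weights and components length mismatch")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be in [0,1] and sum to 1")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def component_means(self) -> np.ndarray:
        return np.array([p.gamma_loc + p.alpha * p.beta for p in self.components])

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        which = rng.choice(self.K, size=size, p=self.weights / self.weights.sum())
        out = np.empty(size)
        for i, p in enumerate(self.components):
            idx = which == i
            if idx.any():
                out[idx] = p.sample(rng, int(idx.sum()))
        return out

    def to_dict(self) -> dict:
        return {"K": self.K,
                "weights": self.weights.tolist(),
                "components": [{"alpha": p.alpha, "beta": p.beta, "loc": p.gamma_loc}
                               for p in self.components]}

    @classmethod
    def from_dict(cls, d: dict) -> "GammaMixture":
        comps = [GammaParams(c["alpha"], c["beta"], c["loc"]) for c in d["components"]]
        return cls(comps, np.asarray(d["weights"]))


@dataclass
class EMState:
    """State of the mixture-refinement loop after fitting."""

    mixture: GammaMixture
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    sufficient_stats: dict  # per-component Ybar, V at the final iteration
    censor_counts: np.ndarray | None = None  # R_j hook; None => fully observed


def gamma_pdf(y, p: GammaParams, log: bool = False):
    """Density of the three-parameter Gamma law, stable in log space.

    f(y) = (y-loc)^(alpha-1) exp(-(y-loc)/beta) / (Gamma(alpha) beta^alpha)
    for y > loc, and 0 (or -inf in log mode) otherwise.
    """
    y = np.asarray(y, dtype=np.float64)
    z = y - p.gamma_loc
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(
            z > 0,
            (p.alpha - 1.0) * np.log(np.where(z > 0, z, 1.0)) - z / p.beta
            - gammaln(p.alpha) - p.alpha * np.log(p.beta),
            -np.inf,
        )
    if log:
        return logf if logf.shape else float(logf)
    out = np.exp(logf)
    return out if out.shape else float(out)


def gamma_moments(p: GammaParams) -> GammaMoments:
    """Mean loc + alpha*beta, variance alpha*beta^2, skewness 2/sqrt(alpha)."""
    return GammaMoments(mean=p.gamma_loc + p.alpha * p.beta,
                        variance=p.alpha * p.beta ** 2,
                        skewness=2.0 / np.sqrt(p.alpha))


def fit_gamma_mom(samples: np.ndarray, gamma_loc: float) -> GammaParams:
    """Method-of-moments fit with the location held fixed.

    With Ybar = mean(y - loc) and V = var(y - loc): beta = V / Ybar and
    alpha = Ybar^2 / V, so the fitted mean loc + alpha*beta reproduces the
    sample mean exactly.
    """
    y = np.asarray(samples, dtype=np.float64)
    if y.size < 10:
        raise ValueError(f"need at least 10 samples, got {y.size}")
    if np.any(y <= gamma_loc):
        raise ValueError("all samples must exceed the location parameter")
    z = y - gamma_loc
    ybar = z.mean()
    v = z.var()
    if v <= 0:
        raise ValueError("degenerate sample: zero variance")
    return GammaParams(alpha=ybar ** 2 / v, beta=v / ybar, gamma_loc=gamma_loc)


def _weighted_mom(y: np.ndarray, w: np.ndarray, loc: float) -> tuple[float, float]:
    """Responsibility-weighted (Ybar, V) of y - loc over the support y > loc."""
    mask = y > loc
    w = np.where(mask, w, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        return np.nan, np.nan
    z = np.where(mask, y - loc, 0.0)
    ybar = float((w * z).sum() / wsum)
    v = float((w * (z - ybar) ** 2).sum() / wsum)
    return ybar, v


def hierarchical_init(samples: np.ndarray, max_k: int = 6,
                      linkage_method: str = "ward",
                      subsample: int = 3000,
                      gap_ratio: float = 3.0,
                      seed: int = 0) -> GammaMixture:
    """Initialize a mixture by agglomerative clustering of an intensity subsample.

    The component count K comes from the dendrogram's merge heights: with
    ``h_j`` the height of the merge that reduces j+1 clusters to j, the cut
    is placed at the deepest gap whose ratio ``h_j / h_{j+1}`` exceeds
    ``gap_ratio`` (giving K = j+2), or K = 1 when no gap is significant.
    Ward linkage is the default: on 1-D intensity data its between-cluster
    merge heights dwarf within-cluster ones, which makes the gap rule far
    more reliable than average linkage.  Cluster fractions become the
    weights, and each cluster is fitted by :func:`fit_gamma_mom` with its
    location set just below the cluster minimum (1% of the cluster range).
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    y = np.asarray(samples, dtype=np.float64).ravel()
    if y.size < max_k * 10:
        raise ValueError(f"need at least {max_k * 10} samples, got {y.size}")
    rng = np.random.default_rng(seed)
    sub = y if y.size <= subsample else rng.choice(y, size=subsample, replace=False)
    Z = linkage(sub.reshape(-1, 1), method=linkage_method)
    heights = Z[:, 2]  # increasing
    # h[j-1] = height of merge producing j clusters
    k = 1
    if max_k > 1 and heights[-1] > 0:
        hs = heights[::-1][: max_k]  # h_1 (final merge), h_2, ...
        significant = [j for j in range(len(hs) - 1)
                       if (hs[j] / hs[j + 1] if hs[j + 1] > 0 else np.inf)
                       > gap_ratio]
        if significant:
            # deepest significant gap: cutting below h_{j+1} leaves j+2 clusters
            k = max(significant) + 2
    if k > 1:
        from scipy.cluster.hierarchy import fcluster
        assign = fcluster(Z, t=k, criterion="maxclust")
    else:
        assign = np.ones(sub.size, dtype=int)
    comps, weights = [], []
    # order clusters by mean so component index tracks intensity
    ids = sorted(np.unique(assign), key=lambda c: sub[assign == c].mean())
    first = True
    for cid in ids:
        pts = sub[assign == cid]
        if pts.size < 10:
            continue
        rng_span = np.ptp(pts)
        eps = 0.01 * rng_span if rng_span > 0 else 0.01 * max(1.0, abs(pts.min()))
        loc = pts.min() - eps
        if first:
            # anchor the lowest component below the full-sample minimum so
            # every observation lies inside the mixture's support
            loc = min(loc, y.min() - eps)
            first = False
        try:
            comps.append(fit_gamma_mom(pts, loc))
        except ValueError:
            continue
        weights.append(pts.size)
    if not comps:  # fully degenerate sample: one near-point mass component
        loc = sub.min() - max(1e-6, 0.01 * max(1.0, abs(sub.min())))
        z = sub - loc
        comps = [GammaParams(alpha=max(z.mean() ** 2 / max(z.var(), 1e-12), 1.0),
                             beta=max(z.var(), 1e-12) / z.mean(), gamma_loc=loc)]
        weights = [1.0]
    w = np.asarray(weights, float)
    return GammaMixture(comps, w / w.sum())


def _mixture_log_density(y: np.ndarray, mix: GammaMixture) -> np.ndarray:
    """(n, K) matrix of log w_i + log f_i(y_j)."""
    cols = [np.log(max(w, 1e-300)) + gamma_pdf(y, p, log=True)
            for p, w in zip(mix.components, mix.weights)]
    return np.stack(cols, axis=-1)


def em_fit(samples: np.ndarray, init: GammaMixture, tol: float = 1e-6,
           max_iter: int = 200) -> EMState:
    """Refine a Gamma mixture by EM-style iteration with fixed locations.

    E-step: posterior responsibilities from the current mixture.  M-step:
    weights are mean responsibilities and each component's (alpha, beta) is
    re-estimated by responsibility-weighted inversion of the moment
    equations (beta = V/Ybar, alpha = Ybar^2/V).  Because the M-step matches
    moments rather than maximizing the likelihood exactly, an update that
    fails to improve the log-likelihood is rejected and the loop stops there;
    the recorded log-likelihood trace is therefore nondecreasing.
    Components whose weight collapses below 1e-8 are pruned with a warning.
    """
    y = np.asarray(samples, dtype=np.float64).ravel()
    mix = GammaMixture([GammaParams(p.alpha, p.beta, p.gamma_loc)
                        for p in init.components], init.weights.copy())
    ld = _mixture_log_density(y, mix)
    ll = float(logsumexp(ld, axis=1).sum())
    if not np.isfinite(ll):
        raise FloatingPointError(
            "non-finite log-likelihood at initialization: samples outside "
            "the union of component supports")
    trace = [ll]
    stats: dict = {}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log space)
        r = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
        # M-step: weighted moment inversion, locations fixed
        new_comps, new_w, new_stats = [], [], {}
        for i, p in enumerate(mix.components):
            wsum = r[:, i].sum()
            if wsum / y.size < 1e-8:
                log.warning("EM: pruning empty component %d (weight %.2e)",
                            i, wsum / y.size)
                continue
            ybar, v = _weighted_mom(y, r[:, i], p.gamma_loc)
            if not np.isfinite(ybar) or v <= 0:
                log.warning("EM: pruning degenerate component %d", i)
                continue
            new_comps.append(GammaParams(alpha=ybar ** 2 / v, beta=v / ybar,
                                         gamma_loc=p.gamma_loc))
            new_w.append(wsum / y.size)
            new_stats[len(new_comps) - 1] = {"Ybar": ybar, "V": v}
        if not new_comps:
            break
        cand = GammaMixture(new_comps, np.asarray(new_w) / np.sum(new_w))
        cand_ld = _mixture_log_density(y, cand)
        cand_ll = float(logsumexp(cand_ld, axis=1).sum())
        if not np.isfinite(cand_ll):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
        if cand_ll < trace[-1] - 1e-10:
            converged = True  # moment update stalled; keep the better params
            break
        mix, ld = cand, cand_ld
        stats = new_stats
        trace.append(cand_ll)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return EMState(mixture=mix, loglik_trace=trace, n_iter=it,
                   converged=converged, sufficient_stats=stats,
                   censor_counts=None)


def posterior_responsibilities(y: np.ndarray, mix: GammaMixture) -> np.ndarray:
    """Per-sample component probabilities; rows sum to 1.

    Samples outside every component's support get a uniform fallback (with a
    warning) rather than NaNs.
    """
    y = np.asarray(y, dtype=np.float64)
    flat = y.ravel()
    ld = _mixture_log_density(flat, mix)
    norm = logsumexp(ld, axis=1, keepdims=True)
    bad = ~np.isfinite(norm[:, 0])
    if bad.any():
        log.warning("%d samples outside all component supports; uniform fallback",
                    int(bad.sum()))
        ld[bad] = 0.0
        norm[bad] = np.log(mix.K)
    r = np.exp(ld - norm)
    return r.reshape(y.shape + (mix.K,))


def segment_by_mixture(img: ImageSlice, mix: GammaMixture) -> SegMask:
    """Per-pixel argmax of posterior responsibilities (ties -> lowest index)."""
    r = posterior_responsibilities(img.pixels, mix)
    labels = np.argmax(r, axis=-1).astype(np.int64)
    label_map = {i: f"component_{i}" for i in range(mix.K)}
    label_map[0] = "component_0"
    return SegMask(labels=labels, label_map=label_map)


def mixture_mean(mix: GammaMixture) -> float:
    """Expected intensity of the mixture: sum_i w_i (loc_i + alpha_i beta_i)."""
    return float(np.dot(mix.weights, mix.component_means))


def gamma_feature_map(img: ImageSlice, fitted: GammaMixture,
                      roi: SegMask | None = None) -> ImageSlice:
    """Atypicality map in [0, 1]: high where no component explains a pixel.

    Per pixel, each component's density is normalized by its own peak
    (density at the mode), giving a typicality q_i in [0, 1] that is 1 at
    the component's mode; the map is 1 - max_i q_i.  A pixel well inside
    any tissue law scores near 0; pixels in the gaps between laws — small
    or low-contrast lesions — score high.  (Posterior responsibilities are
    unsuitable here: they renormalize across components and saturate at 1
    even for intensities no law explains.)  With an ROI mask the map is
    zeroed outside the ROI.
    """
    y = img.pixels
    best = np.zeros_like(y)
    for p in fitted.components:
        # mode of the shifted Gamma law; alpha < 1 has an unbounded density
        # at the boundary, so clamp to the exponential case
        a = max(p.alpha, 1.0)
        mode = p.gamma_loc + (a - 1.0) * p.beta
        peak_log = gamma_pdf(mode, GammaParams(a, p.beta, p.gamma_loc), log=True)
        if not np.isfinite(peak_log):
            # numerically degenerate component (near point mass): pixels are
            # typical only exactly at its mode
            best = np.maximum(best, (y == mode).astype(float))
            continue
        with np.errstate(invalid="ignore"):
            diff = gamma_pdf(y, p, log=True) - peak_log
        diff = np.where(np.isnan(diff), -np.inf, np.minimum(diff, 0.0))
        best = np.maximum(best, np.exp(diff))
    score = 1.0 - best
    if roi is not None:
        score = np.where(roi.labels > 0, score, 0.0)
    return ImageSlice(np.clip(score, 0.0, 1.0), img.spacing)
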
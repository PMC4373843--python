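"""Beta-mixture quantile normalization of Infinium type-II probes.

The two Infinium chemistries on the 450K array produce systematically
different beta-value distributions: type-II probes have a compressed
dynamic range.  This module implements an intra-array (per-sample)
correction in the beta-mixture-quantile family: each sample's type-I and
type-II beta values are modelled as three-state beta mixtures
(unmethylated U, hemimethylated H, methylated M); type-II values are then
quantile-mapped onto the type-I distribution through the fitted mixture
CDFs.  Type-I values pass through unchanged.

The mixture is fitted by EM with exact weighted maximum-likelihood M-steps
(Newton on the digamma system), so the log-likelihood is non-decreasing
across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, polygamma, psi
from scipy.stats import beta as beta_dist

from .core import BetaMatrix, CoMethNetError, ProbeManifest

logger = logging.getLogger("comethnet")

EPS = 1e-6  # boundary nudge: beta density is undefined at 0 and 1
_DEGENERATE_WEIGHT = 1e-4


@dataclass
class BetaMixtureFit:
    """A fitted K-state beta mixture over values in (0, 1)."""

    weights: np.ndarray  # (K,), sums to 1
    shapes: np.ndarray  # (K, 2) of (a, b), all > 0
    posteriors: np.ndarray  # (n, K) responsibilities
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False

    @property
    def n_states(self) -> int:
        return len(self.weights)

    @property
    def state_means(self) -> np.ndarray:
        a, b = self.shapes[:, 0], self.shapes[:, 1]
        return a / (a + b)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, (a, b) in zip(self.weights, self.shapes):
            out += w * beta_dist.pdf(x, a, b)
        return out

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """State responsibilities for new values, shape (n, K)."""
        x = np.asarray(x, dtype=float)
        dens = np.stack(
            [w * beta_dist.pdf(x, a, b) for w, (a, b) in zip(self.weights, self.shapes)],
            axis=1,
        )
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


def _moment_shapes(x: np.ndarray, w: np.ndarray | None = None) -> tuple[float, float]:
    """Method-of-moments beta shape estimates from (weighted) mean/variance."""
    if w is None:
        m, v = float(np.mean(x)), float(np.var(x))
    else:
        ws = w.sum()
        m = float(np.dot(w, x) / ws)
        v = float(np.dot(w, (x - m) ** 2) / ws)
    m = min(max(m, 1e-4), 1 - 1e-4)
    v = max(v, 1e-8)
    common = max(m * (1 - m) / v - 1.0, 1e-3)
    return max(m * common, 1e-3), max((1 - m) * common, 1e-3)


def _weighted_beta_mle(
    x: np.ndarray, w: np.ndarray, a0: float, b0: float, n_iter: int = 25
) -> tuple[float, float]:
    """Weighted beta MLE via Newton on the digamma score equations."""
    ws = w.sum()
    t1 = float(np.dot(w, np.log(x)) / ws)
    t2 = float(np.dot(w, np.log1p(-x)) / ws)
    a, b = a0, b0

    def obj(a, b):
        return a * t1 + b * t2 - t1 - t2 - betaln(a, b)

    best = obj(a, b)
    for _ in range(n_iter):
        f1 = psi(a) - psi(a + b) - t1
        f2 = psi(b) - psi(a + b) - t2
        tri_ab = polygamma(1, a + b)
        j11 = polygamma(1, a) - tri_ab
        j22 = polygamma(1, b) - tri_ab
        det = j11 * j22 - tri_ab**2
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        da = -(j22 * f1 + tri_ab * f2) / det
        db = -(tri_ab * f1 + j11 * f2) / det
        step = 1.0
        while (a + step * da <= 0) or (b + step * db <= 0):
            step /= 2.0
            if step < 1e-8:
                break
        a_new, b_new = a + step * da, b + step * db
        if a_new <= 0 or b_new <= 0:
            break
        # damp any non-improving step (keeps the EM ascent property)
        while obj(a_new, b_new) < best - 1e-12 and step > 1e-8:
            step /= 2.0
            a_new, b_new = a + step * da, b + step * db
        a, b = a_new, b_new
        cur = obj(a, b)
        if cur > best:
            best = cur
        if abs(f1) < 1e-10 and abs(f2) < 1e-10:
            break
    return a, b


def fit_beta_mixture(
    values: np.ndarray,
    n_states: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: BetaMixtureFit | None = None,
) -> BetaMixtureFit:
    """Fit a beta mixture to values in (0, 1) by EM.

    Default initialization is deterministic: values are cut at empirical
    quantiles into ``n_states`` groups and each group seeds one state by
    method of moments (no random restarts, no label switching).  States are
    returned ordered by mean, so for three states U < H < M.

    When ``init`` is given, EM starts from that fit's weights and shapes.
    The three-state decomposition of a smooth beta-value density is only
    weakly identified (many weight/shape combinations give near-identical
    likelihood), so anchoring a second fit on a first keeps the two
    decompositions in the same likelihood basin — which is what makes
    state-wise quantile maps between them stable.

    Raises :class:`CoMethNetError` on fewer than 30 usable values or a
    (near-)constant input.  Non-convergence returns the best fit with
    ``converged=False``; states collapsing below weight 1e-4 are merged and
    the fit flagged ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    x = np.clip(x, EPS, 1 - EPS)
    if x.size < 30:
        raise CoMethNetError(f"need >= 30 values to fit a mixture, got {x.size}")
    if np.std(x) < 1e-8:
        raise CoMethNetError("degenerate input: all values (near-)identical")

    if init is not None:
        shapes = init.shapes.copy().astype(float)
        weights = init.weights.copy().astype(float)
    else:
        # deterministic quantile-based initialization
        qs = np.quantile(x, np.linspace(0, 1, n_states + 1))
        shapes = []
        weights = []
        order = np.argsort(x)
        xs = x[order]
        bounds = np.searchsorted(xs, qs[1:-1])
        groups = np.split(xs, bounds)
        for g in groups:
            if g.size < 2 or np.std(g) < 1e-9:
                g = xs  # fall back to the pooled values
            shapes.append(_moment_shapes(g))
            weights.append(max(g.size, 1) / xs.size)
        shapes = np.array(shapes, dtype=float)
        weights = np.asarray(weights, dtype=float)
        weights /= weights.sum()

    trace: list[float] = []
    converged = False
    degenerate = False
    post = np.full((x.size, len(weights)), 1.0 / len(weights))
    for _ in range(max_iter):
        # E step
        logdens = np.stack(
            [
                np.log(w + 1e-300) + beta_dist.logpdf(x, a, b)
                for w, (a, b) in zip(weights, shapes)
            ],
            axis=1,
        )
        mx = logdens.max(axis=1, keepdims=True)
        dens = np.exp(logdens - mx)
        total = dens.sum(axis=1, keepdims=True)
        post = dens / total
        ll = float(np.sum(np.log(total.ravel()) + mx.ravel()))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            converged = True
            break
        # merge collapsed states
        w_new = post.mean(axis=0)
        keep = w_new > _DEGENERATE_WEIGHT
        if not keep.all():
            logger.warning(
                "merging %d degenerate mixture state(s)", int((~keep).sum())
            )
            degenerate = True
            weights = w_new[keep] / w_new[keep].sum()
            shapes = shapes[keep]
            post = post[:, keep] / post[:, keep].sum(axis=1, keepdims=True)
            w_new = post.mean(axis=0)
        # M step: exact weighted MLE per state, warm-started at the current
        # shapes so the fit tracks one likelihood basin
        weights = w_new
        for k in range(len(weights)):
            shapes[k] = _weighted_beta_mle(x, post[:, k], *shapes[k])
    else:
        logger.warning("beta-mixture EM did not converge in %d iterations", max_iter)

    order = np.argsort(shapes[:, 0] / shapes.sum(axis=1))
    fit = BetaMixtureFit(
        weights=weights[order],
        shapes=shapes[order],
        posteriors=post[:, order],
        loglik_trace=trace,
        converged=converged,
        degenerate=degenerate or len(weights) < n_states,
    )
    return fit


def _state_boundaries(fit: BetaMixtureFit, n_grid: int = 2001) -> tuple[float, float]:
    """(U/H, H/M) boundaries: where the maximum-posterior state switches."""
    grid = np.linspace(EPS, 1 - EPS, n_grid)
    state = fit.posterior(grid).argmax(axis=1)
    in_u = np.where(state == 0)[0]
    in_m = np.where(state == fit.n_states - 1)[0]
    if in_u.size == 0 or in_m.size == 0:
        raise CoMethNetError("degenerate mixture: missing U or M state region")
    t_low = grid[in_u.max()]
    t_high = grid[in_m.min()]
    if t_low >= t_high:
        raise CoMethNetError("degenerate mixture: state regions overlap")
    return float(t_low), float(t_high)


def _mixture_cdf(fit: BetaMixtureFit, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(x, dtype=float))
    for w, (a, b) in zip(fit.weights, fit.shapes):
        out += w * beta_dist.cdf(x, a, b)
    return out


_MAP_GRID = np.linspace(EPS, 1 - EPS, 4001)


def _normalize_sample(v2: np.ndarray, fit1: BetaMixtureFit, fit2: BetaMixtureFit):
    """Quantile-map one sample's type-II values onto the type-I distribution.

    The transform is ``b' = F1^{-1}(F2(b))`` through the two fitted mixture
    CDFs (inverted on a fine grid).  Mapping through the full mixture
    rather than state-by-state matters: the three-state decomposition of a
    smooth beta-value density is weakly identified, so maps between
    individually fitted components are unstable, while the overall fitted
    CDF is pinned down by the data.  The map is strictly monotone and is
    the identity when the two fitted distributions coincide.
    """
    x = np.clip(v2, EPS, 1 - EPS)
    p = _mixture_cdf(fit2, x)
    out = np.interp(p, _mixture_cdf(fit1, _MAP_GRID), _MAP_GRID)
    return np.clip(out, 0.0, 1.0)


def bmiq_normalize(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Per-sample quantile normalization of type-II probes onto type-I.

    Returns the normalized matrix (type-I rows bit-identical to the input)
    and a per-sample fit report.  A sample whose type-II mixture fit is
    degenerate is passed through unnormalized with a logged warning.
    """
    type1 = [p for p in manifest.probes_of_type("I") if p in beta.values.index]
    type2 = [p for p in manifest.probes_of_type("II") if p in beta.values.index]
    if not type1 or not type2:
        raise CoMethNetError("both Infinium probe types are required per sample")

    out = beta.values.copy()
    rows = []
    for sample in beta.sample_ids:
        v1 = out.loc[type1, sample].to_numpy()
        v2 = out.loc[type2, sample].to_numpy()
        record = {"sample_id": sample, "normalized": False}
        try:
            fit1 = fit_beta_mixture(v1, max_iter=max_iter, tol=tol)
            # anchor the type-II fit on the type-I decomposition so the
            # two fits share a likelihood basin
            fit2 = fit_beta_mixture(v2, max_iter=max_iter, tol=tol, init=fit1)
            # a state-merged ("degenerate") fit is still a proper density:
            # the full-mixture quantile map remains valid, and skipping the
            # sample would leave it systematically biased relative to the
            # rest of the cohort — a batch artifact worse than any fit issue
            keep_na = np.isnan(v2)
            mapped = _normalize_sample(np.nan_to_num(v2, nan=0.5), fit1, fit2)
            mapped[keep_na] = np.nan
            out.loc[type2, sample] = mapped
            record.update(
                normalized=True,
                type1_means=",".join(f"{m:.3f}" for m in fit1.state_means),
                type2_means=",".join(f"{m:.3f}" for m in fit2.state_means),
                type2_loglik=fit2.loglik_trace[-1],
                converged=fit1.converged and fit2.converged,
                degenerate=fit1.degenerate or fit2.degenerate,
            )
        except CoMethNetError as exc:
            logger.warning("sample %s left unnormalized: %s", sample, exc)
        rows.append(record)
    report = pd.DataFrame(rows).set_index("sample_id")
    return BetaMatrix(out), report
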
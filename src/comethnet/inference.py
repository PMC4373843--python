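"""Effect screening, the acceleration model, and reference-free adjustment.

Three layers of inference on a methylation cohort:

* per-CpG screening — paired and unpaired t-tests for the serostatus
  effect (with Storey q-values), Pearson correlation with age, and
  cross-cohort concordance of effect vectors;
* the acceleration model — ordinary least squares of a module eigenvector
  on age and HIV serostatus; the seropositive offset expressed in
  equivalent years of aging is the coefficient ratio
  ``beta_hiv / beta_age``, with a delta-method standard error;
* reference-free adjustment — latent variables estimated from the
  residuals of the per-CpG covariate fit (their number set by the
  Marchenko-Pastur edge of the residual spectrum) absorb unmeasured
  cell-composition variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import BetaMatrix, CoMethNetError, SampleSheet
from .network import ModuleEigenvector, correlation_pvalue

logger = logging.getLogger("comethnet")


# --------------------------------------------------------------------------
# per-CpG screening
# --------------------------------------------------------------------------

def paired_hiv_effect(beta: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Paired t-test of the seropositive-minus-seronegative difference.

    One-sample t on the per-pair differences for every probe.  The signed
    log p-value is ``sign(mean difference) * (-log10 p)`` (log base 10).
    Zero-variance differences give missing values with a warning.
    """
    pairs = sheet.pairs()
    sp = [p[0] for p in pairs]
    sn = [p[1] for p in pairs]
    d = beta.values[sp].to_numpy() - beta.values[sn].to_numpy()
    k = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d probes have zero-variance differences", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(k))
    t[zero] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), k - 1)
    with np.errstate(divide="ignore"):
        slp = np.sign(mean) * (-np.log10(np.maximum(p, 1e-300)))
    slp[zero] = np.nan
    return pd.DataFrame(
        {"t": t, "p": p, "signed_log_p": slp}, index=beta.probe_ids
    )


def storey_qvalues(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with the lambda-grid smoother estimate of pi0.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is evaluated on the
    grid, smoothed by a cubic polynomial and read off at the largest
    lambda; forcing ``pi0=1`` reduces the procedure to Benjamini-Hochberg.
    Missing p-values propagate as missing q-values.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if (pv < 0).any() or (pv > 1).any():
        raise CoMethNetError("p-values must lie in [0, 1]")
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_grid = np.array(
            [(pv > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
        )
        if m < 100 or np.allclose(pi0_grid, pi0_grid[0]):
            pi0_hat = float(np.minimum(pi0_grid.min(), 1.0))
        else:
            coeffs = np.polyfit(lambdas, pi0_grid, 3)
            pi0_hat = float(np.polyval(coeffs, lambdas.max()))
        pi0_hat = min(max(pi0_hat, 1e-8), 1.0)
    else:
        pi0_hat = float(pi0)
    order = np.argsort(pv)
    ranked = pv[order]
    qv = pi0_hat * m * ranked / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def unpaired_hiv_screen(
    beta: BetaMatrix,
    sheet: SampleSheet,
    equal_var: bool = True,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Two-sample t screen for serostatus with Storey q-value adjustment.

    Equal-variance (Student) t by default; set ``equal_var=False`` for
    Welch.  ``pi0=1.0`` forces the Benjamini-Hochberg fallback.
    """
    sp = [s for s in sheet.sample_ids if sheet.hiv_status[s] == 1]
    sn = [s for s in sheet.sample_ids if sheet.hiv_status[s] == 0]
    if len(sp) < 2 or len(sn) < 2:
        raise CoMethNetError("both serostatus groups need at least 2 samples")
    a = beta.values[sp].to_numpy()
    b = beta.values[sn].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if zero.any():
        logger.warning("%d probes are constant in both groups", int(zero.sum()))
        t = np.where(zero, np.nan, t)
        p = np.where(zero, np.nan, p)
    q = storey_qvalues(p, pi0=pi0)
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=beta.probe_ids)


def age_effect(
    beta: BetaMatrix, sheet: SampleSheet, subset=None
) -> pd.DataFrame:
    """Pearson correlation of every probe with age, with t-transform p.

    ``subset`` optionally restricts the samples (e.g. seronegatives only);
    the default uses all samples.
    """
    samples = list(subset) if subset is not None else sheet.sample_ids
    if len(samples) < 4:
        raise CoMethNetError("at least 4 samples are required")
    age = sheet.age.loc[samples].to_numpy()
    X = beta.values[samples].to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    ac = age - age.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Xc @ ac) / denom, -1.0, 1.0)
    const = X.std(axis=1) == 0
    if const.any():
        logger.warning("%d constant probes; age correlation missing", int(const.sum()))
        r = np.where(const, np.nan, r)
    p = correlation_pvalue(r, len(samples))
    return pd.DataFrame({"r": r, "p": p}, index=beta.probe_ids)


def effect_concordance(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Pearson correlation between two per-probe effect vectors.

    Vectors are aligned on their shared probe index; missing values are
    dropped pairwise.
    """
    x = pd.Series(x)
    y = pd.Series(y)
    shared = x.index.intersection(y.index)
    xv = x.loc[shared].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy(dtype=float)
    ok = ~(np.isnan(xv) | np.isnan(yv))
    if ok.sum() < 3:
        raise CoMethNetError("fewer than 3 shared non-missing probes")
    res = stats.pearsonr(xv[ok], yv[ok])
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# the acceleration model
# --------------------------------------------------------------------------

@dataclass
class AccelerationFit:
    """OLS of a module eigenvector on [1, age, hiv] plus the year ratio.

    ``acceleration_years = beta_hiv / beta_age`` re-expresses the
    seropositive offset in equivalent years of age-related methylation
    change; its standard error comes from the delta method.
    """

    intercept: float
    beta_age: float
    beta_hiv: float
    se_intercept: float
    se_age: float
    se_hiv: float
    p_intercept: float
    p_age: float
    p_hiv: float
    df_resid: int
    acceleration_years: float
    acceleration_se: float | None

    def acceleration_ci(self, level: float = 0.95) -> tuple[float, float]:
        if self.acceleration_se is None:
            raise CoMethNetError("ratio SE undefined (beta_age is 0)")
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        half = zcrit * self.acceleration_se
        return self.acceleration_years - half, self.acceleration_years + half

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.intercept, self.beta_age, self.beta_hiv],
                "se": [self.se_intercept, self.se_age, self.se_hiv],
                "p": [self.p_intercept, self.p_age, self.p_hiv],
            },
            index=["Intercept", "Age", "HIV Seropositive"],
        )


def acceleration_ratio(beta_hiv: float, beta_age: float) -> float:
    """Seropositive offset expressed in years: ``beta_hiv / beta_age``."""
    if beta_age == 0:
        raise CoMethNetError("acceleration undefined when the age coefficient is 0")
    return beta_hiv / beta_age


def fit_acceleration(
    me: ModuleEigenvector | pd.Series, sheet: SampleSheet
) -> AccelerationFit:
    """Fit the multivariate model ME ~ age + hiv and derive the year ratio."""
    scores = me.scores if isinstance(me, ModuleEigenvector) else pd.Series(me)
    samples = [s for s in sheet.sample_ids if s in scores.index]
    if len(samples) < 4:
        raise CoMethNetError("at least 4 samples are required")
    y = scores.loc[samples].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(samples)),
            sheet.age.loc[samples].to_numpy(),
            sheet.hiv_status.loc[samples].to_numpy(dtype=float),
        ]
    )
    if len(set(sheet.hiv_status.loc[samples])) < 2:
        raise CoMethNetError("both serostatus groups must be represented")
    if np.linalg.matrix_rank(X) < 3:
        raise CoMethNetError("rank-deficient design (age constant within status?)")
    model = sm.OLS(y, X).fit()
    b0, ba, bh = model.params
    se0, sea, seh = model.bse
    cov = model.cov_params()
    ratio = bh / ba if ba != 0 else float("nan")
    if ba != 0:
        rel = (seh / bh) ** 2 + (sea / ba) ** 2 - 2 * cov[1, 2] / (bh * ba)
        ratio_se = abs(ratio) * float(np.sqrt(max(rel, 0.0)))
    else:
        ratio_se = None
    return AccelerationFit(
        intercept=float(b0),
        beta_age=float(ba),
        beta_hiv=float(bh),
        se_intercept=float(se0),
        se_age=float(sea),
        se_hiv=float(seh),
        p_intercept=float(model.pvalues[0]),
        p_age=float(model.pvalues[1]),
        p_hiv=float(model.pvalues[2]),
        df_resid=int(model.df_resid),
        acceleration_years=float(ratio),
        acceleration_se=ratio_se,
    )


# --------------------------------------------------------------------------
# reference-free adjustment
# --------------------------------------------------------------------------

def rmt_dimension(residuals: np.ndarray, df: int | None = None) -> int:
    """Latent dimension by the Marchenko-Pastur edge of the residual spectrum.

    ``residuals`` is samples x probes.  Columns are standardized; the
    eigenvalues of ``Z Z' / p`` are compared against the bulk upper edge
    of a noise spectrum with aspect ratio samples/probes, and the count
    above the edge is returned.

    ``df`` is the residual rank (samples minus fitted design columns) when
    the matrix comes from a regression; projection onto the residual space
    compresses the noise bulk, and column standardization re-inflates it
    by n/df, so the edge is ``(n/df) * (1 + sqrt(df/p))^2``.  Without
    ``df`` the matrix is treated as centred data of rank n - 1.
    """
    R = np.asarray(residuals, dtype=float)
    n, p = R.shape
    if n < 5:
        raise CoMethNetError("at least 5 samples are required")
    sd = R.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise CoMethNetError("residual matrix has rank < 2")
    Z = (R[:, keep] - R[:, keep].mean(axis=0)) / sd[keep]
    p_eff = int(keep.sum())
    m = df if df is not None else n - 1
    M = (Z @ Z.T) / p_eff
    evals = np.linalg.eigvalsh(M)
    edge = (n / m) * (1.0 + np.sqrt(m / p_eff)) ** 2
    return int((evals > edge).sum())


@dataclass
class RefFreeFit:
    """Reference-free EWAS fit: latent dimension and coefficient tables."""

    k_latent: int
    unadjusted: pd.DataFrame  # probes x covariates
    adjusted: pd.DataFrame
    latent_scores: pd.DataFrame  # samples x k
    concordance: dict[str, float]  # cor(adjusted, unadjusted) per covariate


def reffree_adjust(
    beta: BetaMatrix,
    sheet: SampleSheet,
    covariates: tuple[str, ...] = ("age", "hiv_status"),
    k: int | None = None,
) -> RefFreeFit:
    """Two-stage reference-free adjustment of per-CpG covariate effects.

    Stage 1 fits each probe on the covariates by OLS and collects the
    residual matrix; stage 2 estimates the latent dimension ``k`` from the
    Marchenko-Pastur edge of that matrix (unless given), recovers latent
    sample scores, appends them to the design, and refits.  With ``k = 0``
    the adjusted coefficients equal the unadjusted ones.

    The latent scores are the projection of the (probe-centred) raw data
    onto the top-k *right* singular vectors of the residual matrix.  The
    residuals pin down the confounder's probe-loading pattern; projecting
    the raw data onto those loadings then recovers the full confounder
    score, including the component correlated with the covariates — which
    is exactly the part an adjustment must absorb.  (Appending the
    residuals' left singular vectors instead would be a no-op: residuals
    are orthogonal to the design, so the covariate coefficients would not
    move.)
    """
    Y = beta.values.T.to_numpy(dtype=float)  # samples x probes
    n = Y.shape[0]
    D = np.column_stack(
        [np.ones(n)] + [sheet.data[c].loc[beta.sample_ids].to_numpy(dtype=float)
                        for c in covariates]
    )
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise CoMethNetError("covariate design is rank deficient")
    coef_unadj, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef_unadj
    if k is None:
        k = rmt_dimension(resid, df=n - D.shape[1])
    k_max = n - D.shape[1] - 1
    if k > k_max:
        logger.warning("capping latent dimension at %d (was %d)", k_max, k)
        k = k_max
    cols = ["intercept", *covariates]
    unadj = pd.DataFrame(coef_unadj.T, index=beta.probe_ids, columns=cols)
    if k > 0:
        _, _, vt = np.linalg.svd(resid, full_matrices=False)
        loadings = vt[:k].T  # probes x k
        latent = (Y - Y.mean(axis=0)) @ loadings
        D2 = np.column_stack([D, latent])
        if np.linalg.matrix_rank(D2) < D2.shape[1]:
            raise CoMethNetError("latent scores collinear with covariates")
        coef_adj, *_ = np.linalg.lstsq(D2, Y, rcond=None)
        adj = pd.DataFrame(coef_adj[: D.shape[1]].T, index=beta.probe_ids, columns=cols)
    else:
        latent = np.empty((n, 0))
        adj = unadj.copy()
    concordance = {}
    for c in covariates:
        r, _ = effect_concordance(unadj[c], adj[c])
        concordance[c] = r
    return RefFreeFit(
        k_latent=int(k),
        unadjusted=unadj,
        adjusted=adj,
        latent_scores=pd.DataFrame(
            latent, index=beta.sample_ids, columns=[f"LV{i+1}" for i in range(k)]
        ),
        concordance=concordance,
    )


# --------------------------------------------------------------------------
# hypermethylation sign-count comparison
# --------------------------------------------------------------------------

@dataclass
class SignCountResult:
    n_positive: int
    n_negative: int
    n_effective: int
    p: float


def hypermethylation_count_test(
    beta: BetaMatrix,
    members,
    sheet: SampleSheet,
    group_a,
    group_b,
) -> SignCountResult:
    """Count module CpGs hypermethylated in group A vs B; exact binomial p.

    For each module CpG, the sign of (group-A mean - group-B mean) is
    recorded; the count of positive signs is tested against a fair coin by
    a two-sided exact binomial test.  This sign-count formulation is a
    documented interpretation of "a greater number of hypermethylated
    CpGs"; ties (exact zero differences) are excluded.
    """
    members = list(members)
    if not members:
        raise CoMethNetError("empty module")
    a = beta.values.loc[members, list(group_a)].to_numpy().mean(axis=1)
    b = beta.values.loc[members, list(group_b)].to_numpy().mean(axis=1)
    diff = a - b
    n_pos = int((diff > 0).sum())
    n_neg = int((diff < 0).sum())
    n_eff = n_pos + n_neg
    if n_eff == 0:
        return SignCountResult(0, 0, 0, 1.0)
    p = float(stats.binomtest(n_pos, n_eff, 0.5, alternative="two-sided").pvalue)
    return SignCountResult(n_pos, n_neg, n_eff, p)
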
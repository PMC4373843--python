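"""Signed weighted co-methylation networks and module detection.

Probes are nodes; the edge weight between probes i and j is the signed
soft-thresholded Pearson correlation ``a_ij = ((1 + r_ij)/2)^power`` so that
anti-correlated probes are unconnected.  Pairwise adjacency is augmented by
shared-neighbour agreement into the topological overlap measure (TOM), and
``1 - TOM`` is the dissimilarity clustered by average-linkage hierarchical
clustering.  Dendrogram branches become co-methylation modules; each module
is summarised by its eigenvector (first principal component of the
standardized module matrix), and module membership (kME) is the correlation
of a probe's profile with that eigenvector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .core import BetaMatrix, CoMethNetError, ModuleAssignment, SampleSheet

logger = logging.getLogger("comethnet")

DEFAULT_SOFT_POWER = 12


def _probe_correlation(values: pd.DataFrame) -> np.ndarray:
    """Probe x probe Pearson correlation; pairwise-complete when NaN present."""
    X = values.to_numpy()
    if np.isnan(X).any():
        n_pairs = (~np.isnan(X)).astype(int) @ (~np.isnan(X)).astype(int).T
        if n_pairs.min() < X.shape[1] - 2:
            logger.warning(
                "pairwise-complete sample counts drop to %d", int(n_pairs.min())
            )
        return values.T.corr().to_numpy()
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = values.index[sd == 0][0]
        raise CoMethNetError(f"zero-variance probe: {bad}")
    return np.corrcoef(X)


@dataclass
class AdjacencyMatrix:
    probe_ids: list[str]
    values: np.ndarray
    soft_power: int

    def __post_init__(self) -> None:
        A = self.values
        if not np.allclose(A, A.T, atol=1e-10):
            raise CoMethNetError("adjacency must be symmetric")
        if A.min() < -1e-12 or A.max() > 1 + 1e-12:
            raise CoMethNetError("adjacency entries must lie in [0, 1]")


@dataclass
class TOMMatrix:
    probe_ids: list[str]
    values: np.ndarray

    def dissimilarity(self) -> pd.DataFrame:
        return pd.DataFrame(
            1.0 - self.values, index=self.probe_ids, columns=self.probe_ids
        )


def signed_adjacency(
    beta: BetaMatrix, soft_power: int = DEFAULT_SOFT_POWER
) -> AdjacencyMatrix:
    """Signed soft-thresholded adjacency ``((1 + cor)/2)^power``.

    Requires >= 3 samples and no zero-variance probe.  The diagonal is 1.
    """
    if soft_power < 1 or int(soft_power) != soft_power:
        raise CoMethNetError(f"soft_power must be a positive integer, got {soft_power}")
    if beta.n_samples < 3:
        raise CoMethNetError("at least 3 samples are required")
    corr = _probe_correlation(beta.values)
    A = ((1.0 + corr) / 2.0) ** soft_power
    np.fill_diagonal(A, 1.0)
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)
    return AdjacencyMatrix(beta.probe_ids, A, int(soft_power))


def topological_overlap(adjacency: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap: ``(L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.

    ``L_ij`` counts shared-neighbour agreement and ``k_i`` is node
    connectivity (both excluding self-edges); the diagonal is 1 by
    convention.
    """
    A = adjacency.values.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # off-diagonal entries are sums over u != i, j since a_ii = 0
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(adjacency.probe_ids, tom)


@dataclass
class ModuleEigenvector:
    """Per-sample summary profile of one module (first principal component)."""

    module_label: int
    scores: pd.Series  # unit-norm, indexed by sample id
    variance_explained: float
    orientation_sign: int

    def correlation_with(self, values: pd.Series) -> float:
        aligned = values.loc[self.scores.index].to_numpy(dtype=float)
        return float(np.corrcoef(self.scores.to_numpy(), aligned)[0, 1])


def module_eigenvector(
    beta: BetaMatrix, members, module_label: int = 0
) -> ModuleEigenvector:
    """First principal component of the standardized module matrix.

    Sample scores are unit-norm and sign-fixed so that their correlation
    with the mean standardized module profile is non-negative: a module
    hypermethylated with age therefore has a positive eigenvector-age
    correlation.  Constant probes are dropped with a warning.
    """
    members = list(members)
    if len(members) < 2:
        raise CoMethNetError("a module needs at least 2 probes")
    if beta.n_samples < 3:
        raise CoMethNetError("at least 3 samples are required")
    X = beta.values.loc[members].to_numpy()
    sd = X.std(axis=1)
    if (sd == 0).any():
        logger.warning("dropping %d constant probe(s) from module", int((sd == 0).sum()))
        X = X[sd > 0]
        if X.shape[0] < 2:
            raise CoMethNetError("fewer than 2 non-constant probes in module")
        sd = sd[sd > 0]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    scores = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = Z.mean(axis=0)
    sign = 1
    c = np.corrcoef(scores, mean_profile)[0, 1]
    if c < 0:
        sign = -1
        scores = -scores
    return ModuleEigenvector(
        module_label=module_label,
        scores=pd.Series(scores, index=beta.sample_ids, name=f"ME{module_label}"),
        variance_explained=var_explained,
        orientation_sign=sign,
    )


def _corr_with_vector(values: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of a probes x samples frame with y."""
    X = values.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    return np.clip(r, -1.0, 1.0)


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Pearson correlation via the t transform."""
    if n < 4:
        raise CoMethNetError("at least 4 samples are required for correlation tests")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * t_dist.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))


def module_membership(
    beta: BetaMatrix, eigenvectors: dict[int, ModuleEigenvector]
) -> pd.DataFrame:
    """kME table: per probe, correlation with every module eigenvector.

    Columns ``kME{label}`` and ``p{label}``; p-values from the exact t
    transform of the correlation with n - 2 degrees of freedom.
    """
    n = beta.n_samples
    if n < 4:
        raise CoMethNetError("at least 4 samples are required for kME")
    out = {}
    for label, ev in sorted(eigenvectors.items()):
        y = ev.scores.loc[beta.sample_ids].to_numpy()
        r = _corr_with_vector(beta.values, y)
        out[f"kME{label}"] = r
        out[f"p{label}"] = correlation_pvalue(r, n)
    return pd.DataFrame(out, index=beta.probe_ids)


def detect_modules(
    dissimilarity: pd.DataFrame,
    beta: BetaMatrix,
    min_module_size: int = 20,
    cut_height: float = 0.995,
    kme_reassign_threshold: float = 0.5,
    kme_prune_threshold: float = 0.3,
    min_mean_kme: float = 0.6,
) -> ModuleAssignment:
    """Cut the average-linkage dendrogram of ``1 - TOM`` into modules.

    A simplified dynamic-hybrid procedure:

    1. static cut of the dendrogram at absolute height ``cut_height``
       (heights are TOM dissimilarities in [0, 1]) gives candidate
       branches; branches below ``min_module_size`` dissolve into the
       unassigned background (label 0);
    2. each candidate branch is pruned of members whose kME against the
       branch eigenvector falls below ``kme_prune_threshold`` — topological
       overlap attaches a halo of weakly connected probes to any highly
       connected branch, and kME is what separates core from halo;
    3. a pruned branch survives only if it still has ``min_module_size``
       members whose mean kME (against the unpruned branch eigenvector, so
       the check is not biased by the pruning itself) reaches
       ``min_mean_kme``; this cohesion check rejects the incidental
       branches that a static cut produces on unstructured data, whose
       first principal component rarely attains mean kME above ~0.45 at
       desk-scale sample sizes;
    4. a membership-based second pass reassigns background probes to the
       module whose (recomputed) eigenvector they correlate with above
       ``kme_reassign_threshold``.

    Modules are renumbered by decreasing size starting at 1.
    """
    probe_ids = list(dissimilarity.index)
    if list(dissimilarity.columns) != probe_ids:
        raise CoMethNetError("dissimilarity must be square with matching labels")
    if len(probe_ids) < min_module_size:
        logger.warning(
            "fewer probes (%d) than min_module_size (%d): all unassigned",
            len(probe_ids),
            min_module_size,
        )
        return ModuleAssignment(
            pd.Series(0, index=probe_ids, name="module"), min_module_size
        )

    D = dissimilarity.to_numpy()
    condensed = squareform((D + D.T) / 2.0, checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    labels = pd.Series(raw.astype(np.int64), index=probe_ids, name="module")
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_module_size]
    labels[~labels.isin(keep)] = 0

    # prune halos, then validate branch cohesion
    for lab in [l for l in labels.unique() if l != 0]:
        members = labels.index[labels == lab]
        ev = module_eigenvector(beta, members, module_label=int(lab))
        kme = _corr_with_vector(beta.values.loc[members], ev.scores.to_numpy())
        core = kme >= kme_prune_threshold
        if core.sum() < min_module_size or np.nanmean(kme[core]) < min_mean_kme:
            logger.info(
                "dissolving branch of %d probes (core %d, core mean kME %.2f)",
                len(members),
                int(core.sum()),
                float(np.nanmean(kme[core])) if core.any() else float("nan"),
            )
            labels[members] = 0
        else:
            labels[members[~core]] = 0

    # membership-based reassignment of background probes
    module_labels = [l for l in labels.unique() if l != 0]
    if module_labels:
        evs = {
            int(lab): module_eigenvector(beta, labels.index[labels == lab], int(lab))
            for lab in module_labels
        }
        grey = labels.index[labels == 0]
        if len(grey):
            kme = np.stack(
                [
                    _corr_with_vector(
                        beta.values.loc[grey], evs[lab].scores.to_numpy()
                    )
                    for lab in sorted(evs)
                ],
                axis=1,
            )
            best = np.nanargmax(kme, axis=1)
            best_val = kme[np.arange(len(grey)), best]
            pull = best_val > kme_reassign_threshold
            if pull.any():
                ordered = np.array(sorted(evs))
                labels.loc[grey[pull]] = ordered[best[pull]]

    # renumber by decreasing size, ties broken by old label for determinism
    sizes = labels[labels != 0].value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    labels = labels.map(remap).astype(int)
    return ModuleAssignment(labels, min_module_size)


def select_hubs(
    kme_table: pd.DataFrame,
    module_label: int,
    threshold: float = 0.85,
    manifest=None,
) -> pd.DataFrame:
    """Intramodular hub probes: kME above ``threshold``, sorted descending.

    Returns columns ``gene`` (when a manifest is given), ``probe_id``
    (index) and ``kME``.
    """
    col = f"kME{module_label}"
    if col not in kme_table.columns:
        raise CoMethNetError(f"unknown module label {module_label}")
    kme = kme_table[col]
    hubs = kme[kme > threshold].sort_values(ascending=False)
    out = pd.DataFrame({"kME": hubs})
    if manifest is not None:
        out.insert(0, "gene", manifest.genes_for(hubs.index).to_numpy())
    out.index.name = "probe_id"
    return out


@dataclass
class ModuleTraitMatrix:
    """Module x trait grid of Pearson correlations and p-values."""

    correlations: pd.DataFrame
    pvalues: pd.DataFrame

    def filter(self, min_abs_cor: float) -> "ModuleTraitMatrix":
        """Mask (module, trait) cells with |cor| below the threshold."""
        mask = self.correlations.abs() >= min_abs_cor
        return ModuleTraitMatrix(
            self.correlations.where(mask), self.pvalues.where(mask)
        )


def module_trait_correlations(
    eigenvectors: dict[int, ModuleEigenvector],
    sheet: SampleSheet,
    trait_names: list[str] | None = None,
) -> ModuleTraitMatrix:
    """Correlate each module eigenvector with age, serostatus and traits."""
    traits = pd.concat(
        [sheet.data[["age", "hiv_status"]].astype(float), sheet.traits], axis=1
    )
    if trait_names is not None:
        traits = traits[list(trait_names)]
    if len(traits) < 4:
        raise CoMethNetError("at least 4 samples are required")
    cors, ps = {}, {}
    for label, ev in sorted(eigenvectors.items()):
        scores = ev.scores.loc[traits.index].to_numpy()
        row_c, row_p = {}, {}
        for name, col in traits.items():
            y = col.to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 4 or np.std(y[ok]) == 0:
                logger.warning("trait %r constant or too sparse; reported missing", name)
                row_c[name], row_p[name] = np.nan, np.nan
                continue
            r = float(np.corrcoef(scores[ok], y[ok])[0, 1])
            row_c[name] = r
            row_p[name] = float(correlation_pvalue(np.array([r]), int(ok.sum()))[0])
        cors[f"ME{label}"] = row_c
        ps[f"ME{label}"] = row_p
    return ModuleTraitMatrix(
        correlations=pd.DataFrame(cors).T, pvalues=pd.DataFrame(ps).T
    )


def scale_free_fit(adjacency: AdjacencyMatrix, n_bins: int = 10) -> float:
    """R-squared of the log-log connectivity-distribution fit.

    Diagnostic for soft-power choice; not used for automatic selection.
    """
    A = adjacency.values.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    counts, edges = np.histogram(k, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    ok = (counts > 0) & (centers > 0)
    if ok.sum() < 3:
        return float("nan")
    x, y = np.log10(centers[ok]), np.log10(counts[ok] / counts.sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else float("nan")
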
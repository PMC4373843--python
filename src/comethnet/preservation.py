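"""Permutation-based module preservation between two cohorts.

Quantifies whether modules found in a reference cohort keep their density
(tight within-module connectivity) and connectivity pattern (which probes
are hubs) in an independent test cohort.  For each module, five statistics
are computed in the test network — mean within-module adjacency, mean
within-module correlation, and the correlations between reference and test
of intramodular connectivity (kIM), of the within-module correlation
matrices, and of module membership (kME) — and each is standardized against
random probe sets of the same size, giving a permutation Z.  The composite

    Z_summary = (Z_density + Z_connectivity) / 2

is banded as: < 2 not preserved, 2-10 weak-to-moderately preserved,
> 10 strongly preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BetaMatrix, CoMethNetError, ModuleAssignment
from .network import DEFAULT_SOFT_POWER

logger = logging.getLogger("comethnet")

CATEGORY_NOT = "not_preserved"
CATEGORY_WEAK = "weak_to_moderate"
CATEGORY_STRONG = "strong"

MIN_PERMUTATIONS = 50


def classify_preservation(z: float) -> str:
    """Band a Z_summary score: <2 not preserved, 2-10 weak/moderate, >10 strong."""
    if np.isnan(z):
        raise CoMethNetError("cannot classify a missing Z_summary")
    if z > 10:
        return CATEGORY_STRONG
    if z < 2:
        return CATEGORY_NOT
    return CATEGORY_WEAK


@dataclass
class PreservationReport:
    """Per-module preservation statistics and their permutation context."""

    table: pd.DataFrame  # module, size, Z_density, Z_connectivity, Z_summary, category
    n_permutations: int
    seed: int

    def z_summary(self, module_label: int) -> float:
        return float(self.table.loc[module_label, "Z_summary"])

    def category(self, module_label: int) -> str:
        return str(self.table.loc[module_label, "category"])


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _set_statistics(
    Zr: np.ndarray, Zt: np.ndarray, idx: np.ndarray, n_ref: int, n_test: int,
    soft_power: int,
) -> np.ndarray:
    """The five preservation statistics for one probe set.

    ``Zr``/``Zt`` are row-standardized probes x samples matrices of the
    reference and test cohorts; ``idx`` indexes the probe set.  Returns
    [meanAdj, meanCor, cor_kIM, cor_cor, cor_kME].
    """
    s = len(idx)
    Ar = Zr[idx]
    At = Zt[idx]
    Cr = (Ar @ Ar.T) / n_ref
    Ct = (At @ At.T) / n_test
    np.clip(Cr, -1.0, 1.0, out=Cr)
    np.clip(Ct, -1.0, 1.0, out=Ct)
    adj_r = ((1.0 + Cr) / 2.0) ** soft_power
    adj_t = ((1.0 + Ct) / 2.0) ** soft_power
    off = ~np.eye(s, dtype=bool)

    mean_adj = float(adj_t[off].mean())
    mean_cor = float(Ct[off].mean())

    k_r = adj_r.sum(axis=1) - 1.0  # intramodular connectivity, self excluded
    k_t = adj_t.sum(axis=1) - 1.0
    cor_kim = _safe_corr(k_r, k_t)
    cor_cor = _safe_corr(Cr[off], Ct[off])

    kme_r = _kme_within(Ar)
    kme_t = _kme_within(At)
    cor_kme = _safe_corr(kme_r, kme_t)
    return np.array([mean_adj, mean_cor, cor_kim, cor_cor, cor_kme])


def _kme_within(Z: np.ndarray) -> np.ndarray:
    """kME of each set probe against the set's own eigenvector."""
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    scores = vt[0]
    scores = scores - scores.mean()
    norm = np.linalg.norm(scores)
    if norm == 0:
        return np.zeros(Z.shape[0])
    scores /= norm
    zc = Z - Z.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(zc, axis=1)
    denom[denom == 0] = 1.0
    return (zc @ scores) / denom


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def preservation_z(
    ref: BetaMatrix,
    test: BetaMatrix,
    assignment: ModuleAssignment,
    soft_power: int = DEFAULT_SOFT_POWER,
    n_permutations: int = 200,
    seed: int = 0,
) -> PreservationReport:
    """Permutation Z statistics for each reference module in a test cohort.

    The probe universe is the intersection of both matrices and the
    assignment.  For each module the five observed statistics are compared
    with ``n_permutations`` random probe sets of the same size;
    ``Z_density`` is the median of the density Zs, ``Z_connectivity`` the
    median of the connectivity Zs, and ``Z_summary`` their mean.
    Deterministic given ``seed``.
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise CoMethNetError(
            f"at least {MIN_PERMUTATIONS} permutations are required for Z values"
        )
    common = [
        p
        for p in assignment.labels.index
        if p in set(ref.probe_ids) and p in set(test.probe_ids)
    ]
    logger.info(
        "preservation universe: %d probes (of %d assigned)",
        len(common),
        len(assignment.labels),
    )
    ref_v = ref.values.loc[common]
    test_v = test.values.loc[common]
    Zr = _standardize_rows(ref_v.to_numpy())
    Zt = _standardize_rows(test_v.to_numpy())
    n_ref = ref.n_samples
    n_test = test.n_samples
    labels = assignment.labels.loc[common]
    pos = {p: i for i, p in enumerate(common)}

    rng = np.random.default_rng(int(seed) % (2**31))
    rows = []
    for lab in assignment.module_labels:
        members = [p for p in assignment.members(lab) if p in pos]
        size = len(members)
        if size < 3:
            logger.warning("module %d has < 3 probes in the intersection; skipped", lab)
            continue
        idx = np.array([pos[p] for p in members])
        observed = _set_statistics(Zr, Zt, idx, n_ref, n_test, soft_power)
        null = np.empty((n_permutations, 5))
        for b in range(n_permutations):
            draw = rng.choice(len(common), size=size, replace=False)
            null[b] = _set_statistics(Zr, Zt, draw, n_ref, n_test, soft_power)
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        z = np.empty(5)
        for i in range(5):
            if sd[i] == 0:
                logger.warning("zero null spread for statistic %d; Z set to +inf", i)
                z[i] = np.inf if observed[i] > mu[i] else -np.inf
            else:
                z[i] = (observed[i] - mu[i]) / sd[i]
        z_density = float(np.median(z[:2]))
        z_connectivity = float(np.median(z[2:]))
        z_summary = (z_density + z_connectivity) / 2.0
        rows.append(
            {
                "module": lab,
                "size": size,
                "Z_meanAdj": z[0],
                "Z_meanCor": z[1],
                "Z_cor_kIM": z[2],
                "Z_cor_cor": z[3],
                "Z_cor_kME": z[4],
                "Z_density": z_density,
                "Z_connectivity": z_connectivity,
                "Z_summary": z_summary,
                "category": classify_preservation(z_summary),
            }
        )
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    return PreservationReport(table=table, n_permutations=n_permutations, seed=seed)
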
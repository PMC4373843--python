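"""Synthetic 450K-style cohorts with planted age/HIV co-methylation structure.

The generator emulates the design of a matched-pair PBMC methylation study:
seropositive/seronegative pairs sharing an age, a beta-value matrix with a
bimodal 450K-like background, one or more planted co-methylation modules
whose latent factor is linear in age with an additive seropositive offset,
Infinium type-II dynamic-range compression, and (optionally) cell-type
mixture confounding.  Effects are planted on the logit scale so emitted
betas stay inside [0, 1] without clipping.

Every random draw comes from a named stream derived from one global seed,
so adding a component does not perturb the others and identical seeds give
bit-identical cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import BetaMatrix, CoMethNetError, ProbeManifest, SampleSheet


def _stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component RNG derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass
class PlantedModule:
    """One planted co-methylation module.

    The module's latent factor for sample *s* is
    ``f(s) = alpha_age * age_s + gamma_hiv * hiv_s + noise``; probe *j*
    carries it with loading ``l_j`` on the logit scale.  The planted
    age-acceleration ratio is ``gamma_hiv / alpha_age`` (years).
    """

    size: int = 300
    alpha_age: float = 0.01  # latent slope per year of age
    gamma_hiv: float = 0.14  # latent offset for seropositive samples
    loading_range: tuple[float, float] = (0.8, 1.2)
    baseline_range: tuple[float, float] = (-1.5, 1.5)  # logit-scale

    def __post_init__(self) -> None:
        if self.size < 3:
            raise CoMethNetError("planted module size must be >= 3")

    @property
    def planted_ratio(self) -> float:
        """Planted acceleration in years, gamma_hiv / alpha_age."""
        if self.alpha_age == 0:
            return float("nan")
        return self.gamma_hiv / self.alpha_age


@dataclass
class CellMixSpec:
    """Cell-type mixture confounding.

    Each sample's observed profile is a proportion-weighted average of
    per-cell-type pure profiles.  Proportions are Dirichlet draws whose
    concentration differs between serostatus groups when
    ``hiv_concentration`` is given, which confounds cell composition with
    HIV status (the situation reference-free adjustment addresses).
    """

    concentration: tuple[float, ...] = (8.0, 4.0, 2.0)
    hiv_concentration: tuple[float, ...] | None = None
    differential_fraction: float = 0.3  # probes with cell-type-specific offsets
    effect_logit_sd: float = 1.0


@dataclass
class SimulationConfig:
    n_pairs: int = 24
    age_range: tuple[float, float] = (20.0, 56.0)
    n_probes: int = 2000
    modules: list[PlantedModule] = field(default_factory=lambda: [PlantedModule()])
    noise_sd: float = 0.05  # latent-factor noise
    probe_noise_sd: float = 0.1  # per-probe logit noise
    type2_fraction: float = 0.5
    type2_squeeze: float = 0.8
    age_jitter_sd: float = 0.0  # matched pairs share ages exactly by default
    cell_types: CellMixSpec | None = None
    seed: int = 0
    #: seed for probe-level architecture (baselines, loadings, chemistry,
    #: genes).  Two configs sharing a probe_seed but differing in seed
    #: emulate two cohorts assayed on the same array: same CpG properties,
    #: independent participants.  Defaults to ``seed``.
    probe_seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(m.size for m in self.modules)
        if total > self.n_probes:
            raise CoMethNetError(
                f"module sizes sum to {total} > n_probes = {self.n_probes}"
            )
        if not (0.0 <= self.type2_fraction <= 1.0):
            raise CoMethNetError("type2_fraction must be in [0, 1]")
        if not (0.0 < self.type2_squeeze <= 1.0):
            raise CoMethNetError("type2_squeeze must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    labels: pd.Series  # probe -> true module label (0 = background)
    latent: pd.DataFrame  # samples x module labels, the true factors
    planted_ratio: dict[int, float]
    cell_proportions: pd.DataFrame | None = None


def _background_baselines(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal logit-scale baselines mimicking the 450K beta distribution."""
    comp = rng.choice(3, size=n, p=[0.5, 0.35, 0.15])
    mu = np.array([-2.4, 1.7, 0.0])[comp]
    sd = np.array([0.8, 0.8, 1.0])[comp]
    return mu + sd * rng.standard_normal(n)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeManifest, GroundTruth]:
    """Generate one matched-pair cohort with planted module structure.

    Returns the beta matrix, sample sheet, probe manifest and ground truth.
    Deterministic given ``config.seed``.  The emitted matrix is *unbiased*
    (no type-II compression); apply :func:`apply_type2_bias` to emulate the
    raw-array state that normalization corrects.
    """
    cfg = config
    seed = cfg.seed
    probe_seed = cfg.probe_seed if cfg.probe_seed is not None else seed
    n_samples = 2 * cfg.n_pairs

    # --- samples: matched SP/SN pairs sharing an age -----------------------
    rng_age = _stream(seed, "ages")
    pair_ages = rng_age.uniform(*cfg.age_range, size=cfg.n_pairs)
    sample_ids, ages, hiv, pair_ids = [], [], [], []
    for i, a in enumerate(pair_ages):
        for status, tag in ((1, "SP"), (0, "SN")):
            sample_ids.append(f"P{i:03d}_{tag}")
            jitter = (
                rng_age.normal(0.0, cfg.age_jitter_sd) if cfg.age_jitter_sd > 0 else 0.0
            )
            ages.append(max(a + jitter, 1.0))
            hiv.append(status)
            pair_ids.append(f"P{i:03d}")
    sheet = SampleSheet(
        pd.DataFrame(
            {"age": ages, "hiv_status": hiv, "pair_id": pair_ids},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    age_vec = np.asarray(ages)
    hiv_vec = np.asarray(hiv, dtype=float)

    # --- probes ------------------------------------------------------------
    probe_ids = [f"cg{i:07d}" for i in range(cfg.n_probes)]
    labels = np.zeros(cfg.n_probes, dtype=int)
    start = 0
    for m_idx, mod in enumerate(cfg.modules, start=1):
        labels[start : start + mod.size] = m_idx
        start += mod.size

    rng_base = _stream(probe_seed, "baselines")
    rng_load = _stream(probe_seed, "loadings")
    rng_latent = _stream(seed, "latent_noise")
    rng_noise = _stream(seed, "probe_noise")

    logits = np.empty((cfg.n_probes, n_samples))
    latent = {}
    ratios = {}
    start = 0
    for m_idx, mod in enumerate(cfg.modules, start=1):
        f = (
            mod.alpha_age * age_vec
            + mod.gamma_hiv * hiv_vec
            + rng_latent.normal(0.0, cfg.noise_sd, size=n_samples)
        )
        latent[m_idx] = f
        ratios[m_idx] = mod.planted_ratio
        baselines = rng_base.uniform(*mod.baseline_range, size=mod.size)
        loadings = rng_load.uniform(*mod.loading_range, size=mod.size)
        # centre the factor so baselines set the module's methylation level
        fc = f - f.mean()
        logits[start : start + mod.size] = (
            baselines[:, None] + loadings[:, None] * fc[None, :]
        )
        start += mod.size
    n_bg = cfg.n_probes - start
    logits[start:] = _background_baselines(rng_base, n_bg)[:, None]
    logits += rng_noise.normal(0.0, cfg.probe_noise_sd, size=logits.shape)
    values = expit(logits)

    beta = BetaMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sample_ids)
    )

    # --- manifest: exact type-II count, random placement -------------------
    rng_type = _stream(probe_seed, "type_assignment")
    n_type2 = int(round(cfg.type2_fraction * cfg.n_probes))
    types = np.array(["I"] * cfg.n_probes, dtype=object)
    types[rng_type.permutation(cfg.n_probes)[:n_type2]] = "II"
    rng_gene = _stream(probe_seed, "genes")
    n_genes = max(cfg.n_probes // 3, 1)
    genes = [f"GENE{g:05d}" for g in rng_gene.integers(0, n_genes, size=cfg.n_probes)]
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "infinium_type": types,
                "gene": genes,
                "chrom": "chr1",
                "pos": np.arange(1, cfg.n_probes + 1) * 1000,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    truth = GroundTruth(
        labels=pd.Series(labels, index=probe_ids, name="module"),
        latent=pd.DataFrame(latent, index=sample_ids),
        planted_ratio=ratios,
    )

    # --- optional cell-type mixture confounding ----------------------------
    if cfg.cell_types is not None:
        beta, props = _apply_cell_mixture(
            beta, sheet, cfg.cell_types, logits, seed
        )
        truth.cell_proportions = props

    return beta, sheet, manifest, truth


def _apply_cell_mixture(beta, sheet, spec, logits, seed):
    """Replace the emitted matrix with a cell-type mixture of pure profiles."""
    rng = _stream(seed, "cells")
    n_types = len(spec.concentration)
    n_probes, n_samples = logits.shape
    diff = rng.random(n_probes) < spec.differential_fraction
    offsets = np.zeros((n_types, n_probes))
    offsets[:, diff] = rng.normal(
        0.0, spec.effect_logit_sd, size=(n_types, diff.sum())
    )
    pure = [
        BetaMatrix(
            pd.DataFrame(
                expit(logits + offsets[k][:, None]),
                index=beta.values.index,
                columns=beta.values.columns,
            )
        )
        for k in range(n_types)
    ]
    conc_sn = np.asarray(spec.concentration, dtype=float)
    conc_sp = (
        np.asarray(spec.hiv_concentration, dtype=float)
        if spec.hiv_concentration is not None
        else conc_sn
    )
    props = np.empty((n_samples, n_types))
    hiv = sheet.hiv_status.to_numpy()
    for s in range(n_samples):
        props[s] = rng.dirichlet(conc_sp if hiv[s] == 1 else conc_sn)
    props_df = pd.DataFrame(
        props,
        index=beta.values.columns,
        columns=[f"celltype_{k}" for k in range(n_types)],
    )
    return mix_cell_types(pure, props_df), props_df


def apply_type2_bias(
    beta: BetaMatrix, manifest: ProbeManifest, squeeze: float
) -> BetaMatrix:
    """Compress type-II probe betas toward 0.5: ``b' = 0.5 + squeeze*(b-0.5)``.

    Emulates the reduced dynamic range of the Infinium II chemistry that
    beta-mixture quantile normalization is designed to undo.  Type I probes
    are untouched; ``squeeze = 1`` is the identity.
    """
    if not (0.0 < squeeze <= 1.0):
        raise CoMethNetError(f"squeeze must be in (0, 1], got {squeeze}")
    if squeeze == 1.0:
        return BetaMatrix(beta.values.copy())
    out = beta.values.copy()
    t2 = [p for p in manifest.probes_of_type("II") if p in out.index]
    out.loc[t2] = 0.5 + squeeze * (out.loc[t2] - 0.5)
    return BetaMatrix(out)


def mix_cell_types(
    pure_profiles: list[BetaMatrix] | dict[str, BetaMatrix],
    proportions: pd.DataFrame,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BetaMatrix:
    """Proportion-weighted mixture of pure cell-type profiles.

    ``proportions`` is samples x cell-types and each row must sum to 1
    (within 1e-8).  Optional Gaussian noise is added on the beta scale and
    the result clipped into [0, 1].
    """
    if isinstance(pure_profiles, dict):
        profiles = [pure_profiles[c] for c in proportions.columns]
    else:
        profiles = list(pure_profiles)
    if len(profiles) != proportions.shape[1]:
        raise CoMethNetError("one pure profile required per proportion column")
    if set(proportions.index) == set(profiles[0].sample_ids):
        proportions = proportions.loc[profiles[0].sample_ids]
    rowsum = proportions.to_numpy().sum(axis=1)
    if np.abs(rowsum - 1.0).max() > 1e-8:
        raise CoMethNetError("proportion rows must sum to 1")
    ref = profiles[0].values
    mixed = np.zeros_like(ref.to_numpy())
    for k, prof in enumerate(profiles):
        if prof.values.shape != ref.shape:
            raise CoMethNetError("pure profile dimensions disagree")
        w = proportions.iloc[:, k].to_numpy()
        mixed += prof.values.to_numpy() * w[None, :]
    if noise_sd > 0:
        gen = rng if rng is not None else np.random.default_rng()
        mixed = np.clip(mixed + gen.normal(0.0, noise_sd, mixed.shape), 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(mixed, index=ref.index, columns=ref.columns))
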
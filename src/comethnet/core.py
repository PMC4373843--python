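"""Core data model for 450K-style methylation analysis.

The central object is the :class:`BetaMatrix`: a probes x samples matrix of
methylation fractions (beta values) in ``[0, 1]``.  Sample covariates live in
a :class:`SampleSheet` (age in years, HIV serostatus, optional matched-pair
identifiers, and arbitrary numeric traits such as cell-subset counts), and
array design metadata in a :class:`ProbeManifest` (Infinium type I/II
chemistry, gene annotation, genomic position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("comethnet")

MISSING_PROBE_FRACTION = 0.2  # probes with more missingness are dropped


class CoMethNetError(Exception):
    """Base class for all package errors."""


class ParseError(CoMethNetError):
    """A file violated the expected format or an invariant of its type."""


class InvalidParameterError(CoMethNetError, ValueError):
    """A parameter was outside its valid domain."""


def compute_beta(m_signal, u_signal, offset: float = 100.0):
    """Methylation fraction from methylated/unmethylated intensities.

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + offset)

    Negative intensities are clamped to zero; the positive ``offset``
    regularises low-intensity probes, so the result lies in ``[0, 1)``.
    Accepts scalars or arrays (broadcast).
    """
    if offset <= 0:
        raise InvalidParameterError(f"offset must be > 0, got {offset}")
    m = np.maximum(np.asarray(m_signal, dtype=float), 0.0)
    u = np.maximum(np.asarray(u_signal, dtype=float), 0.0)
    beta = m / (m + u + offset)
    if beta.ndim == 0:
        return float(beta)
    return beta


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()[:5]
        raise ParseError(f"duplicate {what}: {dupes}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``values`` is a float DataFrame indexed by probe id with sample ids as
    columns.  Missing values are NaN; all non-missing entries must lie in
    ``[0, 1]``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ParseError(
                "beta values outside [0, 1]: "
                f"range [{finite.min():.4g}, {finite.max():.4g}]"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    def select_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def select_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)])

    def drop_high_missing(
        self, max_fraction: float = MISSING_PROBE_FRACTION
    ) -> "BetaMatrix":
        """Drop probes whose missing-sample fraction exceeds ``max_fraction``."""
        frac = self.values.isna().mean(axis=1)
        bad = frac[frac > max_fraction].index
        if len(bad):
            logger.warning(
                "dropping %d probes with > %.0f%% missing values",
                len(bad),
                100 * max_fraction,
            )
            return BetaMatrix(self.values.drop(index=bad))
        return self


#: sample-sheet columns with a reserved meaning; everything else is a trait
RESERVED_SHEET_COLUMNS = ("age", "hiv_status", "pair_id")


@dataclass
class SampleSheet:
    """Per-sample covariates: age (years), HIV serostatus and numeric traits.

    ``hiv_status`` is coded 0 = seronegative, 1 = seropositive, so a
    regression coefficient on it is the seropositive offset.  ``pair_id``
    marks individually matched seropositive/seronegative pairs; each
    non-missing pair id must occur exactly twice, once per serostatus.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample ids")
        for col in ("age", "hiv_status"):
            if col not in df.columns:
                raise ParseError(f"sample sheet is missing required column {col!r}")
        df["age"] = df["age"].astype(float)
        if (df["age"] <= 0).any():
            bad = df.index[df["age"] <= 0].tolist()
            raise ParseError(f"non-positive age for samples {bad}")
        status = df["hiv_status"]
        if not status.isin([0, 1]).all():
            raise ParseError("hiv_status must be coded 0 (SN) / 1 (SP)")
        df["hiv_status"] = status.astype(int)
        if "pair_id" in df.columns:
            self._check_pairs(df)

    @staticmethod
    def _check_pairs(df: pd.DataFrame) -> None:
        for pid, grp in df.dropna(subset=["pair_id"]).groupby("pair_id"):
            if len(grp) != 2 or set(grp["hiv_status"]) != {0, 1}:
                raise ParseError(
                    f"pair_id {pid!r} must occur exactly twice, "
                    "once seropositive and once seronegative"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def age(self) -> pd.Series:
        return self.data["age"]

    @property
    def hiv_status(self) -> pd.Series:
        return self.data["hiv_status"]

    @property
    def pair_id(self) -> pd.Series | None:
        return self.data["pair_id"] if "pair_id" in self.data.columns else None

    @property
    def traits(self) -> pd.DataFrame:
        """Numeric covariate columns beyond the reserved ones."""
        extra = [c for c in self.data.columns if c not in RESERVED_SHEET_COLUMNS]
        return self.data[extra].apply(pd.to_numeric, errors="coerce")

    def pairs(self) -> list[tuple[str, str]]:
        """(seropositive, seronegative) sample-id tuples, one per pair."""
        if self.pair_id is None:
            raise CoMethNetError("sample sheet has no pair_id column")
        out = []
        for pid, grp in self.data.dropna(subset=["pair_id"]).groupby("pair_id"):
            sp = grp.index[grp["hiv_status"] == 1][0]
            sn = grp.index[grp["hiv_status"] == 0][0]
            out.append((sp, sn))
        return out


VALID_INFINIUM_TYPES = frozenset({"I", "II"})


@dataclass
class ProbeManifest:
    """Array design metadata: Infinium chemistry type and gene annotation.

    Positions are 1-based (Illumina manifest convention).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "probe ids")
        if "infinium_type" not in df.columns:
            raise ParseError("manifest is missing required column 'infinium_type'")
        types = df["infinium_type"].astype(str)
        bad = set(types) - VALID_INFINIUM_TYPES
        if bad:
            raise ParseError(f"invalid infinium_type values: {sorted(bad)}")
        df["infinium_type"] = types
        for col in ("gene", "chrom", "pos"):
            if col not in df.columns:
                df[col] = pd.NA

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def probes_of_type(self, infinium_type: str) -> list[str]:
        mask = self.data["infinium_type"] == infinium_type
        return list(self.data.index[mask])

    def genes_for(self, probe_ids) -> pd.Series:
        return self.data.loc[list(probe_ids), "gene"]


@dataclass
class ModuleAssignment:
    """Probe -> module-label map; label 0 is the unassigned background."""

    labels: pd.Series  # index: probe_id, values: int >= 0
    min_module_size: int = field(default=0)

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "probe ids")
        self.labels = self.labels.astype(int)
        if (self.labels < 0).any():
            raise ParseError("module labels must be non-negative")
        sizes = self.module_sizes
        small = {
            lab: n
            for lab, n in sizes.items()
            if lab != 0 and n < self.min_module_size
        }
        if small:
            raise ParseError(
                f"modules below the minimum size {self.min_module_size}: {small}"
            )

    @property
    def module_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()

    @property
    def module_labels(self) -> list[int]:
        """Sorted non-zero module labels."""
        return sorted(lab for lab in self.labels.unique() if lab != 0)

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])
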
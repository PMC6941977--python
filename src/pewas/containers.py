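"""Core in-memory containers shared by every pipeline stage.

The common currency of the package is the :class:`OmicsMatrix`: a samples x
features table of methylation, protein, or metabolite values together with a
scale tag that records which transform has been applied.  Stages consume and
produce tagged matrices so that, e.g., an EWAS scan cannot silently be run on
raw beta-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognized value scales for an :class:`OmicsMatrix`.
SCALE_TAGS = frozenset(
    {"beta", "M", "raw_protein", "log_protein", "standardized", "residual"}
)


class PewasError(Exception):
    """Base class for errors raised by this package."""


class DomainError(PewasError, ValueError):
    """A value lies outside the mathematical domain of a transform."""


class ConfigurationError(PewasError, ValueError):
    """Inconsistent dimensions or invalid configuration."""


@dataclass
class OmicsMatrix:
    """Samples x features numeric matrix with identifiers and a scale tag.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and feature
        identifiers as the columns.  Missing values are allowed.
    scale
        One of :data:`SCALE_TAGS`.  ``beta`` values must lie strictly in
        (0, 1); ``raw_protein`` values must be positive.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TAGS:
            raise ConfigurationError(
                f"unknown scale tag {self.scale!r}; expected one of {sorted(SCALE_TAGS)}"
            )
        if not isinstance(self.data, pd.DataFrame):
            raise ConfigurationError("OmicsMatrix.data must be a pandas DataFrame")
        if not self.data.index.is_unique:
            raise ConfigurationError("sample identifiers must be unique")
        if not self.data.columns.is_unique:
            raise ConfigurationError("feature identifiers must be unique")
        self.data = self.data.astype(float)
        values = self.data.to_numpy()
        finite = values[np.isfinite(values)]
        if self.scale == "beta" and finite.size:
            if finite.min() <= 0.0 or finite.max() >= 1.0:
                raise DomainError("beta values must lie strictly in (0, 1)")
        if self.scale == "raw_protein" and finite.size:
            if finite.min() <= 0.0:
                raise DomainError("raw protein intensities must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "OmicsMatrix":
        """Return a new matrix with replaced values (same construction checks)."""
        return OmicsMatrix(data, self.scale if scale is None else scale)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(feature_ids)], self.scale)

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[list(sample_ids)], self.scale)


@dataclass
class CellReference:
    """Reference methylation profiles of sorted leukocyte populations.

    ``profile`` is a cell-types x marker-CpGs table of beta-values used for
    reference-based (Houseman-style) deconvolution of whole-blood samples.
    """

    cell_types: list[str]
    marker_ids: list[str]
    profile: pd.DataFrame  # cell types x markers, beta scale

    def __post_init__(self) -> None:
        self.profile = self.profile.astype(float)
        if list(self.profile.index) != list(self.cell_types):
            self.profile = self.profile.loc[self.cell_types]
        if list(self.profile.columns) != list(self.marker_ids):
            self.profile = self.profile.loc[:, self.marker_ids]
        values = self.profile.to_numpy()
        if np.nanmin(values) < 0.0 or np.nanmax(values) > 1.0:
            raise DomainError("reference profile beta values must lie in [0, 1]")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)


#: Columns of a probe manifest table (Illumina-450K style).
MANIFEST_COLUMNS = [
    "probe_id",
    "probe_class",      # cg / ch / rs
    "targets_snp",      # bool: probe is a SNP control
    "chromosome",       # "1".."22", "X", "Y"
    "position",         # 1-based coordinate
    "n_measured",       # samples with a measurement for this probe
    "ucsc_region",      # ';'-separated subset of TSS200/TSS1500/5'UTR/Body/3'UTR
    "island_relation",  # island / north_shore / south_shore / north_shelf / south_shelf / open_sea
    "regulatory_feature",  # promoter / gene / non_gene / unclassified / none
    "cell_type_specific",  # bool: regulatory feature is cell-type specific
    "enhancer",
    "dhs",
    "dmr",
    "cdmr",
]

MANIFEST_BOOL_COLUMNS = [
    "targets_snp",
    "cell_type_specific",
    "enhancer",
    "dhs",
    "dmr",
    "cdmr",
]


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check a probe manifest for the required columns and basic invariants."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ConfigurationError(f"manifest is missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        raise ConfigurationError("manifest probe_id values must be unique")
    if (manifest["position"] < 1).any():
        raise ConfigurationError("manifest positions must be >= 1 (1-based)")
    return manifest
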
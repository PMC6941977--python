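"""Probe QC, scale transforms, winsorization, standardization, deconvolution.

The preprocessing contract for an EWAS with proteomics is: methylation
beta-values are converted to M-values (log2 of the methylated/unmethylated
ratio), protein intensities are natural-log scaled, both are winsorized at
the 5th/95th percentiles and z-scored per feature.  Whole-blood cell-type
composition is estimated from reference profiles by constrained projection
so it can be regressed out downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import (
    CellReference,
    ConfigurationError,
    DomainError,
    OmicsMatrix,
    validate_manifest,
)

# Order matters: a probe is counted under the first rule that removes it.
QC_RULES = ["snp_probe", "under_measured", "chr_x", "chr_y", "non_cg"]


@dataclass
class QCResult:
    """Retained probes plus a ledger of how many probes each rule removed."""

    retained: list[str]
    ledger: dict[str, int]
    n_input: int

    def __post_init__(self) -> None:
        removed = sum(self.ledger.values())
        assert removed == self.n_input - len(self.retained)


def qc_filter_probes(manifest: pd.DataFrame, min_measured: int = 100) -> QCResult:
    """Apply the standard 450K probe filters in a fixed order.

    Rules, in order of precedence: SNP-control probes (class ``rs`` or
    ``targets_snp``), probes with fewer than ``min_measured`` measurements,
    probes on chromosome X, probes on chromosome Y, and non-``cg`` probes.
    Each excluded probe is counted once, under the first rule that removes it.
    """
    validate_manifest(manifest)
    if manifest.empty:
        raise ConfigurationError("manifest is empty")

    chrom = manifest["chromosome"].astype(str)
    rule_masks = {
        "snp_probe": (manifest["probe_class"] == "rs")
        | manifest["targets_snp"].astype(bool),
        "under_measured": manifest["n_measured"] < min_measured,
        "chr_x": chrom == "X",
        "chr_y": chrom == "Y",
        "non_cg": manifest["probe_class"] != "cg",
    }

    removed = np.zeros(len(manifest), dtype=bool)
    ledger: dict[str, int] = {}
    for rule in QC_RULES:
        hits = rule_masks[rule].to_numpy() & ~removed
        ledger[rule] = int(hits.sum())
        removed |= hits
    retained = manifest.loc[~removed, "probe_id"].tolist()
    return QCResult(retained=retained, ledger=ledger, n_input=len(manifest))


def beta_to_m(matrix: OmicsMatrix) -> OmicsMatrix:
    """M = log2(b / (1 - b)), elementwise; missing values propagate."""
    if matrix.scale != "beta":
        raise ConfigurationError(f"expected a beta-scale matrix, got {matrix.scale!r}")
    values = matrix.values()
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
        raise DomainError("beta values at 0 or 1 have no M-value; refusing to clamp")
    m = np.log2(values / (1.0 - values))
    return OmicsMatrix(pd.DataFrame(m, index=matrix.data.index, columns=matrix.data.columns), "M")


def m_to_beta(matrix: OmicsMatrix) -> OmicsMatrix:
    """Inverse of :func:`beta_to_m`: b = 2^M / (1 + 2^M)."""
    if matrix.scale != "M":
        raise ConfigurationError(f"expected an M-scale matrix, got {matrix.scale!r}")
    values = matrix.values()
    beta = 1.0 / (1.0 + np.exp2(-values))
    return OmicsMatrix(
        pd.DataFrame(beta, index=matrix.data.index, columns=matrix.data.columns), "beta"
    )


def log_scale_proteins(matrix: OmicsMatrix) -> OmicsMatrix:
    """Natural-log transform of positive protein intensities."""
    if matrix.scale != "raw_protein":
        raise ConfigurationError(
            f"expected a raw_protein-scale matrix, got {matrix.scale!r}"
        )
    values = matrix.values()
    finite = values[np.isfinite(values)]
    if finite.size and finite.min() <= 0.0:
        raise DomainError("protein intensities must be positive for log scaling")
    return OmicsMatrix(
        pd.DataFrame(np.log(values), index=matrix.data.index, columns=matrix.data.columns),
        "log_protein",
    )


def winsorize(
    matrix: OmicsMatrix,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
    method: str = "linear",
) -> OmicsMatrix:
    """Clamp each feature column to its [lower_q, upper_q] empirical quantiles.

    Values strictly below the lower quantile are set to that quantile, values
    strictly above the upper quantile to the upper quantile.  Quantiles are
    computed over non-missing entries with the given ``method`` (any
    ``np.quantile`` interpolation; the default is linear interpolation,
    type 7).  With ``method="lower"`` the bounds snap to order statistics
    (lower bound via ``lower``, upper bound via ``higher``), which makes the
    operation exactly idempotent.
    """
    if not (0.0 <= lower_q < upper_q <= 1.0):
        raise ConfigurationError("require 0 <= lower_q < upper_q <= 1")
    values = matrix.values().copy()
    lower_method, upper_method = (
        ("lower", "higher") if method == "lower" else (method, method)
    )
    with np.errstate(invalid="ignore"):
        lo = np.nanquantile(values, lower_q, axis=0, method=lower_method)
        hi = np.nanquantile(values, upper_q, axis=0, method=upper_method)
        clipped = np.clip(values, lo, hi)
    clipped[np.isnan(values)] = np.nan
    scale = matrix.scale
    return OmicsMatrix(
        pd.DataFrame(clipped, index=matrix.data.index, columns=matrix.data.columns), scale
    )


def standardize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Z-score each feature column to mean 0, sample SD (n-1 denominator) 1.

    Missing values are preserved and excluded from the column statistics.
    A zero-variance column is an error naming the offending feature.
    """
    values = matrix.values()
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    bad = ~(sd > 0)
    if bad.any():
        names = [matrix.feature_ids[i] for i in np.flatnonzero(bad)[:10]]
        raise DomainError(f"zero-variance feature column(s): {names}")
    z = (values - mean) / sd
    return OmicsMatrix(
        pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns),
        "standardized",
    )


def estimate_cell_fractions(
    methylation: OmicsMatrix, reference: CellReference
) -> pd.DataFrame:
    """Reference-based (Houseman-style) cell-composition estimation.

    For each sample, project its marker-CpG beta-values onto the reference
    profiles under non-negativity (active-set NNLS, exact at convergence),
    then renormalize the weights to the unit simplex.

    Returns a samples x cell-types DataFrame whose rows are non-negative and
    sum to 1.
    """
    if methylation.scale != "beta":
        raise ConfigurationError("cell-fraction estimation expects beta-scale data")
    markers = [m for m in reference.marker_ids if m in methylation.data.columns]
    if len(markers) < reference.n_cell_types:
        raise ConfigurationError(
            f"need at least {reference.n_cell_types} shared marker CpGs, found {len(markers)}"
        )
    profile = reference.profile.loc[:, markers].to_numpy()  # cells x markers
    if np.linalg.matrix_rank(profile) < reference.n_cell_types:
        raise ConfigurationError("reference profile matrix is rank deficient")
    betas = methylation.data.loc[:, markers].to_numpy()

    a_full = profile.T  # markers x cells
    weights = np.empty((betas.shape[0], reference.n_cell_types))
    for i, row in enumerate(betas):
        ok = np.isfinite(row)
        w, _ = nnls(a_full[ok], row[ok])
        total = w.sum()
        weights[i] = w / total if total > 0 else np.full(w.shape, 1.0 / w.size)
    return pd.DataFrame(
        weights, index=methylation.data.index, columns=reference.cell_types
    )
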
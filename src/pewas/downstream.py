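"""Downstream associations of pQTM CpGs/proteins with clinical phenotypes
and metabolites, metabolic-syndrome derivation, and joint variance models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ConfigurationError, OmicsMatrix
from .stepwise import design_columns

_MIN_P = np.nextafter(0.0, 1.0)

MET_S_COMPONENTS = [
    "waist_cm",
    "tg_mg_dl",
    "hdl_mg_dl",
    "sbp_mmHg",
    "dbp_mmHg",
    "glucose_mg_dl",
    "lipid_drug",
    "bp_drug",
    "glucose_drug",
]


def derive_mets(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Metabolic syndrome by the harmonized >=3-of-5 criteria.

    Criteria (sex column: 1 = male, 0 = female):

    1. waist circumference >= 94 cm (men) / >= 80 cm (women);
    2. triglycerides >= 150 mg/dl or lipid-lowering drug;
    3. HDL < 40 mg/dl (men) / < 50 mg/dl (women) or lipid-lowering drug;
    4. SBP >= 130 mmHg or DBP >= 85 mmHg or antihypertensive drug;
    5. fasting glucose >= 100 mg/dl or glucose-lowering drug.

    Missing components count as criterion-not-met (a drug flag can still
    satisfy the criterion).  Returns (flag, number of missing components).
    """
    required = ["sex"] + MET_S_COMPONENTS
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ConfigurationError(f"MetS derivation needs columns: {missing_cols}")
    male = table["sex"].fillna(0).astype(float) >= 0.5

    def ge(col, cutoff):
        return table[col].ge(cutoff).fillna(False)

    def lt(col, cutoff):
        return table[col].lt(cutoff).fillna(False)

    def drug(col):
        return table[col].fillna(0).astype(float) >= 0.5

    waist = ge("waist_cm", 94).where(male, ge("waist_cm", 80))
    tg = ge("tg_mg_dl", 150) | drug("lipid_drug")
    hdl = lt("hdl_mg_dl", 40).where(male, lt("hdl_mg_dl", 50)) | drug("lipid_drug")
    bp = ge("sbp_mmHg", 130) | ge("dbp_mmHg", 85) | drug("bp_drug")
    glucose = ge("glucose_mg_dl", 100) | drug("glucose_drug")

    count = (
        waist.astype(int) + tg.astype(int) + hdl.astype(int) + bp.astype(int) + glucose.astype(int)
    )
    n_missing = table[MET_S_COMPONENTS].isna().sum(axis=1)
    return (count >= 3), n_missing


def _masked_adjusted_scan(
    y_matrix: np.ndarray,
    x: np.ndarray,
    covs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of every column of y on [1, x, covs]; returns slope/se/p for x."""
    design = np.column_stack([np.ones(len(x)), x, covs])
    k = design.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(design, y_matrix, rcond=None)
    if rank < k:
        raise ConfigurationError("rank-deficient design in adjusted scan")
    resid = y_matrix - design @ coef
    df = len(x) - k
    sigma2 = (resid * resid).sum(axis=0) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    slope = coef[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = slope / se
        p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _MIN_P, 1.0)
    return slope, se, p, df


def phenotype_association(
    features: OmicsMatrix,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype_names=None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Feature ~ phenotype + age + sex, per feature x phenotype.

    Binary phenotypes enter as 0/1 regressors.  Returns the association
    table and the Bonferroni threshold alpha / n_features.  Zero-variance
    phenotypes are skipped with a record.
    """
    if phenotype_names is None:
        phenotype_names = [c for c in phenotypes.columns if c not in ("sex",)]
    cov = design_columns(covariates.loc[features.data.index], ["age", "sex"]).to_numpy(float)
    y_all = features.data.to_numpy(float)
    rows = []
    for name in phenotype_names:
        x = phenotypes.loc[features.data.index, name].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(cov).all(axis=1)
        if x[ok].std() == 0 or ok.sum() < 4:
            rows.append(
                {
                    "feature_id": None,
                    "phenotype": name,
                    "slope": np.nan,
                    "p": np.nan,
                    "n": int(ok.sum()),
                    "skipped": "zero-variance or too few observations",
                }
            )
            continue
        y = y_all[ok]
        col_ok = np.isfinite(y).all(axis=0)
        slope, se, p, _ = _masked_adjusted_scan(y[:, col_ok], x[ok], cov[ok])
        for j, fid in enumerate(np.array(features.feature_ids)[col_ok]):
            rows.append(
                {
                    "feature_id": fid,
                    "phenotype": name,
                    "slope": float(slope[j]),
                    "p": float(p[j]),
                    "n": int(ok.sum()),
                    "skipped": "",
                }
            )
    threshold = alpha / features.n_features
    return pd.DataFrame(rows), threshold


def metabolite_association(
    cpgs: OmicsMatrix,
    metabolites: OmicsMatrix,
    covariates: pd.DataFrame,
    covariate_names=("age", "sex", "cell"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """CpG ~ metabolite + (age, sex, cell fractions, genetic PCs).

    ``covariate_names`` defaults to age/sex/cell; genetic PC columns present
    in the covariate table (geno_pc*) are appended automatically.  Returns
    the association table and the Bonferroni threshold
    alpha / (n_cpgs x n_metabolites).
    """
    names = list(covariate_names) + [
        c for c in covariates.columns if c.startswith("geno_pc")
    ]
    cov = design_columns(covariates.loc[cpgs.data.index], names).to_numpy(float)
    y_all = cpgs.data.to_numpy(float)
    rows = []
    for name in metabolites.feature_ids:
        x = metabolites.data[name].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(cov).all(axis=1)
        if x[ok].std() == 0 or ok.sum() < cov.shape[1] + 3:
            continue
        y = y_all[ok]
        col_ok = np.isfinite(y).all(axis=0)
        slope, se, p, _ = _masked_adjusted_scan(y[:, col_ok], x[ok], cov[ok])
        for j, fid in enumerate(np.array(cpgs.feature_ids)[col_ok]):
            rows.append(
                {
                    "feature_id": fid,
                    "metabolite": name,
                    "slope": float(slope[j]),
                    "p": float(p[j]),
                    "n": int(ok.sum()),
                }
            )
    threshold = alpha / (cpgs.n_features * metabolites.n_features)
    return pd.DataFrame(rows), threshold


def joint_variance_explained(
    meth: OmicsMatrix, cpg_ids, protein: pd.Series
) -> tuple[float, float]:
    """R^2 (and adjusted R^2) of a protein on a CpG set jointly.

    Fits one OLS of the protein on all named CpG columns simultaneously;
    quantifies how much of the protein's variance the CpG set accounts for.
    """
    cpg_ids = list(cpg_ids)
    x = meth.data.loc[:, cpg_ids]
    y = protein.loc[meth.data.index]
    ok = np.isfinite(x.to_numpy()).all(axis=1) & np.isfinite(y.to_numpy(float))
    if ok.sum() <= len(cpg_ids) + 1:
        raise ConfigurationError(
            "design wider than samples; regularized joint models are out of scope"
        )
    fit = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    return float(fit.rsquared), float(fit.rsquared_adj)
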
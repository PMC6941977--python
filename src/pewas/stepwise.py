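"""Step-wise deconfounding EWAS: residualization, mass-univariate scan,
Bonferroni control, driver attribution, and diagnostics.

The procedure starts from transformed (winsorized, z-scored) methylation
M-values and log-protein levels and performs a mass-univariate scan of every
CpG x protein pair (M-value as the dependent variable, protein as the
independent variable).  Candidate drivers are then regressed out of BOTH
matrices in a fixed order -- sex, white-blood-cell fractions, cis-SNPs, age,
smoking, BMI, diabetes -- re-scanning after each step.  A pair that was
significant before a step but not after is attributed to the covariate added
at that step; pairs that survive every step have no identifiable common
driver.

Residualization is cumulative: every step regresses the original transformed
data on the covariate set accumulated so far, which is equivalent to
sequential residualization for nested OLS but numerically more stable.
Comparisons with the significance threshold are strict (p < threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ConfigurationError, DomainError, OmicsMatrix

#: default covariate order of the step-wise regression
DEFAULT_STEP_ORDER = ["sex", "cell", "snp", "age", "smoking", "bmi", "diabetes"]

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)

_MIN_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class StepDefinition:
    """One step of the step-wise regression.

    ``covariates_added`` are symbolic names resolved against the covariate
    table: ``sex``/``age``/``bmi``/``diabetes`` are single columns,
    ``smoking`` expands to never/former/current indicator contrasts,
    ``cell`` expands to the estimated cell-fraction columns (dropping one to
    avoid simplex collinearity with the intercept) and ``snp`` switches on
    per-feature cis-SNP residualization.  ``cohort_extras`` are additional
    covariate columns (e.g. genetic and proteomic PCs of a multi-ethnic
    replication cohort) applied at this step.
    """

    index: int
    name: str
    covariates_added: tuple[str, ...]
    cohort_extras: tuple[str, ...] = ()


def default_steps(cohort_extras: tuple[str, ...] = ()) -> list[StepDefinition]:
    """Initial scan plus the seven deconfounding steps in the default order.

    ``cohort_extras`` (e.g. ``("geno_pc1", ..., "proteo_pc3")``) are applied
    at the sex step, as in a replication cohort with population structure.
    """
    steps = [StepDefinition(0, "initial", ())]
    for i, name in enumerate(DEFAULT_STEP_ORDER, start=1):
        extras = tuple(cohort_extras) if name == "sex" else ()
        steps.append(StepDefinition(i, name, (name,), extras))
    return steps


# ---------------------------------------------------------------------------
# design matrices and residualization
# ---------------------------------------------------------------------------


def design_columns(covariates: pd.DataFrame, names) -> pd.DataFrame:
    """Resolve symbolic covariate names into a numeric design block."""
    cols: dict[str, np.ndarray] = {}
    for name in names:
        if name == "smoking":
            smoking = covariates["smoking"]
            if smoking.dtype == object or isinstance(smoking.dtype, pd.CategoricalDtype):
                for level in ("former", "current"):
                    cols[f"smoking_{level}"] = (smoking == level).to_numpy(float)
            else:
                cols["smoking"] = smoking.to_numpy(float)
        elif name == "cell":
            frac_cols = [c for c in covariates.columns if c.startswith("cell_frac_")]
            if not frac_cols:
                raise ConfigurationError(
                    "no cell_frac_* columns in the covariate table; "
                    "run cell-fraction estimation first"
                )
            for c in frac_cols[:-1]:  # drop one: fractions sum to 1
                cols[c] = covariates[c].to_numpy(float)
        elif name == "snp":
            continue  # handled per feature by residualize_with_snps
        elif name in covariates.columns:
            cols[name] = covariates[name].to_numpy(float)
        else:
            raise ConfigurationError(f"covariate {name!r} not found in covariate table")
    return pd.DataFrame(cols, index=covariates.index)


def _check_rank(design: pd.DataFrame) -> None:
    x = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        offending = []
        for j, name in enumerate(design.columns):
            reduced = np.delete(x, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offending.append(name)
        raise ConfigurationError(
            f"collinear covariate design; offending column(s): {offending or list(design.columns)}"
        )


def residualize(
    matrix: OmicsMatrix, covariates: pd.DataFrame, covariate_names
) -> tuple[OmicsMatrix, list[str]]:
    """OLS-residualize every feature column on an intercept + named covariates.

    Rows with missing covariate values are dropped (and reported).  Returns
    the residual matrix (same sample set minus dropped rows) and the list of
    dropped sample ids.
    """
    covariates = covariates.loc[matrix.data.index]
    design = design_columns(covariates, covariate_names)
    keep = ~design.isna().any(axis=1)
    dropped = list(design.index[~keep])
    design = design.loc[keep]
    y = matrix.data.loc[keep]
    _check_rank(design)

    x = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    q, _ = np.linalg.qr(x)
    values = y.to_numpy()
    if np.isnan(values).any():
        resid = np.empty_like(values)
        for j in range(values.shape[1]):
            col = values[:, j]
            ok = np.isfinite(col)
            qj, _ = np.linalg.qr(x[ok])
            r = np.full(col.shape, np.nan)
            r[ok] = col[ok] - qj @ (qj.T @ col[ok])
            resid[:, j] = r
    else:
        resid = values - q @ (q.T @ values)
    out = OmicsMatrix(pd.DataFrame(resid, index=y.index, columns=y.columns), "residual")
    return out, dropped


def residualize_with_snps(
    matrix: OmicsMatrix,
    covariates: pd.DataFrame,
    covariate_names,
    snp_selection: dict[str, list[str]],
    genotypes: pd.DataFrame,
) -> tuple[OmicsMatrix, list[str]]:
    """Residualize on shared covariates plus each feature's own cis-SNPs."""
    resid, dropped = residualize(matrix, covariates, covariate_names)
    active = {f: s for f, s in snp_selection.items() if s and f in resid.data.columns}
    if not active:
        return resid, dropped
    geno = genotypes.loc[resid.data.index]
    values = resid.data.to_numpy().copy()
    col_index = {c: i for i, c in enumerate(resid.data.columns)}
    for feature, snp_ids in active.items():
        g = geno[list(snp_ids)].to_numpy(float)
        x = np.column_stack([np.ones(len(g)), g])
        j = col_index[feature]
        col = values[:, j]
        ok = np.isfinite(col) & np.isfinite(g).all(axis=1)
        coef, *_ = np.linalg.lstsq(x[ok], col[ok], rcond=None)
        col[ok] = col[ok] - x[ok] @ coef
        values[:, j] = col
    return (
        OmicsMatrix(pd.DataFrame(values, index=resid.data.index, columns=resid.data.columns), "residual"),
        dropped,
    )


def select_cis_snps(
    features: OmicsMatrix,
    positions: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_positions: pd.DataFrame,
    window: int = 1_000_000,
    alpha: float = 1e-5,
    max_snps: int = 1,
) -> dict[str, list[str]]:
    """Choose up to ``max_snps`` cis-SNPs per feature by univariate OLS.

    ``positions`` has columns feature_id, chromosome, start, end (1-based
    inclusive; for a CpG start == end == position).  For each feature, every
    SNP within ``window`` of the interval is tested; the most significant is
    retained if p < ``alpha``, then selection proceeds greedily on the
    residuals.  Features with no qualifying SNP get an empty list.
    """
    pos = positions.set_index("feature_id")
    snps_by_chrom = {
        chrom: grp.sort_values("position")
        for chrom, grp in snp_positions.groupby(snp_positions["chromosome"].astype(str))
    }
    geno = genotypes.loc[features.data.index]
    selection: dict[str, list[str]] = {}
    for feature in features.data.columns:
        selection[feature] = []
        if feature not in pos.index:
            continue
        chrom = str(pos.loc[feature, "chromosome"])
        start = int(pos.loc[feature, "start"])
        end = int(pos.loc[feature, "end"])
        nearby = snps_by_chrom.get(chrom)
        if nearby is None:
            continue
        in_window = nearby[
            (nearby["position"] >= start - window) & (nearby["position"] <= end + window)
        ]["snp_id"].tolist()
        if not in_window:
            continue
        y = features.data[feature].to_numpy(float)
        for _ in range(max_snps):
            remaining = [s for s in in_window if s not in selection[feature]]
            if not remaining:
                break
            best, best_p, best_t = None, 1.0, 0.0
            for sid in remaining:
                g = geno[sid].to_numpy(float)
                ok = np.isfinite(y) & np.isfinite(g)
                if ok.sum() < 3 or g[ok].std() == 0:
                    continue
                slope, se, p, _ = _simple_ols(g[ok], y[ok])
                t = abs(slope / se) if se > 0 else np.inf
                if p < best_p or (p == best_p and t > best_t):
                    best, best_p, best_t = sid, p, t
            if best is None or best_p >= alpha:
                break
            selection[feature].append(best)
            g = geno[best].to_numpy(float)
            ok = np.isfinite(y) & np.isfinite(g)
            x = np.column_stack([np.ones(ok.sum()), g[ok]])
            coef, *_ = np.linalg.lstsq(x, y[ok], rcond=None)
            y = y.copy()
            y[ok] = y[ok] - x @ coef
    return selection


def _simple_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Slope, SE, two-sided p (t with n-2 df), n of y ~ intercept + x."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return np.nan, np.nan, np.nan, n
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        return slope, 0.0, _MIN_P, n
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return slope, se, max(p, _MIN_P), n


# ---------------------------------------------------------------------------
# mass-univariate scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """All pairwise regressions of one EWAS step.

    ``records`` holds the pairs significant at the threshold; the full
    slope/p matrices (CpGs x proteins) stay available for diagnostics such
    as per-protein inflation factors.
    """

    records: pd.DataFrame
    p_values: pd.DataFrame  # CpGs x proteins
    slopes: pd.DataFrame
    n_obs: pd.DataFrame
    threshold: float
    step_index: int
    cohort: str
    n_skipped: int

    def significant_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.records["cpg_id"], self.records["protein_id"]))

    def lookup(self, cpg_id: str, protein_id: str) -> tuple[float, float]:
        """(slope, p) for one pair, significant or not."""
        return (
            float(self.slopes.at[cpg_id, protein_id]),
            float(self.p_values.at[cpg_id, protein_id]),
        )


def ewas_scan(
    meth: OmicsMatrix,
    prot: OmicsMatrix,
    threshold: float,
    step_index: int = 0,
    cohort: str = "discovery",
) -> ScanResult:
    """Simple OLS of every CpG on every protein over pairwise-complete rows.

    The model is M ~ intercept + protein; two-sided p-values use the t
    distribution with n-2 degrees of freedom.  Pairs with fewer than three
    complete observations are skipped and counted.
    """
    if list(meth.data.index) != list(prot.data.index):
        raise ConfigurationError("methylation and protein matrices must share sample ids")
    m = meth.data.to_numpy()
    p_mat = prot.data.to_numpy()

    mv = np.isfinite(m)
    pv = np.isfinite(p_mat)
    m0 = np.where(mv, m, 0.0)
    p0 = np.where(pv, p_mat, 0.0)

    # pairwise-complete cross moments via indicator matmuls (proteins x CpGs)
    n = pv.T.astype(float) @ mv.astype(float)
    sp = p0.T @ mv
    sm = pv.T.astype(float) @ m0
    spp = (p0 * p0).T @ mv
    smm = pv.T.astype(float) @ (m0 * m0)
    spm = p0.T @ m0

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = spm - sp * sm / n
        var_p = spp - sp * sp / n
        var_m = smm - sm * sm / n
        slope = cov / var_p
        r2 = np.clip(cov * cov / (var_p * var_m), 0.0, 1.0)
        df = n - 2
        tstat = np.sqrt(df) * np.sqrt(r2 / np.clip(1.0 - r2, 1e-300, None))
        pval = 2.0 * stats.t.sf(tstat, np.maximum(df, 1))
        se = np.abs(slope) / np.clip(tstat, 1e-300, None)

    usable = (n >= 3) & (var_p > 0) & (var_m > 0)
    n_skipped = int((~usable).sum())
    pval = np.where(usable, np.clip(pval, _MIN_P, 1.0), np.nan)
    slope = np.where(usable, slope, np.nan)

    cpg_ids = meth.data.columns
    prot_ids = prot.data.columns
    p_df = pd.DataFrame(pval.T, index=cpg_ids, columns=prot_ids)
    slope_df = pd.DataFrame(slope.T, index=cpg_ids, columns=prot_ids)
    n_df = pd.DataFrame(n.T, index=cpg_ids, columns=prot_ids, dtype=int)

    hit_cpg, hit_prot = np.nonzero(p_df.to_numpy() < threshold)
    records = pd.DataFrame(
        {
            "cpg_id": cpg_ids[hit_cpg],
            "protein_id": prot_ids[hit_prot],
            "beta_hat": slope_df.to_numpy()[hit_cpg, hit_prot],
            "se": se.T[hit_cpg, hit_prot],
            "p": p_df.to_numpy()[hit_cpg, hit_prot],
            "n": n_df.to_numpy()[hit_cpg, hit_prot],
            "step_index": step_index,
            "cohort": cohort,
        }
    )
    return ScanResult(
        records=records,
        p_values=p_df,
        slopes=slope_df,
        n_obs=n_df,
        threshold=threshold,
        step_index=step_index,
        cohort=cohort,
        n_skipped=n_skipped,
    )


def bonferroni_threshold(alpha: float, counts) -> float:
    """alpha divided by the product of the test-multiplicity counts."""
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha must lie in (0, 1)")
    counts = list(counts)
    if any(c <= 0 for c in counts):
        raise ConfigurationError("counts must be positive")
    return float(alpha) / float(np.prod([float(c) for c in counts]))


# ---------------------------------------------------------------------------
# the step-wise procedure
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    steps: list[StepDefinition]
    scans: list[ScanResult]
    dropout_ledger: pd.DataFrame  # cpg_id, protein_id, attributed_driver, last_significant_step
    final_set: pd.DataFrame
    threshold: float
    cohort: str
    snp_selection_meth: dict[str, list[str]] = field(default_factory=dict)
    snp_selection_prot: dict[str, list[str]] = field(default_factory=dict)

    @property
    def significant_by_step(self) -> list[pd.DataFrame]:
        return [s.records for s in self.scans]

    def step0_pairs(self) -> set[tuple[str, str]]:
        return self.scans[0].significant_pairs()


def run_stepwise(
    meth: OmicsMatrix,
    prot: OmicsMatrix,
    covariates: pd.DataFrame,
    threshold: float,
    steps: list[StepDefinition] | None = None,
    genotypes: pd.DataFrame | None = None,
    snp_positions: pd.DataFrame | None = None,
    meth_positions: pd.DataFrame | None = None,
    prot_positions: pd.DataFrame | None = None,
    cis_window: int = 1_000_000,
    cis_alpha: float = 1e-5,
    cohort: str = "discovery",
    full_rescan: bool = False,
) -> StepwiseResult:
    """Run the full step-wise EWAS with driver attribution.

    Step 0 scans the transformed (non-residual) matrices.  Every later step
    residualizes both matrices on the cumulative covariate set and re-scans.
    The candidate universe of steps >= 1 is the step-0 significant set
    unless ``full_rescan`` is given.  A pair significant at step k-1 but not
    at k is attributed to the covariate added at step k; the final set
    contains the pairs significant at every step.
    """
    if steps is None:
        steps = default_steps()
    scan0 = ewas_scan(meth, prot, threshold, step_index=0, cohort=cohort)
    scans = [scan0]
    alive = scan0.significant_pairs()
    ledger_rows: list[tuple[str, str, str, int]] = []

    cumulative: list[str] = []
    extras_seen: list[str] = []
    snp_sel_meth: dict[str, list[str]] = {}
    snp_sel_prot: dict[str, list[str]] = {}
    snp_active = False

    for step in steps[1:]:
        cumulative.extend(n for n in step.covariates_added if n != "snp")
        extras_seen.extend(step.cohort_extras)
        names = cumulative + extras_seen

        if "snp" in step.covariates_added:
            snp_active = True
            if genotypes is not None and snp_positions is not None:
                base_meth, _ = residualize(meth, covariates, names)
                base_prot, _ = residualize(prot, covariates, names)
                if meth_positions is not None:
                    snp_sel_meth = select_cis_snps(
                        base_meth, meth_positions, genotypes, snp_positions,
                        window=cis_window, alpha=cis_alpha,
                    )
                if prot_positions is not None:
                    snp_sel_prot = select_cis_snps(
                        base_prot, prot_positions, genotypes, snp_positions,
                        window=cis_window, alpha=cis_alpha,
                    )

        if snp_active and genotypes is not None:
            meth_r, _ = residualize_with_snps(meth, covariates, names, snp_sel_meth, genotypes)
            prot_r, _ = residualize_with_snps(prot, covariates, names, snp_sel_prot, genotypes)
        else:
            meth_r, _ = residualize(meth, covariates, names)
            prot_r, _ = residualize(prot, covariates, names)

        scan = ewas_scan(meth_r, prot_r, threshold, step_index=step.index, cohort=cohort)
        scans.append(scan)
        sig_k = scan.significant_pairs()
        if not full_rescan:
            sig_k &= scans[0].significant_pairs()
        dropped = alive - sig_k
        for cpg_id, protein_id in sorted(dropped):
            ledger_rows.append((cpg_id, protein_id, step.name, step.index - 1))
        alive &= sig_k

    last = scans[-1]
    final_records = last.records[
        [
            (c, p) in alive
            for c, p in zip(last.records["cpg_id"], last.records["protein_id"])
        ]
    ].reset_index(drop=True)
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["cpg_id", "protein_id", "attributed_driver", "last_significant_step"],
    )
    return StepwiseResult(
        steps=steps,
        scans=scans,
        dropout_ledger=ledger,
        final_set=final_records,
        threshold=threshold,
        cohort=cohort,
        snp_selection_meth=snp_sel_meth,
        snp_selection_prot=snp_sel_prot,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median chi2_1 quantile of the observed
    p-values divided by the chi2_1 median (~0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise DomainError("cannot compute inflation of an empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def inflation_report(scan: ScanResult) -> pd.Series:
    """Per-protein genomic inflation of the CpG-wise p-value vectors."""
    return pd.Series(
        {prot: genomic_inflation(scan.p_values[prot].dropna()) for prot in scan.p_values.columns},
        name="lambda",
    )


def pc_confounder_check(
    meth_resid: OmicsMatrix,
    prot_resid: OmicsMatrix,
    n_pcs: int = 10,
    r2_limit: float = 0.015,
) -> pd.DataFrame:
    """Residual-confounder diagnostic via principal components.

    Computes the top ``n_pcs`` PCs of each residual matrix (features
    standardized, missing entries imputed with column means) and, for every
    PC, the maximum univariate OLS R^2 against each feature of the *other*
    data set.  PCs exceeding ``r2_limit`` (default 1.5%) are flagged as
    evidence of a remaining global driver.
    """

    def prepare(matrix: OmicsMatrix) -> np.ndarray:
        x = matrix.data.to_numpy().copy()
        mean = np.nanmean(x, axis=0)
        inds = np.where(np.isnan(x))
        x[inds] = np.take(mean, inds[1])
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        return x / sd

    def pcs(x: np.ndarray, k: int) -> np.ndarray:
        k = min(k, *x.shape)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        return u[:, :k] * s[:k]

    k = min(n_pcs, meth_resid.n_samples - 1, meth_resid.n_features, prot_resid.n_features)
    xm = prepare(meth_resid)
    xp = prepare(prot_resid)
    rows = []
    for label, scores, other, other_ids in [
        ("methylation", pcs(xm, k), xp, prot_resid.feature_ids),
        ("protein", pcs(xp, k), xm, meth_resid.feature_ids),
    ]:
        other_c = other - other.mean(axis=0)
        norms = np.linalg.norm(other_c, axis=0)
        norms[norms == 0] = 1.0
        for i in range(scores.shape[1]):
            s = scores[:, i] - scores[:, i].mean()
            s_norm = np.linalg.norm(s)
            if s_norm == 0:
                r2 = np.zeros(other_c.shape[1])
            else:
                r2 = (s @ other_c / (s_norm * norms)) ** 2
            j = int(np.argmax(r2))
            rows.append(
                {
                    "matrix": label,
                    "pc": i + 1,
                    "max_r2": float(r2[j]),
                    "top_feature": other_ids[j],
                    "flagged": bool(r2[j] > r2_limit),
                }
            )
    return pd.DataFrame(rows)


def joint_model_check(
    meth: OmicsMatrix,
    prot: OmicsMatrix,
    covariates: pd.DataFrame,
    pairs,
    covariate_names=None,
    stepwise_slopes: dict[tuple[str, str], float] | None = None,
    include_interactions: bool = False,
) -> pd.DataFrame:
    """Compare the step-wise estimate with a single joint regression.

    For each pair, fits M ~ protein + all covariates simultaneously and
    reports the protein slope, its p-value, and the absolute difference from
    the step-wise slope.  With ``include_interactions`` all pairwise
    products of the covariate columns are added, probing whether predictor
    interactions (which sequential residualization cannot capture) change
    the conclusion.
    """
    if covariate_names is None:
        covariate_names = [n for n in DEFAULT_STEP_ORDER if n != "snp"]
    design = design_columns(covariates.loc[meth.data.index], covariate_names)
    base = design.to_numpy(float)
    names = list(design.columns)
    if include_interactions:
        inter = []
        for i in range(base.shape[1]):
            for j in range(i + 1, base.shape[1]):
                inter.append(base[:, i] * base[:, j])
                names.append(f"{design.columns[i]}*{design.columns[j]}")
        if inter:
            base = np.column_stack([base] + inter)
    rows = []
    for cpg_id, protein_id in pairs:
        y = meth.data[cpg_id].to_numpy(float)
        xp = prot.data[protein_id].to_numpy(float)
        x = sm.add_constant(np.column_stack([xp, base]))
        ok = np.isfinite(y) & np.isfinite(x).all(axis=1)
        model = sm.OLS(y[ok], x[ok])
        if np.linalg.matrix_rank(x[ok]) < x.shape[1]:
            raise ConfigurationError(f"rank-deficient joint design for pair ({cpg_id}, {protein_id})")
        fit = model.fit()
        slope = float(fit.params[1])
        pval = float(fit.pvalues[1])
        ref = None if stepwise_slopes is None else stepwise_slopes.get((cpg_id, protein_id))
        rows.append(
            {
                "cpg_id": cpg_id,
                "protein_id": protein_id,
                "joint_slope": slope,
                "joint_p": pval,
                "stepwise_slope": ref,
                "abs_slope_diff": None if ref is None else abs(slope - ref),
            }
        )
    return pd.DataFrame(rows)
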
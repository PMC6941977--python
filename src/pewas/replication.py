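"""Two-cohort replication: per-step Bonferroni thresholds, directionality,
and sampling-based replication power.

A discovery association is *replicated* when its p-value in the replication
cohort passes 0.05/N, with N the number of associations identified at the
same discovery step (N stays fixed even when some pairs cannot be tested in
the replication data).  Directionality consistency is reported among the
nominally significant replication results, and replication power is
estimated by sampling the discovery effect from its estimation distribution
and propagating it through a noncentral-t tail at the replication sample
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError
from .stepwise import ScanResult


@dataclass
class ReplicationResult:
    """Per-pair replication outcomes for one discovery step."""

    table: pd.DataFrame
    threshold: float
    n_discovery: int
    nominal_alpha: float = 0.05

    def summary(self) -> dict:
        t = self.table
        return {
            "n_discovery": self.n_discovery,
            "threshold": self.threshold,
            "n_tested": int(t["tested"].sum()),
            "n_replicated": int(t["replicated"].sum()),
            "n_sign_consistent": int((t["replicated"] & t["sign_consistent"]).sum()),
        }


def replicate_step(
    discovery_records: pd.DataFrame,
    replication_scan: ScanResult,
    alpha: float = 0.05,
    nominal_alpha: float = 0.05,
    threshold: float | None = None,
) -> ReplicationResult:
    """Test exactly the discovery pairs in the replication scan.

    The replication threshold is ``alpha / N`` with N the discovery count at
    this step (or an explicit ``threshold`` override).  Pairs whose features
    are absent from the replication data are marked untestable and count as
    non-replicated (N is not reduced).
    """
    n_discovery = len(discovery_records)
    if n_discovery == 0:
        return ReplicationResult(
            table=pd.DataFrame(
                columns=[
                    "cpg_id", "protein_id", "disc_beta", "disc_p",
                    "rep_beta", "rep_p", "tested", "replicated",
                    "sign_consistent", "reason",
                ]
            ),
            threshold=np.nan,
            n_discovery=0,
            nominal_alpha=nominal_alpha,
        )
    if threshold is None:
        threshold = alpha / n_discovery
    rep_cpgs = set(replication_scan.p_values.index)
    rep_prots = set(replication_scan.p_values.columns)
    rows = []
    for rec in discovery_records.itertuples():
        testable = rec.cpg_id in rep_cpgs and rec.protein_id in rep_prots
        if testable:
            rep_beta, rep_p = replication_scan.lookup(rec.cpg_id, rec.protein_id)
            testable = np.isfinite(rep_p)
        if testable:
            replicated = rep_p < threshold
            sign_consistent = np.sign(rep_beta) == np.sign(rec.beta_hat)
            reason = ""
        else:
            rep_beta, rep_p = np.nan, np.nan
            replicated, sign_consistent = False, False
            reason = "feature absent from replication data"
        rows.append(
            {
                "cpg_id": rec.cpg_id,
                "protein_id": rec.protein_id,
                "disc_beta": rec.beta_hat,
                "disc_p": rec.p,
                "rep_beta": rep_beta,
                "rep_p": rep_p,
                "tested": testable,
                "replicated": bool(replicated),
                "sign_consistent": bool(sign_consistent),
                "reason": reason,
            }
        )
    return ReplicationResult(
        table=pd.DataFrame(rows),
        threshold=threshold,
        n_discovery=n_discovery,
        nominal_alpha=nominal_alpha,
    )


def directionality_consistency(
    result: ReplicationResult, nominal_alpha: float = 0.05
) -> float | None:
    """Among nominally significant replication results, the fraction whose
    slope sign agrees with discovery.  None when no pair is nominally
    significant."""
    t = result.table
    nominal = t[t["tested"] & (t["rep_p"] < nominal_alpha)]
    if nominal.empty:
        return None
    return float(nominal["sign_consistent"].mean())


def replication_power(
    beta_hat: float,
    se: float,
    n_discovery: int,
    n_replication: int,
    threshold: float,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, bool]:
    """Sampling-based replication power for one discovery association.

    Draws the unknown true effect from Normal(beta_hat, se^2), rescales the
    standard error to the replication sample size (se * sqrt(n_disc/n_rep))
    and evaluates the two-sided rejection probability at ``threshold`` via
    the noncentral-t tail with n_replication - 2 degrees of freedom.  The
    power is the mean over draws; the flag marks power >= 0.95.
    """
    if n_replication < 3:
        raise ConfigurationError("n_replication must be at least 3")
    if se <= 0:
        raise ConfigurationError("se must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.normal(beta_hat, se, size=n_draws)
    se_rep = se * np.sqrt(n_discovery / n_replication)
    df = n_replication - 2
    t_crit = stats.t.isf(threshold / 2.0, df)
    # two-sided power is symmetric in the noncentrality; the opposite-tail
    # term underflows in scipy for large |ncp| and is then negligibly small
    ncp = np.abs(draws) / se_rep
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    reject = np.nan_to_num(upper, nan=1.0) + np.nan_to_num(lower, nan=0.0)
    power = float(np.mean(np.clip(reject, 0.0, 1.0)))
    return power, power >= 0.95


def add_power_flags(
    result: ReplicationResult,
    n_discovery_samples: int,
    n_replication_samples: int,
    discovery_records: pd.DataFrame,
    n_draws: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotate a replication table with per-pair power and powered_95."""
    rng = np.random.default_rng(seed)
    se_map = {
        (r.cpg_id, r.protein_id): r.se for r in discovery_records.itertuples()
    }
    powers, flags = [], []
    for rec in result.table.itertuples():
        se = se_map.get((rec.cpg_id, rec.protein_id))
        if se is None or not np.isfinite(se) or se <= 0:
            powers.append(np.nan)
            flags.append(False)
            continue
        power, ok = replication_power(
            rec.disc_beta,
            se,
            n_discovery_samples,
            n_replication_samples,
            result.threshold,
            n_draws=n_draws,
            seed=rng,
        )
        powers.append(power)
        flags.append(ok)
    out = result.table.copy()
    out["power"] = powers
    out["powered_95"] = flags
    return out
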
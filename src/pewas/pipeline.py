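"""Orchestration: configuration, stage sequencing, logging, run report.

``run_pipeline`` drives the full experiment on a synthetic two-cohort
design: simulate -> preprocess -> step-wise EWAS (discovery) -> step-wise
EWAS (replication) -> per-step replication -> pQTM post-processing ->
downstream phenotype/metabolite associations.  Every stage writes its
outputs as TSV under the configured output directory and contributes row
counts, thresholds and timings to a JSON run report, so a run is fully
self-describing and reproducible from its config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .containers import ConfigurationError, OmicsMatrix
from .downstream import (
    joint_variance_explained,
    metabolite_association,
    phenotype_association,
)
from .postprocess import (
    annotation_enrichment,
    classify_cis_trans,
    cross_reactivity_filter,
    eqtm_overlap,
    group_signals,
    hic_contact_enrichment,
)
from .preprocess import (
    beta_to_m,
    estimate_cell_fractions,
    log_scale_proteins,
    qc_filter_probes,
    standardize,
    winsorize,
)
from .replication import add_power_flags, directionality_consistency, replicate_step
from .simulate import CohortBundle, SimulationConfig, read_bundle, simulate_cohort, write_bundle
from .stepwise import (
    StepwiseResult,
    bonferroni_threshold,
    default_steps,
    inflation_report,
    pc_confounder_check,
    residualize,
    run_stepwise,
)

logger = logging.getLogger("pewas")

PHENOTYPES_TESTED = [
    "hypertension",
    "myocardial_infarction",
    "type2_diabetes",
    "metabolic_syndrome",
    "bmi",
    "alcohol_g_per_day",
    "total_cholesterol",
    "hdl",
    "ldl",
    "triglycerides",
]


@dataclass
class PipelineConfig:
    """Flat, human-editable configuration of one pipeline run."""

    outdir: str = "pewas_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    winsor_lower: float = 0.05
    winsor_upper: float = 0.95
    cis_window: int = 1_000_000
    cis_alpha: float = 1e-5
    hic_bin_size: int = 1000
    n_hic_random: int = 200
    nominal_alpha: float = 0.05
    n_power_draws: int = 1000
    enrichment_categories: tuple[str, ...] = (
        "enhancer",
        "dhs",
        "dmr",
        "cdmr",
        "promoter",
        "promoter_cell_specific",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enrichment_categories"] = list(self.enrichment_categories)
        d["simulation"]["planted_effects"] = [
            asdict(e) if not isinstance(e, dict) else e
            for e in d["simulation"]["planted_effects"]
        ]
        return d


@dataclass
class Processed:
    meth: OmicsMatrix  # standardized M-values, QC-passing probes
    prot: OmicsMatrix  # standardized log-proteins
    covariates: pd.DataFrame  # incl. estimated cell_frac_* columns
    qc_ledger: dict


def preprocess_bundle(
    bundle: CohortBundle, winsor_lower: float = 0.05, winsor_upper: float = 0.95
) -> Processed:
    """QC-filter probes, estimate cell fractions, and transform both omics.

    Methylation: beta -> M -> winsorize -> z-score.  Proteins: log ->
    winsorize -> z-score.  Estimated cell fractions join the covariate
    table as ``cell_frac_*`` columns.
    """
    qc = qc_filter_probes(bundle.manifest)
    retained = [p for p in qc.retained if p in bundle.methylation.data.columns]
    beta = bundle.methylation.subset_features(retained)
    fractions = estimate_cell_fractions(beta, bundle.cell_reference)
    covariates = bundle.covariates.copy()
    for k, cell in enumerate(fractions.columns):
        covariates[f"cell_frac_{cell}"] = fractions[cell]
    meth = standardize(winsorize(beta_to_m(beta), winsor_lower, winsor_upper))
    prot = standardize(winsorize(log_scale_proteins(bundle.proteins), winsor_lower, winsor_upper))
    return Processed(meth=meth, prot=prot, covariates=covariates, qc_ledger=qc.ledger)


def feature_positions_from_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": manifest["probe_id"],
            "chromosome": manifest["chromosome"].astype(str),
            "start": manifest["position"],
            "end": manifest["position"],
        }
    )


def feature_positions_from_aptamers(aptamers: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": aptamers["protein_id"],
            "chromosome": aptamers["chromosome"].astype(str),
            "start": aptamers["gene_start"],
            "end": aptamers["gene_end"],
        }
    )


def run_cohort_stepwise(
    bundle: CohortBundle,
    processed: Processed,
    config: PipelineConfig,
    threshold: float,
) -> StepwiseResult:
    """Step-wise EWAS for one cohort; replication cohorts with genetic and
    proteomic PC covariates apply them at the sex step."""
    extras = tuple(
        c
        for c in ("geno_pc1", "geno_pc2", "geno_pc3", "proteo_pc1", "proteo_pc2", "proteo_pc3")
        if c in processed.covariates.columns
    )
    steps = default_steps(cohort_extras=extras)
    return run_stepwise(
        processed.meth,
        processed.prot,
        processed.covariates,
        threshold=threshold,
        steps=steps,
        genotypes=bundle.genotypes,
        snp_positions=bundle.snp_positions,
        meth_positions=feature_positions_from_manifest(bundle.manifest),
        prot_positions=feature_positions_from_aptamers(bundle.aptamers),
        cis_window=config.cis_window,
        cis_alpha=config.cis_alpha,
        cohort=bundle.label,
    )


def _annotate_pairs(records: pd.DataFrame, bundle: CohortBundle) -> pd.DataFrame:
    cpg_coords = bundle.manifest.set_index("probe_id")[["chromosome", "position"]]
    apt = bundle.aptamers.set_index("protein_id")
    out = records.copy()
    out["cpg_chr"] = [cpg_coords.loc[c, "chromosome"] for c in out["cpg_id"]]
    out["cpg_pos"] = [int(cpg_coords.loc[c, "position"]) for c in out["cpg_id"]]
    out["protein_gene"] = [apt.loc[p, "gene"] for p in out["protein_id"]]
    out["protein_chr"] = [apt.loc[p, "chromosome"] for p in out["protein_id"]]
    out["gene_start"] = [int(apt.loc[p, "gene_start"]) for p in out["protein_id"]]
    out["gene_end"] = [int(apt.loc[p, "gene_end"]) for p in out["protein_id"]]
    return out


def run_pipeline(config: PipelineConfig, bundles: dict[str, CohortBundle] | None = None) -> dict:
    """Execute the full pipeline; returns the run report (also written as
    ``run_report.json`` in the output directory).

    ``bundles`` may carry pre-built discovery/replication cohorts; by
    default both are simulated from ``config.simulation``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    report: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    try:
        # ------------------------------------------------------------ simulate
        t0 = stage("simulate")
        if bundles is None:
            bundles = {
                label: simulate_cohort(config.simulation, label)
                for label in ("discovery", "replication")
            }
        for label, bundle in bundles.items():
            write_bundle(bundle, outdir / label)
        report["stages"]["simulate"] = {
            "n_samples": {k: len(v.sample_ids) for k, v in bundles.items()},
            "n_cpgs": bundles["discovery"].methylation.n_features,
            "n_proteins": bundles["discovery"].proteins.n_features,
            "seconds": round(time.time() - t0, 2),
        }

        # ---------------------------------------------------------- preprocess
        t0 = stage("preprocess")
        processed = {
            label: preprocess_bundle(bundle, config.winsor_lower, config.winsor_upper)
            for label, bundle in bundles.items()
        }
        for label, proc in processed.items():
            pio.write_matrix(proc.meth, outdir / f"{label}_methylation_std.tsv")
            pio.write_matrix(proc.prot, outdir / f"{label}_proteins_std.tsv")
            cov = proc.covariates.copy()
            cov.index.name = pio.SAMPLE_COLUMN
            cov.to_csv(outdir / f"{label}_covariates.tsv", sep="\t", float_format=pio.FLOAT_FORMAT)
        report["stages"]["preprocess"] = {
            "qc_ledger": processed["discovery"].qc_ledger,
            "n_probes_retained": processed["discovery"].meth.n_features,
            "seconds": round(time.time() - t0, 2),
        }

        # ------------------------------------------------------------- stepwise
        t0 = stage("ewas")
        disc = processed["discovery"]
        threshold = bonferroni_threshold(
            config.alpha, [disc.meth.n_features, disc.prot.n_features]
        )
        results = {
            label: run_cohort_stepwise(bundles[label], processed[label], config, threshold)
            for label in ("discovery", "replication")
        }
        for label, res in results.items():
            all_records = pd.concat([s.records for s in res.scans], ignore_index=True)
            pio.write_table(all_records, outdir / f"{label}_associations.tsv")
            pio.write_table(res.dropout_ledger, outdir / f"{label}_dropout_ledger.tsv")
            pio.write_table(res.final_set, outdir / f"{label}_final_set.tsv")
        disc_res = results["discovery"]
        lambda_final = inflation_report(disc_res.scans[-1])
        lambda_final.rename_axis("protein_id").reset_index().to_csv(
            outdir / "inflation_lambda.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT
        )
        report["stages"]["ewas"] = {
            "threshold": threshold,
            "per_step_significant": {
                label: [len(s.records) for s in res.scans] for label, res in results.items()
            },
            "n_final": {label: len(res.final_set) for label, res in results.items()},
            "seconds": round(time.time() - t0, 2),
        }

        # residual-confounder PC diagnostic on the final residuals
        t0 = stage("pc_check")
        names = ["sex", "cell", "age", "smoking", "bmi", "diabetes"]
        meth_r, _ = residualize(disc.meth, disc.covariates, names)
        prot_r, _ = residualize(disc.prot, disc.covariates, names)
        pc_check = pc_confounder_check(meth_r, prot_r)
        pio.write_table(pc_check, outdir / "pc_confounder_check.tsv")
        report["stages"]["pc_check"] = {
            "n_flagged": int(pc_check["flagged"].sum()),
            "max_r2": float(pc_check["max_r2"].max()),
            "seconds": round(time.time() - t0, 2),
        }

        # ------------------------------------------------------------ replicate
        t0 = stage("replicate")
        rep_res = results["replication"]
        per_step = []
        for k, disc_scan in enumerate(disc_res.scans):
            rep = replicate_step(
                disc_scan.records, rep_res.scans[k], alpha=config.alpha,
                nominal_alpha=config.nominal_alpha,
            )
            consistency = directionality_consistency(rep, config.nominal_alpha)
            per_step.append(
                {
                    "step": k,
                    **rep.summary(),
                    "directionality_consistency": consistency,
                }
            )
        # final step uses the surviving (never-dropped) set
        final_rep = replicate_step(
            disc_res.final_set, rep_res.scans[-1], alpha=config.alpha,
            nominal_alpha=config.nominal_alpha,
        )
        n_disc = len(bundles["discovery"].sample_ids)
        n_rep = len(bundles["replication"].sample_ids)
        if not final_rep.table.empty:
            final_table = add_power_flags(
                final_rep,
                n_disc,
                n_rep,
                disc_res.final_set,
                n_draws=config.n_power_draws,
                seed=config.seed + 101,
            )
        else:
            final_table = final_rep.table
        pio.write_table(final_table, outdir / "replication_final.tsv")
        pio.write_table(pd.DataFrame(per_step), outdir / "replication_by_step.tsv")
        report["stages"]["replicate"] = {
            "per_step": per_step,
            "n_final_replicated": int(final_rep.table["replicated"].sum())
            if not final_rep.table.empty
            else 0,
            "seconds": round(time.time() - t0, 2),
        }

        # ----------------------------------------------------------- postprocess
        t0 = stage("postprocess")
        bundle = bundles["discovery"]
        if final_rep.table.empty:
            pqtms = pd.DataFrame(
                columns=["cpg_id", "protein_id", "beta_hat", "se", "p", "n"]
            )
        else:
            replicated = final_rep.table[final_rep.table["replicated"]]
            pqtms = disc_res.final_set.merge(
                replicated[["cpg_id", "protein_id"]], on=["cpg_id", "protein_id"]
            )
        post_report: dict = {"n_pqtms": len(pqtms)}
        if not pqtms.empty:
            pqtms = _annotate_pairs(pqtms, bundle)
            pqtms["cis"] = classify_cis_trans(pqtms, window=config.cis_window)
            groups = group_signals(pqtms)
            pqtms["group_label"] = groups.labels
            pqtms, cross_summary = cross_reactivity_filter(
                pqtms, bundle.cross_reactive_cpgs, bundle.cross_reactive_aptamers
            )
            enrichment = annotation_enrichment(
                set(pqtms["cpg_id"]), bundle.manifest, config.enrichment_categories
            )
            pio.write_table(enrichment, outdir / "annotation_enrichment.tsv")
            hic = hic_contact_enrichment(
                pqtms, bundle.hic, n_random=config.n_hic_random,
                seed=config.seed + 202, bin_size=config.hic_bin_size,
            )
            overlap = eqtm_overlap(pqtms, bundle.eqtm_table)
            pio.write_table(overlap, outdir / "eqtm_overlap.tsv")
            post_report.update(
                {
                    "n_cis": int(pqtms["cis"].fillna(False).sum()),
                    "n_signals": groups.n_components,
                    "cross_reactivity": cross_summary,
                    "hic_fold": hic.fold,
                    "hic_p": hic.p,
                    "n_eqtm_overlap": len(overlap),
                }
            )
        pio.write_table(pqtms, outdir / "pqtms.tsv")
        post_report["seconds"] = round(time.time() - t0, 2)
        report["stages"]["postprocess"] = post_report

        # ------------------------------------------------------------ downstream
        t0 = stage("downstream")
        down_report: dict = {}
        if not pqtms.empty:
            cpg_ids = sorted(set(pqtms["cpg_id"]))
            prot_ids = sorted(set(pqtms["protein_id"]))
            pheno = bundle.phenotypes
            cpg_assoc, cpg_thr = phenotype_association(
                disc.meth.subset_features(cpg_ids), pheno, disc.covariates,
                phenotype_names=PHENOTYPES_TESTED, alpha=config.alpha,
            )
            prot_assoc, prot_thr = phenotype_association(
                disc.prot.subset_features(prot_ids), pheno, disc.covariates,
                phenotype_names=PHENOTYPES_TESTED, alpha=config.alpha,
            )
            pio.write_table(cpg_assoc, outdir / "cpg_phenotype_assoc.tsv")
            pio.write_table(prot_assoc, outdir / "protein_phenotype_assoc.tsv")
            down_report["cpg_phenotype_threshold"] = cpg_thr
            down_report["protein_phenotype_threshold"] = prot_thr
            if bundle.metabolites is not None:
                met_assoc, met_thr = metabolite_association(
                    disc.meth.subset_features(cpg_ids), bundle.metabolites,
                    disc.covariates, alpha=config.alpha,
                )
                pio.write_table(met_assoc, outdir / "cpg_metabolite_assoc.tsv")
                down_report["metabolite_threshold"] = met_thr
                down_report["n_metabolite_assoc"] = int(
                    (met_assoc["p"] < met_thr).sum()
                ) if not met_assoc.empty else 0
            rows = []
            for prot_id in prot_ids:
                linked = sorted(set(pqtms.loc[pqtms["protein_id"] == prot_id, "cpg_id"]))
                r2, adj = joint_variance_explained(
                    disc.meth, linked, disc.prot.data[prot_id]
                )
                rows.append(
                    {"protein_id": prot_id, "n_cpgs": len(linked), "r2": r2, "adj_r2": adj}
                )
            pio.write_table(pd.DataFrame(rows), outdir / "joint_variance_explained.tsv")
        down_report["seconds"] = round(time.time() - t0, 2)
        report["stages"]["downstream"] = down_report

        report["status"] = "ok"
    except Exception as exc:  # pragma: no cover - exercised via error tests
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "FAILED").write_text(report["error"] + "\n")
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
        logger.removeHandler(handler)
        raise
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    logger.removeHandler(handler)
    return report
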
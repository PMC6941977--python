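"""Synthetic paired methylation/proteomics cohorts with planted ground truth.

The generator emulates the design of a two-cohort protein EWAS: a discovery
cohort and a smaller, optionally multi-ethnic replication cohort share the
same planted CpG-protein effects but redraw all samples.  Each planted pair
is tagged with the *driver* of its association:

``direct``
    a shared latent couples the CpG and the protein with no covariate cause;
``sex, age, smoking, bmi, diabetes``
    the covariate is a common cause of both the CpG M-value and the
    log-protein (no direct edge);
``cell``
    both sides load on a sampled white-blood-cell fraction;
``snp``
    both sides load on the dosage of a biallelic SNP placed within 1 Mb of
    the CpG;
``global_pc``
    a cohort-wide latent factor shared by all such pairs;
``null``
    no effect (effect size must be 0).

``effect_size`` is the correlation induced between the pair: each side loads
on the shared driver with correlation sqrt(|effect|), the sign is carried by
the protein side, so the marginal CpG-protein correlation equals the stated
effect.  Methylation is simulated on the M scale (where the EWAS regression
is linear) and mapped to beta-values through the inverse of
M = log2(b/(1-b)); marker CpGs are instead produced by mixing reference
cell-type profiles with per-sample Dirichlet cell fractions, which makes the
composition identifiable for reference-based deconvolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .containers import CellReference, ConfigurationError, OmicsMatrix

DRIVERS = (
    "direct",
    "sex",
    "cell",
    "snp",
    "age",
    "smoking",
    "bmi",
    "diabetes",
    "global_pc",
    "null",
)

COHORT_LABELS = ("discovery", "replication")

# Baseline leukocyte composition used for the Dirichlet cell-fraction draw
# (granulocytes dominate whole blood; remaining mass is spread over
# lymphocyte subsets and monocytes).
_BASE_FRACTIONS = np.array([0.55, 0.15, 0.10, 0.08, 0.07, 0.05])
_DIRICHLET_CONCENTRATION = 60.0


def cpg_name(i: int) -> str:
    return f"cg{i:07d}"


def protein_name(j: int) -> str:
    return f"seq_{j:04d}"


def gene_name(j: int) -> str:
    return f"GENE{j:04d}"


@dataclass(frozen=True)
class PlantedEffect:
    """One planted CpG-protein pair with its driving factor."""

    cpg_id: str
    protein_id: str
    driver: str
    effect_size: float
    driver_detail: str | None = None  # e.g. cell-type name or SNP id

    def __post_init__(self) -> None:
        if self.driver not in DRIVERS:
            raise ConfigurationError(f"unknown driver {self.driver!r}")
        if self.driver == "null" and self.effect_size != 0.0:
            raise ConfigurationError("driver='null' requires effect_size == 0")


def default_planted_effects(
    n_cpgs: int,
    n_proteins: int,
    marker_block: int,
    per_driver: int = 6,
    n_null: int = 4,
) -> list[PlantedEffect]:
    """Default palette of planted effects: ``per_driver`` pairs for each of
    the seven covariate drivers plus direct pairs, with pair correlations
    cycling over {0.4, 0.5, 0.6} and alternating sign, followed by a few
    explicit null pairs.  CpG indices start after the cell-type marker block
    so markers stay purely composition-driven."""
    drivers = ["direct", "sex", "cell", "snp", "age", "smoking", "bmi", "diabetes"]
    magnitudes = [0.5, 0.4, 0.6]
    effects: list[PlantedEffect] = []
    k = 0
    for driver in drivers:
        for _ in range(per_driver):
            cpg_i = marker_block + k
            prot_j = k % n_proteins
            if cpg_i >= n_cpgs:
                raise ConfigurationError("not enough CpGs for the default planted effects")
            size = magnitudes[k % len(magnitudes)] * (1 if k % 2 == 0 else -1)
            effects.append(
                PlantedEffect(cpg_name(cpg_i), protein_name(prot_j), driver, size)
            )
            k += 1
    for _ in range(n_null):
        effects.append(
            PlantedEffect(cpg_name(marker_block + k), protein_name(k % n_proteins), "null", 0.0)
        )
        k += 1
    return effects


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic two-cohort experiment."""

    n_samples: int = 500
    n_cpgs: int = 2000
    n_proteins: int = 200
    n_cell_types: int = 6
    n_marker_cpgs_per_cell: int = 10
    planted_effects: list[PlantedEffect] | None = None
    covariate_model: dict[str, float] = field(default_factory=dict)
    noise_sd_methylation: float = 0.3
    noise_sd_protein: float = 0.3
    maf_range: tuple[float, float] = (0.1, 0.4)
    replication_fraction: float = 344.0 / 944.0
    ethnicity_pc_sd: float = 1.0
    n_metabolites: int = 40
    hic_base_rate: float = 0.15
    hic_fold: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_samples,
            self.n_cpgs,
            self.n_proteins,
            self.n_cell_types,
            self.n_marker_cpgs_per_cell,
        ]
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all counts must be positive")
        if self.marker_block > self.n_cpgs:
            raise ConfigurationError(
                "n_marker_cpgs_per_cell * n_cell_types must not exceed n_cpgs"
            )
        if not (0.0 < self.maf_range[0] < self.maf_range[1] < 0.5):
            raise ConfigurationError("maf_range must be an interval inside (0, 0.5)")
        if not (0.0 < self.replication_fraction <= 1.0):
            raise ConfigurationError("replication_fraction must be in (0, 1]")
        if self.noise_sd_methylation <= 0 or self.noise_sd_protein <= 0:
            raise ConfigurationError("noise SDs must be positive")
        if self.ethnicity_pc_sd < 0:
            raise ConfigurationError("ethnicity_pc_sd must be non-negative")
        if self.planted_effects is None:
            self.planted_effects = default_planted_effects(
                self.n_cpgs, self.n_proteins, self.marker_block
            )
        self.planted_effects = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
            for e in self.planted_effects
        ]
        if isinstance(self.maf_range, list):
            self.maf_range = tuple(self.maf_range)
        cpg_ids = {cpg_name(i) for i in range(self.n_cpgs)}
        prot_ids = {protein_name(j) for j in range(self.n_proteins)}
        for eff in self.planted_effects:
            if eff.cpg_id not in cpg_ids or eff.protein_id not in prot_ids:
                raise ConfigurationError(
                    f"planted effect references unknown feature: {eff.cpg_id}/{eff.protein_id}"
                )

    @property
    def marker_block(self) -> int:
        return self.n_cell_types * self.n_marker_cpgs_per_cell

    def scaled_effect(self, effect: PlantedEffect) -> float:
        return effect.effect_size * self.covariate_model.get(effect.driver, 1.0)


@dataclass
class GroundTruth:
    effects: list[PlantedEffect]
    cell_fractions: pd.DataFrame  # samples x cell types, simplex rows
    reference: CellReference

    def __post_init__(self) -> None:
        sums = self.cell_fractions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ConfigurationError("cell fraction rows must sum to 1")
        if (self.cell_fractions.to_numpy() < 0).any():
            raise ConfigurationError("cell fractions must be non-negative")


@dataclass
class CohortBundle:
    """Everything one cohort contributes to the pipeline, plus ground truth."""

    label: str
    methylation: OmicsMatrix  # beta scale
    proteins: OmicsMatrix  # raw positive intensities
    manifest: pd.DataFrame
    aptamers: pd.DataFrame  # protein_id, gene, chromosome, gene_start, gene_end
    covariates: pd.DataFrame
    genotypes: pd.DataFrame  # samples x SNPs, dosages in [0, 2]
    snp_positions: pd.DataFrame  # snp_id, chromosome, position
    phenotypes: pd.DataFrame
    metabolites: OmicsMatrix | None  # log scale; None when no metabolites
    hic: pd.DataFrame  # chrom_a, bin_a_start, chrom_b, bin_b_start, contact_value
    eqtm_table: pd.DataFrame  # cpg_id, transcript, gene, eqtm_p, eqtm_beta
    cross_reactive_cpgs: list[str]
    cross_reactive_aptamers: list[str]
    cell_reference: CellReference
    truth: GroundTruth

    def __post_init__(self) -> None:
        ids = list(self.methylation.data.index)
        for name, table in [
            ("proteins", self.proteins.data),
            ("covariates", self.covariates),
            ("genotypes", self.genotypes),
            ("phenotypes", self.phenotypes),
            ("cell_fractions", self.truth.cell_fractions),
        ]:
            if list(table.index) != ids:
                raise ConfigurationError(f"sample ids of {name} differ from methylation")
        if self.metabolites is not None and list(self.metabolites.data.index) != ids:
            raise ConfigurationError("sample ids of metabolites differ from methylation")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.methylation.data.index)


def _standardized(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _structures(config: SimulationConfig):
    """Cohort-invariant structures: manifest, annotations, reference, SNPs.

    Drawn from the master seed only, so discovery and replication share the
    same array design, protein annotation, reference profiles, and SNP map.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 990001]))
    n_cpgs, n_prot = config.n_cpgs, config.n_proteins

    # --- probe manifest -------------------------------------------------
    idx = np.arange(n_cpgs)
    chrom = ((idx % 22) + 1).astype(str)
    position = 200_000 + (idx // 22) * 75_000
    ucsc_pool = ["TSS200", "TSS1500", "5'UTR", "Body", "3'UTR", ""]
    island_pool = [
        "island",
        "north_shore",
        "south_shore",
        "north_shelf",
        "south_shelf",
        "open_sea",
    ]
    reg_pool = ["promoter", "gene", "non_gene", "unclassified", "none"]
    manifest = pd.DataFrame(
        {
            "probe_id": [cpg_name(i) for i in idx],
            "probe_class": "cg",
            "targets_snp": False,
            "chromosome": chrom,
            "position": position,
            "n_measured": config.n_samples,
            "ucsc_region": rng.choice(ucsc_pool, size=n_cpgs, p=[0.1, 0.1, 0.1, 0.4, 0.1, 0.2]),
            "island_relation": rng.choice(
                island_pool, size=n_cpgs, p=[0.3, 0.1, 0.1, 0.05, 0.05, 0.4]
            ),
            "regulatory_feature": rng.choice(
                reg_pool, size=n_cpgs, p=[0.15, 0.2, 0.1, 0.05, 0.5]
            ),
            "cell_type_specific": rng.random(n_cpgs) < 0.05,
            "enhancer": rng.random(n_cpgs) < 0.12,
            "dhs": rng.random(n_cpgs) < 0.15,
            "dmr": rng.random(n_cpgs) < 0.05,
            "cdmr": rng.random(n_cpgs) < 0.03,
        }
    )

    # --- aptamer annotation ---------------------------------------------
    gene_chrom = rng.integers(1, 23, size=n_prot).astype(str)
    gene_start = rng.integers(1_000_000, 50_000_000, size=n_prot)
    gene_len = rng.integers(5_000, 100_000, size=n_prot)
    aptamers = pd.DataFrame(
        {
            "protein_id": [protein_name(j) for j in range(n_prot)],
            "gene": [gene_name(j) for j in range(n_prot)],
            "chromosome": gene_chrom,
            "gene_start": gene_start,
            "gene_end": gene_start + gene_len,
        }
    )

    # --- cell reference profiles ----------------------------------------
    cell_types = [f"cell_type_{k}" for k in range(config.n_cell_types)]
    marker_ids = [cpg_name(i) for i in range(config.marker_block)]
    profile = rng.uniform(0.05, 0.25, size=(config.n_cell_types, config.marker_block))
    for k in range(config.n_cell_types):
        own = slice(
            k * config.n_marker_cpgs_per_cell, (k + 1) * config.n_marker_cpgs_per_cell
        )
        profile[k, own] = rng.uniform(0.75, 0.95, size=config.n_marker_cpgs_per_cell)
    reference = CellReference(
        cell_types, marker_ids, pd.DataFrame(profile, index=cell_types, columns=marker_ids)
    )

    # --- planted-effect plumbing: cell types, SNPs, latents ---------------
    effects: list[PlantedEffect] = []
    cell_cursor = 0
    snp_rows = []
    snp_mafs = {}
    snp_cursor = 0
    cpg_pos = manifest.set_index("probe_id")[["chromosome", "position"]]
    for eff in config.planted_effects:
        detail = eff.driver_detail
        if eff.driver == "cell" and detail is None:
            detail = cell_types[cell_cursor % config.n_cell_types]
            cell_cursor += 1
        if eff.driver == "snp" and detail is None:
            detail = f"snp_{snp_cursor:04d}"
            chrom_c = cpg_pos.loc[eff.cpg_id, "chromosome"]
            pos_c = int(cpg_pos.loc[eff.cpg_id, "position"])
            offset = int(rng.integers(-500_000, 500_001))
            snp_rows.append((detail, chrom_c, max(1, pos_c + offset)))
            snp_mafs[detail] = rng.uniform(*config.maf_range)
            # one null SNP in the same window, to exercise cis-SNP selection
            null_id = f"snp_null_{snp_cursor:04d}"
            snp_rows.append((null_id, chrom_c, max(1, pos_c + int(rng.integers(-500_000, 500_001)))))
            snp_mafs[null_id] = rng.uniform(*config.maf_range)
            snp_cursor += 1
        effects.append(replace(eff, driver_detail=detail))
    # background SNPs far from every planted CpG
    for b in range(5):
        bid = f"snp_bg_{b:02d}"
        snp_rows.append((bid, str(rng.integers(1, 23)), int(rng.integers(60_000_000, 90_000_000))))
        snp_mafs[bid] = rng.uniform(*config.maf_range)
    snp_positions = pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "position"])

    # --- eQTM lookup table for a few planted direct CpGs -------------------
    direct_cpgs = [e.cpg_id for e in effects if e.driver == "direct"]
    eqtm_rows = []
    for t, cpg in enumerate(direct_cpgs[:5]):
        eqtm_rows.append(
            (cpg, f"ENSTSYN{t:06d}", f"TGENE{t:03d}", 10.0 ** rng.uniform(-20, -8), rng.normal(0, 0.3))
        )
    eqtm_table = pd.DataFrame(
        eqtm_rows, columns=["cpg_id", "transcript", "gene", "eqtm_p", "eqtm_beta"]
    )

    # --- cross-reactivity flag lists --------------------------------------
    planted_cpg_ids = {e.cpg_id for e in effects}
    free = [cpg_name(i) for i in range(config.marker_block, n_cpgs) if cpg_name(i) not in planted_cpg_ids]
    cross_cpgs = free[:2]
    cross_aptamers = [protein_name(n_prot - 1)]

    # --- per-CpG / per-protein baselines ----------------------------------
    mu_cpg = rng.normal(0.0, 1.8, size=n_cpgs)
    sd_cpg = config.noise_sd_methylation * rng.uniform(0.6, 1.6, size=n_cpgs)
    mu_prot = rng.normal(7.0, 0.8, size=n_prot)
    sd_prot = config.noise_sd_protein * rng.uniform(0.6, 1.6, size=n_prot)

    # --- synthetic Hi-C contact map ---------------------------------------
    pool_cpgs = sorted(planted_cpg_ids)
    direct_pairs = [(e.cpg_id, e.protein_id) for e in effects if e.driver == "direct"]
    hic = simulate_hic_map(
        cpg_bins=[
            (cpg_pos.loc[c, "chromosome"], hic_bin(int(cpg_pos.loc[c, "position"])))
            for c in pool_cpgs
        ],
        gene_bins=[
            (row.chromosome, hic_bin(int(row.gene_start))) for row in aptamers.itertuples()
        ],
        true_pairs=[
            (
                (cpg_pos.loc[c, "chromosome"], hic_bin(int(cpg_pos.loc[c, "position"]))),
                (
                    aptamers.set_index("protein_id").loc[p, "chromosome"],
                    hic_bin(int(aptamers.set_index("protein_id").loc[p, "gene_start"])),
                ),
            )
            for c, p in direct_pairs
        ],
        base_rate=config.hic_base_rate,
        fold=config.hic_fold,
        rng=rng,
    )

    return {
        "manifest": manifest,
        "aptamers": aptamers,
        "reference": reference,
        "effects": effects,
        "snp_positions": snp_positions,
        "snp_mafs": snp_mafs,
        "eqtm_table": eqtm_table,
        "hic": hic,
        "cross_cpgs": cross_cpgs,
        "cross_aptamers": cross_aptamers,
        "mu_cpg": mu_cpg,
        "sd_cpg": sd_cpg,
        "mu_prot": mu_prot,
        "sd_prot": sd_prot,
    }


def hic_bin(position: int, bin_size: int = 1000) -> int:
    """1-based start of the 1-kb bin containing a 1-based position."""
    return ((position - 1) // bin_size) * bin_size + 1


def simulate_hic_map(cpg_bins, gene_bins, true_pairs, base_rate, fold, rng):
    """Sparse symmetric contact list over 1-kb bins.

    Every (CpG-bin, gene-bin) pair in the pool cross-product receives a
    contact with probability ``base_rate``; pairs listed in ``true_pairs``
    with probability ``min(1, fold * base_rate)``, planting a known excess.
    """
    truth = {frozenset([a, b]) for a, b in true_pairs}
    rows = []
    seen = set()
    p_true = min(1.0, fold * base_rate)
    for a in set(cpg_bins):
        for b in set(gene_bins):
            key = frozenset([a, b])
            if key in seen:
                continue
            seen.add(key)
            p = p_true if key in truth else base_rate
            if rng.random() < p:
                rows.append((a[0], a[1], b[0], b[1], float(rng.integers(1, 50))))
    return pd.DataFrame(
        rows, columns=["chrom_a", "bin_a_start", "chrom_b", "bin_b_start", "contact_value"]
    )


def _draw_covariates(n: int, rng) -> pd.DataFrame:
    sex = (rng.random(n) < 0.5).astype(int)  # 1 = male, 0 = female
    age = rng.uniform(32.0, 81.0, size=n)
    bmi = rng.normal(27.5, 4.5, size=n).clip(16, 50)
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.45, 0.30, 0.25])
    p_diab = 1.0 / (1.0 + np.exp(-(-3.2 + 0.030 * (age - 55) + 0.080 * (bmi - 27.5))))
    diabetes = (rng.random(n) < p_diab).astype(int)
    return pd.DataFrame(
        {"sex": sex, "age": age, "bmi": bmi, "smoking": smoking, "diabetes": diabetes}
    )


def smoking_score(smoking: pd.Series) -> np.ndarray:
    """Numeric smoking burden: never=0, former=0.5, current=1."""
    return smoking.map({"never": 0.0, "former": 0.5, "current": 1.0}).to_numpy()


def _derive_phenotypes(cov: pd.DataFrame, rng) -> pd.DataFrame:
    from .downstream import derive_mets  # local import to avoid a cycle at import time

    n = len(cov)
    sex = cov["sex"].to_numpy()
    age = cov["age"].to_numpy()
    bmi = cov["bmi"].to_numpy()
    diabetes = cov["diabetes"].to_numpy()
    waist = 25 + 2.1 * bmi + 8 * sex + rng.normal(0, 5, n)
    tg = np.exp(4.6 + 0.03 * (bmi - 27) + rng.normal(0, 0.4, n))
    hdl = (55 - 8 * sex + rng.normal(0, 10, n)).clip(20, 110)
    sbp = 110 + 0.45 * (age - 32) + rng.normal(0, 12, n)
    dbp = 70 + 0.15 * (age - 32) + rng.normal(0, 8, n)
    glucose = 90 + 25 * diabetes + rng.normal(0, 8, n)
    lipid_drug = (rng.random(n) < 0.08).astype(int)
    bp_drug = (rng.random(n) < 0.15).astype(int)
    glucose_drug = ((rng.random(n) < 0.7) & (diabetes == 1)).astype(int)
    chol = 200 + rng.normal(0, 35, n)
    pheno = pd.DataFrame(
        {
            "sex": sex,
            "hypertension": ((sbp >= 140) | (dbp >= 90) | (bp_drug == 1)).astype(int),
            "myocardial_infarction": (rng.random(n) < 0.03).astype(int),
            "type2_diabetes": diabetes,
            "bmi": bmi,
            "alcohol_g_per_day": rng.exponential(15, n),
            "total_cholesterol": chol,
            "hdl": hdl,
            "ldl": (chol - hdl - tg / 5 + rng.normal(0, 10, n)).clip(30, None),
            "triglycerides": tg,
            "waist_cm": waist,
            "tg_mg_dl": tg,
            "hdl_mg_dl": hdl,
            "sbp_mmHg": sbp,
            "dbp_mmHg": dbp,
            "glucose_mg_dl": glucose,
            "lipid_drug": lipid_drug,
            "bp_drug": bp_drug,
            "glucose_drug": glucose_drug,
        },
        index=cov.index,
    )
    mets, _ = derive_mets(pheno)
    pheno["metabolic_syndrome"] = mets.astype(int)
    return pheno


def simulate_cohort(config: SimulationConfig, cohort_label: str = "discovery") -> CohortBundle:
    """Generate one cohort of the paired methylation/protein design.

    ``discovery`` uses ``n_samples``; ``replication`` redraws
    ``round(replication_fraction * n_samples)`` samples with the same planted
    effects and, when ``ethnicity_pc_sd > 0``, adds observed genetic and
    proteomic principal-component covariates that emulate a multi-ethnic
    cohort with mild cell lysis.  Identical configs (including the seed)
    produce byte-identical bundles.
    """
    if cohort_label not in COHORT_LABELS:
        raise ConfigurationError(f"cohort_label must be one of {COHORT_LABELS}")
    structures = _structures(config)
    label_code = COHORT_LABELS.index(cohort_label)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, label_code]))

    n = (
        config.n_samples
        if cohort_label == "discovery"
        else max(10, round(config.replication_fraction * config.n_samples))
    )
    sample_ids = [f"{cohort_label[:4]}_{i:04d}" for i in range(n)]
    n_cpgs, n_prot = config.n_cpgs, config.n_proteins
    effects: list[PlantedEffect] = structures["effects"]
    reference: CellReference = structures["reference"]

    cov = _draw_covariates(n, rng)
    cov.index = pd.Index(sample_ids, name="sample_id")

    alpha = _BASE_FRACTIONS[: config.n_cell_types]
    alpha = alpha / alpha.sum() * _DIRICHLET_CONCENTRATION
    fractions = rng.dirichlet(alpha, size=n)
    frac_df = pd.DataFrame(fractions, index=cov.index, columns=reference.cell_types)

    # genotype dosages for every SNP in the map
    snp_positions: pd.DataFrame = structures["snp_positions"]
    dosages = {
        sid: rng.binomial(2, structures["snp_mafs"][sid], size=n).astype(float)
        for sid in snp_positions["snp_id"]
    }
    genotypes = pd.DataFrame(dosages, index=cov.index)

    # driver signal bank (standardized within cohort)
    signals: dict[str, np.ndarray] = {
        "sex": _standardized(cov["sex"].to_numpy().astype(float)),
        "age": _standardized(cov["age"].to_numpy()),
        "bmi": _standardized(cov["bmi"].to_numpy()),
        "smoking": _standardized(smoking_score(cov["smoking"])),
        "diabetes": _standardized(cov["diabetes"].to_numpy().astype(float)),
    }
    global_factor = rng.normal(size=n)

    def driver_signal(eff: PlantedEffect) -> np.ndarray:
        if eff.driver in signals:
            return signals[eff.driver]
        if eff.driver == "cell":
            return _standardized(frac_df[eff.driver_detail].to_numpy())
        if eff.driver == "snp":
            return _standardized(genotypes[eff.driver_detail].to_numpy())
        if eff.driver == "global_pc":
            return _standardized(global_factor)
        if eff.driver == "direct":
            return rng.normal(size=n)
        raise AssertionError(eff.driver)

    # --- methylation on the M scale ---------------------------------------
    sd_cpg = structures["sd_cpg"]
    m_values = structures["mu_cpg"] + rng.normal(size=(n, n_cpgs)) * sd_cpg
    log_prot = structures["mu_prot"] + rng.normal(size=(n, n_prot)) * structures["sd_prot"]

    cpg_index = {cpg_name(i): i for i in range(n_cpgs)}
    prot_index = {protein_name(j): j for j in range(n_prot)}
    for eff in effects:
        e = config.scaled_effect(eff)
        if e == 0.0:
            continue
        rho = math.sqrt(min(abs(e), 0.995))
        load = rho / math.sqrt(1.0 - rho * rho)
        z = driver_signal(eff)
        ci, pj = cpg_index[eff.cpg_id], prot_index[eff.protein_id]
        m_values[:, ci] += load * sd_cpg[ci] * z
        log_prot[:, pj] += math.copysign(load, e) * structures["sd_prot"][pj] * z

    # multi-ethnic replication structure: observed genetic and proteomic PCs
    if cohort_label == "replication" and config.ethnicity_pc_sd > 0:
        geno_latent = rng.normal(0, config.ethnicity_pc_sd, size=(n, 3))
        proteo_latent = rng.normal(0, config.ethnicity_pc_sd, size=(n, 3))
        cpg_load = rng.normal(0, 0.4, size=(3, n_cpgs)) * (rng.random((3, n_cpgs)) < 0.10)
        prot_load_g = rng.normal(0, 0.3, size=(3, n_prot)) * (rng.random((3, n_prot)) < 0.10)
        prot_load_p = rng.normal(0, 0.4, size=(3, n_prot)) * (rng.random((3, n_prot)) < 0.30)
        m_values += (geno_latent @ cpg_load) * sd_cpg
        log_prot += (geno_latent @ prot_load_g + proteo_latent @ prot_load_p) * structures["sd_prot"]
        for k in range(3):
            cov[f"geno_pc{k + 1}"] = _standardized(geno_latent[:, k])
            cov[f"proteo_pc{k + 1}"] = _standardized(proteo_latent[:, k])

    # beta values: markers from reference mixing, the rest via inverse logit
    beta = 1.0 / (1.0 + np.exp2(-m_values))
    marker_beta = fractions @ reference.profile.to_numpy()
    marker_beta += rng.normal(0, 0.02, size=marker_beta.shape)
    beta[:, : config.marker_block] = np.clip(marker_beta, 0.005, 0.995)
    beta = np.clip(beta, 1e-9, 1 - 1e-9)

    methylation = OmicsMatrix(
        pd.DataFrame(beta, index=cov.index, columns=[cpg_name(i) for i in range(n_cpgs)]),
        "beta",
    )
    proteins = OmicsMatrix(
        pd.DataFrame(
            np.exp(log_prot), index=cov.index, columns=[protein_name(j) for j in range(n_prot)]
        ),
        "raw_protein",
    )

    phenotypes = _derive_phenotypes(cov, rng)

    if config.n_metabolites > 0:
        metab = rng.normal(5.0, 1.0, size=(n, config.n_metabolites))
        smoke_z = signals["smoking"]
        metab[:, : min(3, config.n_metabolites)] += 0.4 * smoke_z[:, None]
        metabolites = OmicsMatrix(
            pd.DataFrame(
                metab,
                index=cov.index,
                columns=[f"metab_{k:03d}" for k in range(config.n_metabolites)],
            ),
            "log_protein",
        )
    else:
        metabolites = None

    truth = GroundTruth(effects=effects, cell_fractions=frac_df, reference=reference)
    return CohortBundle(
        label=cohort_label,
        methylation=methylation,
        proteins=proteins,
        manifest=structures["manifest"],
        aptamers=structures["aptamers"],
        covariates=cov,
        genotypes=genotypes,
        snp_positions=snp_positions,
        phenotypes=phenotypes,
        metabolites=metabolites,
        hic=structures["hic"],
        eqtm_table=structures["eqtm_table"],
        cross_reactive_cpgs=structures["cross_cpgs"],
        cross_reactive_aptamers=structures["cross_aptamers"],
        cell_reference=reference,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle serialization
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "methylation": "methylation.tsv",
    "proteins": "proteins.tsv",
    "manifest": "manifest.tsv",
    "aptamers": "aptamers.tsv",
    "covariates": "covariates.tsv",
    "genotypes": "genotypes.tsv",
    "snp_positions": "snp_positions.tsv",
    "phenotypes": "phenotypes.tsv",
    "metabolites": "metabolites.tsv",
    "hic": "hic_contacts.tsv",
    "eqtm": "eqtm.tsv",
    "cross_cpgs": "cross_reactive_cpgs.txt",
    "cross_aptamers": "cross_reactive_aptamers.txt",
    "truth": "ground_truth.tsv",
    "reference": "cell_reference.tsv",
    "fractions": "true_cell_fractions.tsv",
    "meta": "meta.yaml",
}


def write_bundle(bundle: CohortBundle, directory) -> dict[str, str]:
    """Write every member table as TSV; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = {k: directory / v for k, v in _BUNDLE_FILES.items()}
    pio.write_matrix(bundle.methylation, f["methylation"])
    pio.write_matrix(bundle.proteins, f["proteins"])
    pio.write_manifest(bundle.manifest, f["manifest"])
    pio.write_table(bundle.aptamers, f["aptamers"])
    for name, df in [
        ("covariates", bundle.covariates),
        ("genotypes", bundle.genotypes),
        ("phenotypes", bundle.phenotypes),
        ("fractions", bundle.truth.cell_fractions),
    ]:
        out = df.copy()
        out.index.name = pio.SAMPLE_COLUMN
        out.to_csv(f[name], sep="\t", float_format=pio.FLOAT_FORMAT)
    pio.write_table(bundle.snp_positions, f["snp_positions"])
    if bundle.metabolites is None:
        f["metabolites"].write_text(pio.SAMPLE_COLUMN + "\n")
    else:
        pio.write_matrix(bundle.metabolites, f["metabolites"])
    pio.write_table(bundle.hic, f["hic"])
    pio.write_table(bundle.eqtm_table, f["eqtm"])
    pio.write_id_list(bundle.cross_reactive_cpgs, f["cross_cpgs"])
    pio.write_id_list(bundle.cross_reactive_aptamers, f["cross_aptamers"])
    truth_df = pd.DataFrame(
        [
            (e.cpg_id, e.protein_id, e.driver, e.effect_size, e.driver_detail or "")
            for e in bundle.truth.effects
        ],
        columns=["cpg_id", "protein_id", "driver", "effect_size", "driver_detail"],
    )
    pio.write_table(truth_df, f["truth"])
    pio.write_cell_reference(bundle.cell_reference, f["reference"])
    f["meta"].write_text(yaml.safe_dump({"label": bundle.label, "n_samples": len(bundle.sample_ids)}))
    return {k: str(v) for k, v in f.items()}


def read_bundle(directory) -> CohortBundle:
    """Re-read a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    f = {k: directory / v for k, v in _BUNDLE_FILES.items()}
    meta = yaml.safe_load(f["meta"].read_text())
    methylation = pio.read_matrix(f["methylation"], "beta")
    proteins = pio.read_matrix(f["proteins"], "raw_protein")
    manifest = pio.read_manifest(f["manifest"])
    aptamers = pio.read_table(f["aptamers"], dtype={"chromosome": str})
    covariates = pd.read_csv(f["covariates"], sep="\t", index_col=pio.SAMPLE_COLUMN)
    genotypes = pd.read_csv(f["genotypes"], sep="\t", index_col=pio.SAMPLE_COLUMN)
    snp_positions = pio.read_table(f["snp_positions"], dtype={"chromosome": str})
    phenotypes = pd.read_csv(f["phenotypes"], sep="\t", index_col=pio.SAMPLE_COLUMN)
    metab_df = pd.read_csv(f["metabolites"], sep="\t")
    if metab_df.shape[1] <= 1 and metab_df.empty:
        metabolites = None
    else:
        metabolites = pio.read_matrix(f["metabolites"], "log_protein")
    hic = pio.read_table(f["hic"], dtype={"chrom_a": str, "chrom_b": str})
    eqtm = pio.read_table(f["eqtm"])
    truth_df = pio.read_table(f["truth"], keep_default_na=False)
    reference = pio.read_cell_reference(f["reference"])
    fractions = pd.read_csv(f["fractions"], sep="\t", index_col=pio.SAMPLE_COLUMN)
    effects = [
        PlantedEffect(
            row.cpg_id,
            row.protein_id,
            row.driver,
            float(row.effect_size),
            row.driver_detail or None,
        )
        for row in truth_df.itertuples()
    ]
    for df in (covariates, genotypes, phenotypes, fractions):
        df.index = df.index.astype(str)
    truth = GroundTruth(effects=effects, cell_fractions=fractions, reference=reference)
    return CohortBundle(
        label=meta["label"],
        methylation=methylation,
        proteins=proteins,
        manifest=manifest,
        aptamers=aptamers,
        covariates=covariates,
        genotypes=genotypes,
        snp_positions=snp_positions,
        phenotypes=phenotypes,
        metabolites=metabolites,
        hic=hic,
        eqtm_table=eqtm,
        cross_reactive_cpgs=pio.read_id_list(f["cross_cpgs"]),
        cross_reactive_aptamers=pio.read_id_list(f["cross_aptamers"]),
        cell_reference=reference,
        truth=truth,
    )


def make_array_manifest(
    n_snp_probes: int = 65,
    n_under_measured: int = 35,
    n_chr_x: int = 11231,
    n_chr_y: int = 416,
    n_non_cg: int = 2993,
    n_retained: int = 470_837,
    n_samples: int = 944,
    min_measured: int = 100,
) -> pd.DataFrame:
    """Build a manifest with prescribed QC category counts.

    The defaults reproduce the category sizes of a 485,577-probe 450K array
    after sample QC: 65 SNP-control probes, then among the remaining
    485,512 probes 35 under-measured, 11,231 on chromosome X, 416 on
    chromosome Y and 2,993 non-cg probes, leaving 470,837 autosomal cg
    probes.  Categories are disjoint so the first-rule-wins ledger counts
    equal the category sizes.
    """
    blocks = []

    def block(n, probe_class, targets_snp, chromosome, n_measured, prefix):
        if n == 0:
            return
        blocks.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{prefix}{i:07d}" for i in range(n)],
                    "probe_class": probe_class,
                    "targets_snp": targets_snp,
                    "chromosome": chromosome,
                    "position": np.arange(1, n + 1) * 1000,
                    "n_measured": n_measured,
                }
            )
        )

    block(n_snp_probes, "rs", True, "1", n_samples, "rs_")
    block(n_under_measured, "cg", False, "2", min_measured - 1, "cgu")
    block(n_chr_x, "cg", False, "X", n_samples, "cgx")
    block(n_chr_y, "cg", False, "Y", n_samples, "cgy")
    block(n_non_cg, "ch", False, "3", n_samples, "ch_")
    block(n_retained, "cg", False, "4", n_samples, "cg_")
    manifest = pd.concat(blocks, ignore_index=True)
    for col, value in [
        ("ucsc_region", "Body"),
        ("island_relation", "open_sea"),
        ("regulatory_feature", "none"),
        ("cell_type_specific", False),
        ("enhancer", False),
        ("dhs", False),
        ("dmr", False),
        ("cdmr", False),
    ]:
        manifest[col] = value
    return manifest
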
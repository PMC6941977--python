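"""Final pQTM characterization: cis/trans calls, signal grouping,
cross-reactivity flags, annotation enrichment, Hi-C contact enrichment,
and eQTM overlap.

A pQTM is *cis* when the gene encoding the associated protein lies within
1 Mb of the CpG on the same chromosome (distance 0 if the CpG falls inside
the gene interval; the 1 Mb boundary is inclusive).  Independent association
signals are the connected components of the bipartite CpG-protein graph
whose edges are the pQTMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError

REQUIRED_COORDS = ["cpg_chr", "cpg_pos", "protein_chr", "gene_start", "gene_end"]


def classify_cis_trans(pqtms: pd.DataFrame, window: int = 1_000_000) -> pd.Series:
    """cis/trans flag per pQTM row (nullable boolean; NA when coordinates
    are missing, with those rows recorded via the NA itself)."""
    missing = [c for c in REQUIRED_COORDS if c not in pqtms.columns]
    if missing:
        raise ConfigurationError(f"pQTM table lacks coordinate columns: {missing}")
    out = []
    for row in pqtms.itertuples():
        if (
            pd.isna(row.cpg_chr)
            or pd.isna(row.cpg_pos)
            or pd.isna(row.protein_chr)
            or pd.isna(row.gene_start)
            or pd.isna(row.gene_end)
        ):
            out.append(pd.NA)
            continue
        if str(row.cpg_chr) != str(row.protein_chr):
            out.append(False)
            continue
        pos = float(row.cpg_pos)
        start, end = float(row.gene_start), float(row.gene_end)
        distance = 0.0 if start <= pos <= end else min(abs(pos - start), abs(pos - end))
        out.append(distance <= window)
    return pd.Series(out, index=pqtms.index, dtype="boolean", name="cis")


@dataclass
class SignalGroups:
    labels: pd.Series  # per pQTM row
    components: pd.DataFrame  # label, n_edges, n_cpgs, n_proteins

    @property
    def n_components(self) -> int:
        return len(self.components)


def group_signals(
    pqtms: pd.DataFrame,
    protein_column: str = "protein_gene",
    locus_merge_bp: int = 0,
) -> SignalGroups:
    """Partition pQTMs into independent association signals.

    Builds the bipartite CpG-protein graph (one edge per pQTM row) and takes
    connected components.  With ``locus_merge_bp`` > 0, CpGs on the same
    chromosome within that distance are pre-merged into one locus node.
    Each component is labeled by its lexicographically smallest protein
    name; labels are invariant to the input row order.
    """
    if protein_column not in pqtms.columns:
        raise ConfigurationError(f"column {protein_column!r} not in pQTM table")

    cpg_node: dict[str, tuple] = {}
    if locus_merge_bp > 0 and {"cpg_chr", "cpg_pos"} <= set(pqtms.columns):
        coords = (
            pqtms[["cpg_id", "cpg_chr", "cpg_pos"]]
            .drop_duplicates("cpg_id")
            .sort_values(["cpg_chr", "cpg_pos"])
        )
        for chrom, grp in coords.groupby("cpg_chr", sort=True):
            locus_start = None
            prev_pos = None
            for row in grp.itertuples():
                if prev_pos is None or row.cpg_pos - prev_pos > locus_merge_bp:
                    locus_start = row.cpg_pos
                cpg_node[row.cpg_id] = ("cpg_locus", str(chrom), locus_start)
                prev_pos = row.cpg_pos
    graph = nx.Graph()
    edges = []
    for row in pqtms.itertuples():
        cpg = cpg_node.get(row.cpg_id, ("cpg", row.cpg_id))
        prot = ("prot", getattr(row, protein_column))
        graph.add_edge(cpg, prot)
        edges.append((cpg, prot))

    node_label: dict[tuple, str] = {}
    comp_rows = []
    for component in nx.connected_components(graph):
        proteins = sorted(n[1] for n in component if n[0] == "prot")
        label = proteins[0] if proteins else sorted(component)[0][1]
        for node in component:
            node_label[node] = label
        n_edges = sum(
            1 for cpg, prot in edges if cpg in component
        )
        comp_rows.append(
            {
                "label": label,
                "n_edges": n_edges,
                "n_cpgs": sum(1 for n in component if n[0] != "prot"),
                "n_proteins": len(proteins),
            }
        )
    labels = pd.Series(
        [node_label[cpg] for cpg, _ in edges], index=pqtms.index, name="group_label"
    )
    components = (
        pd.DataFrame(comp_rows).sort_values("label").reset_index(drop=True)
    )
    return SignalGroups(labels=labels, components=components)


def cross_reactivity_filter(
    pqtms: pd.DataFrame, flagged_cpgs, flagged_aptamers
) -> tuple[pd.DataFrame, dict]:
    """Flag (never delete) pQTMs whose CpG or aptamer is on a
    cross-reactivity list."""
    flagged_cpgs = set(flagged_cpgs)
    flagged_aptamers = set(flagged_aptamers)
    out = pqtms.copy()
    out["cross_reactive"] = [
        (row.cpg_id in flagged_cpgs) or (row.protein_id in flagged_aptamers)
        for row in pqtms.itertuples()
    ]
    summary = {
        "n_flagged": int(out["cross_reactive"].sum()),
        "n_flagged_cpg": int(out["cpg_id"].isin(flagged_cpgs).sum()),
        "n_flagged_aptamer": int(out["protein_id"].isin(flagged_aptamers).sum()),
    }
    return out, summary


# ---------------------------------------------------------------------------
# annotation enrichment
# ---------------------------------------------------------------------------

_UCSC_TOKENS = {"TSS200", "TSS1500", "5'UTR", "Body", "3'UTR"}
_ISLAND_TOKENS = {
    "island",
    "north_shore",
    "south_shore",
    "north_shelf",
    "south_shelf",
    "open_sea",
    "shore",
    "shelf",
}
_REG_TOKENS = {"promoter", "gene", "non_gene", "unclassified", "none"}


def category_mask(manifest: pd.DataFrame, category: str) -> pd.Series:
    """Boolean membership of every manifest probe in an annotation category."""
    if category in manifest.columns and manifest[category].dtype == bool:
        return manifest[category]
    if category in {"enhancer", "dhs", "dmr", "cdmr", "cell_type_specific"}:
        return manifest[category].astype(bool)
    if category in _UCSC_TOKENS:
        return manifest["ucsc_region"].fillna("").str.split(";").apply(lambda t: category in t)
    if category in _ISLAND_TOKENS:
        if category in {"shore", "shelf"}:
            return manifest["island_relation"].fillna("").str.endswith(category)
        return manifest["island_relation"] == category
    if category in _REG_TOKENS:
        return manifest["regulatory_feature"] == category
    if category == "promoter_cell_specific":
        return (manifest["regulatory_feature"] == "promoter") & manifest[
            "cell_type_specific"
        ].astype(bool)
    raise ConfigurationError(f"unknown annotation category {category!r}")


def fisher_enrichment(a: int, b: int, c: int, d: int) -> dict:
    """2x2 enrichment statistics for the table [[a, b], [c, d]].

    The odds ratio is the sample OR with a Haldane-Anscombe 0.5 correction
    when any cell is zero; the p-value is the exact two-sided Fisher test
    (hypergeometric enumeration); the 95% CI uses the log-OR normal
    approximation.
    """
    if min(a, b, c, d) < 0:
        raise ConfigurationError("cell counts must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (float(np.exp(np.log(odds) - 1.96 * se)), float(np.exp(np.log(odds) + 1.96 * se)))
    return {
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": float(odds),
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p": float(p),
    }


def annotation_enrichment(
    cpg_set, manifest: pd.DataFrame, categories
) -> pd.DataFrame:
    """Fisher enrichment of a CpG set against the manifest background.

    For each category the 2x2 table crosses membership in ``cpg_set`` with
    membership in the category, over all manifest probes.
    """
    cpg_set = set(cpg_set)
    unknown = cpg_set - set(manifest["probe_id"])
    if unknown:
        raise ConfigurationError(
            f"{len(unknown)} CpGs of the set are absent from the manifest background"
        )
    in_set = manifest["probe_id"].isin(cpg_set).to_numpy()
    rows = []
    for category in categories:
        annotated = category_mask(manifest, category).to_numpy()
        a = int((in_set & annotated).sum())
        b = int((in_set & ~annotated).sum())
        c = int((~in_set & annotated).sum())
        d = int((~in_set & ~annotated).sum())
        rows.append({"category": category, **fisher_enrichment(a, b, c, d)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hi-C contact enrichment
# ---------------------------------------------------------------------------


def hic_bin_start(position: int, bin_size: int = 1000) -> int:
    """1-based start of the bin containing a 1-based position."""
    return int((position - 1) // bin_size) * bin_size + 1


@dataclass
class HiCEnrichment:
    fold: float | None
    p: float | None
    observed_fraction: float
    expected_fraction: float | None
    n_random: int


def hic_contact_enrichment(
    pqtms: pd.DataFrame,
    hic: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
    bin_size: int = 1000,
) -> HiCEnrichment:
    """Fold enrichment of pQTMs in Hi-C contacts over a size-matched
    randomized background.

    Each CpG and each protein gene (start coordinate) is placed in its 1-kb
    bin; a pQTM is contact-positive when its (symmetrized) bin pair is in
    the map.  The background redraws |pQTMs| CpG-protein pairings (with
    replacement) from the observed CpG and protein pools; the empirical p is
    (1 + #{random >= observed}) / (n_random + 1).
    """
    if hic.empty:
        return HiCEnrichment(
            fold=None, p=None,
            observed_fraction=float("nan"), expected_fraction=None,
            n_random=n_random,
        )
    misaligned = ((hic["bin_a_start"] - 1) % bin_size != 0) | (
        (hic["bin_b_start"] - 1) % bin_size != 0
    )
    if misaligned.any():
        raise ConfigurationError("Hi-C bin starts must be aligned to the bin size")
    contacts = set()
    for row in hic.itertuples():
        contacts.add(
            frozenset([(str(row.chrom_a), int(row.bin_a_start)), (str(row.chrom_b), int(row.bin_b_start))])
        )

    cpg_bins = [
        (str(r.cpg_chr), hic_bin_start(int(r.cpg_pos), bin_size)) for r in pqtms.itertuples()
    ]
    gene_bins = [
        (str(r.protein_chr), hic_bin_start(int(r.gene_start), bin_size))
        for r in pqtms.itertuples()
    ]

    def positive_fraction(pairs) -> float:
        return float(np.mean([frozenset([a, b]) in contacts for a, b in pairs]))

    observed = positive_fraction(zip(cpg_bins, gene_bins))
    rng = np.random.default_rng(seed)
    cpg_pool = sorted(set(cpg_bins))
    gene_pool = sorted(set(gene_bins))
    n_pairs = len(cpg_bins)
    random_fracs = np.empty(n_random)
    for i in range(n_random):
        ci = rng.integers(0, len(cpg_pool), size=n_pairs)
        gi = rng.integers(0, len(gene_pool), size=n_pairs)
        random_fracs[i] = positive_fraction(
            (cpg_pool[x], gene_pool[y]) for x, y in zip(ci, gi)
        )
    expected = float(random_fracs.mean())
    fold = observed / expected if expected > 0 else None
    p = float((1 + np.sum(random_fracs >= observed)) / (n_random + 1))
    return HiCEnrichment(
        fold=fold,
        p=p,
        observed_fraction=observed,
        expected_fraction=expected,
        n_random=n_random,
    )


def eqtm_overlap(pqtms: pd.DataFrame, eqtm_table: pd.DataFrame) -> pd.DataFrame:
    """Join pQTMs with a CpG-transcript eQTM lookup table (one output row
    per matching transcript)."""
    if eqtm_table.empty:
        return pqtms.head(0).assign(transcript=None, eqtm_p=None, eqtm_beta=None)
    keep = [c for c in ["cpg_id", "transcript", "gene", "eqtm_p", "eqtm_beta"] if c in eqtm_table.columns]
    merged = pqtms.merge(eqtm_table[keep], on="cpg_id", how="inner")
    return merged.reset_index(drop=True)
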
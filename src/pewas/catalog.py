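"""Curated example catalog of replicated blood-plasma pQTMs.

The package ships a small catalog of 31 replicated CpG-protein associations
spanning nine independent association signals (PAPPA, NLRC5, ICAM5,
CLEC11A, PRTN3, C4, SIGLEC5/SIGLEC14, AHRR/PIGR, GP1BA), with CpG and
protein-gene coordinates, discovery effect sizes and p-values, and, where
available, the overlapping cis-eQTM of the CpG.  It serves as a worked
real-data example for cis/trans classification, signal grouping and eQTM
overlap, and as a fixture for the package's own regression tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_CATALOG_FILE = "pqtm_catalog.tsv"


def load_pqtm_catalog() -> pd.DataFrame:
    """Load the bundled pQTM catalog.

    Columns: cpg_id, cpg_gene, cpg_chr, cpg_pos, protein_gene, protein_id
    (aptamer SeqId), protein_chr, gene_start, gene_end (1-based inclusive),
    p_pqtm, beta_pqtm, and optional eqtm_transcript/eqtm_gene/eqtm_p/
    eqtm_beta for CpGs with a known expression QTM.
    """
    with resources.files("pewas.data").joinpath(_CATALOG_FILE).open() as handle:
        df = pd.read_csv(
            handle, sep="\t", dtype={"cpg_chr": str, "protein_chr": str}
        )
    return df


def load_eqtm_catalog() -> pd.DataFrame:
    """eQTM lookup rows (cpg_id, transcript, gene, eqtm_p, eqtm_beta)
    extracted from the catalog, one row per CpG-transcript pair."""
    df = load_pqtm_catalog()
    eqtm = (
        df.loc[
            df["eqtm_transcript"].notna(),
            ["cpg_id", "eqtm_transcript", "eqtm_gene", "eqtm_p", "eqtm_beta"],
        ]
        .drop_duplicates()
        .rename(columns={"eqtm_transcript": "transcript", "eqtm_gene": "gene"})
        .reset_index(drop=True)
    )
    return eqtm
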
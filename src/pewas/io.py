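"""Plain-text (TSV) readers and writers for every table the pipeline touches.

All matrices are written samples-in-rows with a header row of feature ids and
the sample id in the first column.  Floats are rendered with ``%.10g`` so that
write -> read -> write round-trips are byte-identical on the text
representation.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .containers import CellReference, OmicsMatrix, validate_manifest

FLOAT_FORMAT = "%.10g"
SAMPLE_COLUMN = "sample_id"


def write_matrix(matrix: OmicsMatrix, path: str | os.PathLike) -> None:
    df = matrix.data.copy()
    df.index.name = SAMPLE_COLUMN
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path: str | os.PathLike, scale: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=SAMPLE_COLUMN)
    df.index = df.index.astype(str)
    return OmicsMatrix(df, scale)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_table(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_manifest(manifest)
    write_table(manifest, path)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    manifest = read_table(path, dtype={"chromosome": str, "probe_id": str})
    return validate_manifest(manifest)


def write_cell_reference(reference: CellReference, path: str | os.PathLike) -> None:
    df = reference.profile.copy()
    df.index.name = "cell_type"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_cell_reference(path: str | os.PathLike) -> CellReference:
    df = pd.read_csv(path, sep="\t", index_col="cell_type")
    return CellReference(list(df.index), list(df.columns), df)


def write_id_list(ids, path: str | os.PathLike) -> None:
    Path(path).write_text("".join(f"{x}\n" for x in ids))


def read_id_list(path: str | os.PathLike) -> list[str]:
    text = Path(path).read_text()
    return [line for line in text.splitlines() if line.strip()]
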
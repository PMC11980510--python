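"""Readers and writers for count tables, trees and sample metadata.

Count tables are plain :class:`pandas.DataFrame` objects oriented
samples x ASVs with non-negative integer entries.  Two on-disk encodings
are supported: TSV (samples in rows) and a minimal BIOM v1 JSON document
(sparse, observations in rows, as the BIOM 1.0 spec lays the matrix out).
Trees are Newick files read into :class:`skbio.TreeNode`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"


class FormatError(ValueError):
    """A file failed validation against the expected table format."""


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check and coerce a samples x ASVs count table.

    Raises :class:`FormatError` naming the first offending cell if any
    entry is negative, non-finite or non-integral; raises on duplicate
    sample or ASV identifiers.
    """
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate ASV identifiers: {dups}")
    values = table.to_numpy()
    if values.dtype.kind not in "iu":
        float_vals = np.asarray(values, dtype=float)
        bad = ~np.isfinite(float_vals) | (float_vals != np.floor(float_vals))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-integer count at sample {table.index[i]!r}, "
                f"ASV {table.columns[j]!r}: {table.iat[i, j]!r}"
            )
        values = float_vals.astype(np.int64)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count at sample {table.index[i]!r}, "
            f"ASV {table.columns[j]!r}: {table.iat[i, j]!r}"
        )
    out = pd.DataFrame(values.astype(np.int64), index=table.index, columns=table.columns)
    out.index.name = "sample_id"
    return out


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".biom", ".json"}:
        return "biom-json"
    return "tsv"


def read_count_table(path, format: str | None = None) -> pd.DataFrame:
    """Read a count table from TSV or BIOM-JSON into samples x ASVs."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        table = pd.read_csv(path, sep="\t", index_col=0)
        table.index = table.index.astype(str)
        table.columns = table.columns.astype(str)
        return validate_count_table(table)
    if fmt == "biom-json":
        doc = json.loads(path.read_text())
        if doc.get("format") != _BIOM_FORMAT:
            raise FormatError(f"unsupported BIOM format: {doc.get('format')!r}")
        asv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(sample_ids), len(asv_ids)), dtype=np.int64)
        if doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                mat[j, i] = v  # BIOM rows are observations
        else:
            mat[:] = np.asarray(doc["data"], dtype=np.int64).T
        return validate_count_table(pd.DataFrame(mat, index=sample_ids, columns=asv_ids))
    raise ValueError(f"unknown count-table format: {fmt!r}")


def write_count_table(table: pd.DataFrame, path, format: str | None = None) -> None:
    """Write a count table as TSV or minimal BIOM-JSON (bit-stable output)."""
    table = validate_count_table(table)
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        table.to_csv(path, sep="\t")
        return
    if fmt == "biom-json":
        values = table.to_numpy().T  # observations in rows
        nz = np.argwhere(values != 0)
        doc = {
            "id": "gutshift-count-table",
            "format": _BIOM_FORMAT,
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "gutshift",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [int(values.shape[0]), int(values.shape[1])],
            "rows": [{"id": str(a), "metadata": None} for a in table.columns],
            "columns": [{"id": str(s), "metadata": None} for s in table.index],
            "data": [[int(i), int(j), int(values[i, j])] for i, j in nz],
        }
        path.write_text(json.dumps(doc, separators=(",", ":")) + "\n")
        return
    raise ValueError(f"unknown count-table format: {fmt!r}")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; branch lengths are required downstream."""
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


SITE_ORDER = ("rural", "urban", "amsterdam")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV; the ``site`` column becomes an ordered
    categorical on the migration axis rural < urban < amsterdam."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if "site" in meta.columns:
        meta["site"] = pd.Categorical(meta["site"], categories=SITE_ORDER, ordered=True)
        if meta["site"].isna().any():
            bad = meta.index[meta["site"].isna()].tolist()
            raise FormatError(f"missing/unknown site for samples: {bad[:10]}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")
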
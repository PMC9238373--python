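"""Readers and writers for the interchange formats.

Feature tables travel as TSV (features as rows, the dominant microbiome
export convention, with a transpose flag) or BIOM 2.1 HDF5; trees as
newick; sample metadata as TSV with the sample id in the first column;
distance matrices as labeled square TSV; ordinations in the standard
ordination-results text format.  Internally tables are samples x features
pandas DataFrames.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse
from skbio import DistanceMatrix, OrdinationResults

from .phylo import Phylogeny, parse_newick

logger = logging.getLogger("phylorpca")

__all__ = [
    "read_table",
    "write_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_ordination",
    "write_ordination",
    "filter_features",
    "write_manifest",
]


def filter_features(
    table: pd.DataFrame, min_feature_count: int, inclusive: bool = False
) -> pd.DataFrame:
    """Drop low-total features; strict ``>`` unless ``inclusive`` (``>=``)."""
    totals = table.sum(axis=0)
    keep = totals >= min_feature_count if inclusive else totals > min_feature_count
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "min_feature_count=%d removed %d of %d features",
            min_feature_count,
            n_removed,
            table.shape[1],
        )
    return table.loc[:, keep]


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        counts = pd.Series(ids).value_counts()
        dupes = sorted(counts.index[counts > 1])
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


def read_table(
    path: str | Path,
    format: str | None = None,
    min_feature_count: int = 0,
    inclusive: bool = False,
    transpose: bool = False,
) -> pd.DataFrame:
    """Read a count table as a samples x features DataFrame.

    ``format`` is ``"biom"`` or ``"tsv"``; inferred from the suffix when
    omitted.  TSV tables are features-as-rows unless ``transpose``.
    """
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix.lower() == ".biom" else "tsv"
    if format == "biom":
        table = _read_biom(path)
    elif format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        _check_unique(header, "column")  # pandas would silently mangle dupes
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
        table = df if transpose else df.T
    else:
        raise ValueError(f"unknown table format {format!r}")
    _check_unique(table.index, "sample")
    _check_unique(table.columns, "feature")
    if (table.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if min_feature_count > 0:
        table = filter_features(table, min_feature_count, inclusive=inclusive)
    return table


def write_table(table: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a samples x features table as TSV (features as rows) or BIOM."""
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix.lower() == ".biom" else "tsv"
    if format == "tsv":
        out = table.T
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown table format {format!r}")


# -- BIOM 2.1 (HDF5) ---------------------------------------------------------

def _read_biom(path: Path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    return pd.DataFrame(mat.toarray().T, index=sample_ids, columns=obs_ids)


def _write_biom(table: pd.DataFrame, path: Path) -> None:
    obs = sparse.csr_matrix(table.T.to_numpy(dtype=float))  # observations x samples
    samp = sparse.csr_matrix(table.to_numpy(dtype=float))  # samples x observations
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = (2, 1)
        f.attrs["generated-by"] = "phylorpca"
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()
        f.attrs["shape"] = (table.shape[1], table.shape[0])
        f.attrs["nnz"] = int(obs.nnz)
        for name, ids, mat in (
            ("observation", list(table.columns), obs),
            ("sample", list(table.index), samp),
        ):
            g = f.create_group(name)
            g.create_dataset(
                "ids", data=np.array([str(i).encode() for i in ids])
            )
            m = g.create_group("matrix")
            m.create_dataset("data", data=mat.data.astype(float))
            m.create_dataset("indices", data=mat.indices.astype(np.int64))
            m.create_dataset("indptr", data=mat.indptr.astype(np.int64))
            g.create_group("metadata")
            g.create_group("group-metadata")


# -- trees, metadata, matrices, ordinations ----------------------------------

def read_tree(path: str | Path) -> Phylogeny:
    return parse_newick(Path(path).read_text())


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.write_newick() + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(meta.index, "sample")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    if out.index.name is None:
        out.index.name = "sample-id"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.write(str(path))


def read_ordination(path: str | Path) -> OrdinationResults:
    return OrdinationResults.read(str(path))


def write_ordination(ordination: OrdinationResults, path: str | Path) -> None:
    ordination.write(str(path))


def write_manifest(path: str | Path, params: dict) -> None:
    """Plain-text run manifest: one ``key<TAB>value`` line per parameter."""
    import phylorpca

    lines = [f"phylorpca-version\t{phylorpca.__version__}"]
    lines += [f"{k}\t{v}" for k, v in params.items()]
    lines.append(f"timestamp\t{datetime.datetime.now().isoformat()}")
    Path(path).write_text("\n".join(lines) + "\n")
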
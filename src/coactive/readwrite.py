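"""Readers and writers for the matrix formats the pipeline consumes and emits.

All matrices are oriented genes-as-rows, cells-as-columns.  Delimited input
expects a header of cell ids and a first column of gene ids; Matrix Market
input expects sidecar files with one gene name and one cell name per line.
Ternary matrices are written with a literal ``NA`` for the missing state.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    dup_genes = df.index[df.index.duplicated()].unique()
    if len(dup_genes):
        raise ValueError(f"duplicate gene ids: {', '.join(map(str, dup_genes[:5]))}")
    dup_cells = df.columns[df.columns.duplicated()].unique()
    if len(dup_cells):
        raise ValueError(f"duplicate cell ids: {', '.join(map(str, dup_cells[:5]))}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(f"negative count at gene {df.index[i]!r}, cell {df.columns[j]!r}")
    if not np.allclose(values, np.rint(values)):
        i, j = np.argwhere(~np.isclose(values, np.rint(values)))[0]
        raise ValueError(
            f"non-integer count at gene {df.index[i]!r}, cell {df.columns[j]!r}"
        )
    return df.astype(np.int64)


def read_counts(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x cells count matrix from CSV, TSV or Matrix Market.

    ``fmt`` defaults to the file suffix (.csv/.tsv/.mtx).  For .mtx input,
    sidecar files ``<stem>.genes.txt`` and ``<stem>.cells.txt`` next to the
    matrix supply row and column names.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in {"csv", "tsv"}:
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return _validate_counts(df)
    if fmt == "mtx":
        genes = _read_names(path.with_suffix(".genes.txt"))
        cells = _read_names(path.with_suffix(".cells.txt"))
        m = mmread(path).toarray()
        if m.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {m.shape} but sidecars name {len(genes)} genes "
                f"and {len(cells)} cells"
            )
        return _validate_counts(pd.DataFrame(m, index=genes, columns=cells))
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in {"csv", "tsv"}:
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
    elif fmt == "mtx":
        mmwrite(str(path), coo_matrix(df.to_numpy()))
        _write_names(df.index, path.with_suffix(".genes.txt"))
        _write_names(df.columns, path.with_suffix(".cells.txt"))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"sidecar name file missing: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def _write_names(names, path: Path) -> None:
    path.write_text("\n".join(map(str, names)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_cell_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (cell id, label) mapping cells to their dataset."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "label"], dtype=str)
    return df.set_index("cell")["label"]


def write_ternary(ternary: pd.DataFrame, path: str | Path) -> None:
    """Ternary TSV with integer states and literal NA for missing."""
    out = ternary.copy()
    out = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def read_ternary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return df.astype(float)


def write_fit_table(fits: dict, gene_order, path: str | Path) -> None:
    """Per-gene mixture estimates as TSV (genes lacking a fit are omitted)."""
    rows = []
    for gene in gene_order:
        fit = fits.get(gene)
        if fit is None:
            continue
        rows.append(
            {
                "gene": gene,
                "alpha": fit.alpha,
                "beta": fit.beta,
                "mu": fit.mu,
                "sigma2": fit.sigma2,
                "rho": fit.rho,
                "n_used": fit.n_used,
                "converged": fit.converged,
                "n_iter": fit.n_iter,
                "loglik": fit.loglik_trace[-1] if len(fit.loglik_trace) else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
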
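"""Readers and writers for the package's on-disk formats.

Counts travel as matrix-market with gene/cell TSV sidecars (or a dense
genes x cells CSV); spatial cell tables, truth tables and cluster labels as
TSV; image stacks as multi-page TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix


def write_counts(m: CountMatrix, outdir: str | Path, fmt: str = "mtx") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        spio.mmwrite(outdir / "counts.mtx", sparse.csr_matrix(m.counts.values))
        pd.Series(m.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(m.cells).to_csv(outdir / "cells.tsv", sep="\t", index=False, header=False)
    elif fmt == "csv":
        m.counts.to_csv(outdir / "counts.csv")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_counts(path: str | Path) -> CountMatrix:
    """Read counts from a directory (mtx + sidecars) or a dense CSV file."""
    path = Path(path)
    if path.is_dir():
        mat = spio.mmread(path / "counts.mtx").toarray().astype(np.int64)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path / "cells.tsv", sep="\t", header=None)[0]
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(cells, name="cell"))
    else:
        df = pd.read_csv(path, index_col=0)
        df.index.name = "gene"
        df.columns.name = "cell"
    return CountMatrix(df)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.astype(np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
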
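"""Gene-expression matrix container and tabular I/O.

The matrix is genes x samples, held as a pandas DataFrame with the gene
symbol as the index and one column per sample.  Missing values are NaN;
text I/O writes them as ``NA`` and accepts ``NA``, ``nan`` or empty fields.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

_NA_VALUES = ["", "NA", "na", "NaN", "nan", "null", "NULL"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a missing-value mask.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbol, columns are sample ids,
        cells are floats with NaN marking missing/invalid measurements.
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene symbol {dup!r}")
        if not self.values.columns.is_unique:
            raise FormatError("duplicate sample ids")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.index.name = "gene"

    # -- basic geometry -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across samples (NaN = missing)."""
        return self.values.loc[gene].to_numpy(dtype=float)

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes].copy())

    def missing_fraction(self) -> pd.Series:
        """Per-gene fraction of missing cells."""
        return self.values.isna().mean(axis=1)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a TSV/CSV expression table (delimiter auto-detected).

        The first column holds gene symbols; remaining columns are numeric
        sample values.
        """
        path = Path(path)
        with open(path, "r", newline="") as fh:
            sample = fh.read(8192)
        if not sample.strip():
            raise FormatError(f"{path} is empty")
        try:
            dialect = csv.Sniffer().sniff(sample.splitlines()[0], delimiters="\t,;")
            sep = dialect.delimiter
        except csv.Error:
            sep = "\t"
        df = pd.read_csv(path, sep=sep, index_col=0,
                         na_values=_NA_VALUES, keep_default_na=False)
        non_numeric = [c for c in df.columns
                       if not np.issubdtype(df[c].dtype, np.number)
                       and not df[c].isna().all()]
        if non_numeric:
            raise FormatError(
                f"non-numeric sample column(s) {non_numeric[:3]} in {path}")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene symbol per line; '#' comment lines and blanks ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
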
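"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd


class ExpressionMatrix:
    """Genes x samples expression matrix on the log-CPM scale.

    Thin wrapper over a numpy array plus ordered, unique gene and sample
    identifiers.  Rows are genes, columns are samples, mirroring the usual
    bulk RNA-seq convention.
    """

    def __init__(self, values, gene_ids, sample_ids, check_finite: bool = True):
        values = np.asarray(values, dtype=float)
        gene_ids = list(map(str, gene_ids))
        sample_ids = list(map(str, sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(gene_ids)} genes "
                f"x {len(sample_ids)} samples"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample IDs")
        if check_finite and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids),
                                list(self.sample_ids), check_finite=False)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids),
                                list(sample_ids), check_finite=False)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(self.values[idx, :], list(gene_ids),
                                list(self.sample_ids), check_finite=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), df.index, df.columns)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_dataframe(df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"
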
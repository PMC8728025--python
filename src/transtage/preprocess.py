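"""Label assignment, gene ordering, splitting, scaling and batch correction.

All statistics that must be frozen for out-of-sample projection (gene order,
per-gene training mean/sd) live in small dataclasses so they can be stored
with the trained model and re-applied verbatim to external cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

AD, CN, OTHER = "AD", "CN", "OTHER"

_LABEL_COLUMNS = ("cogdx", "braaksc", "ceradsc")


def assign_diagnosis(phenotypes: pd.DataFrame) -> pd.Series:
    """Assign the AD / CN / OTHER terminus labels from clinical phenotypes.

    AD: final clinical diagnosis of Alzheimer's dementia with confirmatory
    neuropathology (cogdx = 4, Braak stage >= 4, CERAD <= 2).
    CN: no cognitive impairment and at most modest pathology (cogdx = 1,
    Braak <= 3, CERAD >= 3).  Everything else, including records with a
    missing value in any rule field, is OTHER.
    """
    missing = [c for c in _LABEL_COLUMNS if c not in phenotypes.columns]
    if missing:
        raise KeyError(f"phenotype table lacks required columns: {missing}")
    cogdx = pd.to_numeric(phenotypes["cogdx"], errors="coerce")
    braak = pd.to_numeric(phenotypes["braaksc"], errors="coerce")
    cerad = pd.to_numeric(phenotypes["ceradsc"], errors="coerce")
    labels = pd.Series(OTHER, index=phenotypes.index, name="diagnosis")
    is_ad = (cogdx == 4) & (braak >= 4) & (cerad <= 2)
    is_cn = (cogdx == 1) & (braak <= 3) & (cerad >= 3)
    labels[is_ad.fillna(False)] = AD
    labels[is_cn.fillna(False)] = CN
    return labels


def sort_genes_by_variance(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Reorder genes by descending log-CPM variance (stable on ties)."""
    if expr.n_samples < 2:
        raise ValueError("variance undefined with fewer than 2 samples")
    var = expr.values.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")
    return ExpressionMatrix(expr.values[order], [expr.gene_ids[i] for i in order],
                            list(expr.sample_ids), check_finite=False)


@dataclass
class SplitIndex:
    train_ids: List[str]
    test_ids: List[str]
    class_counts: dict
    seed: int


def split_train_test(labels: pd.Series, train_frac: float = 0.8,
                     seed: int = 0) -> SplitIndex:
    """Stratified random split of the AD/CN termini samples.

    Per class, ``round(train_frac * n_class)`` samples go to training, so the
    class balance of the termini is preserved within one sample.  OTHER
    samples are excluded entirely.
    """
    termini = labels[labels.isin([AD, CN])]
    counts = termini.value_counts().to_dict()
    if counts.get(AD, 0) < 2 or counts.get(CN, 0) < 2:
        raise ValueError("need at least 2 samples in each terminus class")
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    class_counts = {}
    for cls in (AD, CN):
        ids = list(termini.index[termini == cls])
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        train_ids += [ids[i] for i in perm[:n_train]]
        test_ids += [ids[i] for i in perm[n_train:]]
        class_counts[cls] = {"train": n_train, "test": len(ids) - n_train}
    if not test_ids:
        warnings.warn("train_frac leaves an empty test set")
    return SplitIndex(train_ids, test_ids, class_counts, seed)


@dataclass
class ScalingStats:
    """Per-gene training mean/sd frozen for Z-scaling, with gene order."""

    gene_ids: List[str]
    mean: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd},
                            index=self.gene_ids)


def fit_scaler(expr_train: ExpressionMatrix) -> ScalingStats:
    """Per-gene mean and sd (n-1 denominator) over the training samples.

    Constant genes get sd := 1 so their Z-scores are 0 rather than NaN.
    """
    mean = expr_train.values.mean(axis=1)
    sd = expr_train.values.std(axis=1, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    return ScalingStats(list(expr_train.gene_ids), mean, sd)


def apply_scaler(expr: ExpressionMatrix, stats: ScalingStats) -> ExpressionMatrix:
    if list(expr.gene_ids) != list(stats.gene_ids):
        raise ValueError("gene order differs from the scaler's; "
                         "run harmonize_genes first")
    z = (expr.values - stats.mean[:, None]) / stats.sd[:, None]
    return ExpressionMatrix(z, list(expr.gene_ids), list(expr.sample_ids),
                            check_finite=False)


def harmonize_genes(expr: ExpressionMatrix, reference_gene_ids: Sequence[str],
                    fill_values: Optional[pd.Series] = None,
                    return_info: bool = False):
    """Reorder genes to the reference order used at training time.

    Genes absent from ``expr`` are inserted as constant filler rows (the
    training-mean surrogate when ``fill_values`` is given, else 0) so that
    they contribute Z = 0 after scaling.  Extra genes are dropped.  If fewer
    than half of the reference genes are present the projection is refused.
    """
    reference_gene_ids = list(reference_gene_ids)
    if not reference_gene_ids:
        raise ValueError("empty reference gene list")
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    present = [g for g in reference_gene_ids if g in pos]
    if len(present) < 0.5 * len(reference_gene_ids):
        raise ValueError(
            f"only {len(present)}/{len(reference_gene_ids)} reference genes "
            "present; projection would be meaningless")
    n_extra = expr.n_genes - len(present)
    missing = [g for g in reference_gene_ids if g not in pos]
    out = np.empty((len(reference_gene_ids), expr.n_samples))
    for row, g in enumerate(reference_gene_ids):
        if g in pos:
            out[row] = expr.values[pos[g]]
        else:
            fill = 0.0
            if fill_values is not None:
                fill = float(fill_values.loc[g])
            out[row] = fill
    if missing:
        warnings.warn(f"{len(missing)} reference genes missing; "
                      "inserted as filler rows")
    if n_extra:
        warnings.warn(f"dropped {n_extra} genes absent from the reference")
    result = ExpressionMatrix(out, reference_gene_ids, list(expr.sample_ids),
                              check_finite=False)
    if return_info:
        return result, {"missing": missing, "n_dropped": n_extra}
    return result


def combat_correct(expr: ExpressionMatrix, batch: pd.Series) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch correction (ComBat, intercept-only).

    Delegates to scanpy's ComBat implementation with no biological
    covariates in the design.  A single batch is returned unchanged with a
    warning; a batch with fewer than 2 samples is an error.
    """
    batch = pd.Series(batch).reindex(expr.sample_ids)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    counts = batch.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    if len(counts) < 2:
        warnings.warn("single batch: ComBat is the identity")
        return expr.copy()

    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=np.asarray(expr.values.T, dtype=np.float64),
        obs=pd.DataFrame({"batch": batch.astype(str).values},
                         index=expr.sample_ids),
        var=pd.DataFrame(index=expr.gene_ids),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch")
    corrected = np.asarray(adata.X, dtype=float).T
    return ExpressionMatrix(corrected, list(expr.gene_ids),
                            list(expr.sample_ids), check_finite=False)
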
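"""Linear models of biomarkers on the severity index plus covariates.

Each biomarker is regressed on SI and the clinical covariates in a declared
order; the model reports a signed correlation (sign of the SI coefficient
times the square root of R^2) and a sequential (Type-I) ANOVA decomposition
giving the proportion of variance explained by each predictor when entered
in order, SI first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: biomarkers that are log-transformed before regression
LOG_TRANSFORMED = ("gpath", "amyloid", "plaq_d", "plaq_n", "nft", "tangles")

#: default covariate list with declared types (ordinal/semi-quantitative
#: measures treated as numeric; sex, race and Lewy-body diagnosis categorical)
DEFAULT_COVARIATES: List[Tuple[str, str]] = [
    ("age_death", "numeric"), ("educ", "numeric"), ("msex", "categorical"),
    ("race7", "categorical"), ("apoe4", "numeric"), ("RIN", "numeric"),
    ("PMI", "numeric"), ("r_pd", "numeric"), ("r_stroke", "numeric"),
    ("dlbdx", "categorical"), ("hspath_typ", "numeric"),
    ("arteriol_scler", "numeric"),
]


@dataclass
class RegressionSpec:
    response: str
    predictors: List[Tuple[str, str]]  # ordered (name, "numeric"|"categorical")
    log_response: bool = False
    cerad_recode: bool = False         # MSBB-style CERAD 1<->4, 2<->3
    sample_filter: str = "all"         # "all" | "exclude-termini"


def recode_cerad_msbb(values: pd.Series) -> pd.Series:
    """Map the MSBB CERAD coding (1=Normal ... 4=Possible AD) onto the
    ROSMAP-style semi-quantitative scale (1=Definite AD ... 4=Normal)."""
    return values.map({1: 4, 2: 3, 3: 2, 4: 1})


def build_design(phenotypes: pd.DataFrame, spec: RegressionSpec,
                 extra_columns: Optional[pd.DataFrame] = None):
    """Build the response vector and blockwise design matrix.

    Complete-case rows only.  Categorical predictors expand to dummy columns
    with the first sorted level as reference; responses flagged for log
    transform use log(x + offset) with offset 0 when min > 0, else 1.
    Predictors absent from the table are dropped with a warning.

    Returns (X, y, blocks, n_dropped) where blocks maps each predictor term
    to its design columns in entry order.
    """
    table = phenotypes.copy()
    if extra_columns is not None:
        table = table.join(extra_columns, how="inner")
    if spec.response not in table.columns:
        raise KeyError(f"response '{spec.response}' not in table")
    kept = []
    for name, kind in spec.predictors:
        if name not in table.columns:
            warnings.warn(f"predictor '{name}' absent; dropped")
            continue
        kept.append((name, kind))

    cols = [spec.response] + [n for n, _ in kept]
    data = table[cols].apply(pd.to_numeric, errors="coerce")
    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)

    y = data[spec.response].astype(float)
    if spec.cerad_recode:
        y = recode_cerad_msbb(y.astype(int)).astype(float)
    if spec.log_response:
        offset = 0.0 if (y.min() > 0) else 1.0
        y = np.log(y + offset)
    if y.nunique() < 2:
        raise ValueError(f"response '{spec.response}' constant after filtering")

    blocks: List[Tuple[str, List[str]]] = []
    pieces = {}
    for name, kind in kept:
        if kind == "categorical":
            levels = sorted(data[name].unique())
            dummies = pd.get_dummies(
                pd.Categorical(data[name], categories=levels),
                prefix=name, drop_first=True, dtype=float)
            dummies.index = data.index
            if dummies.shape[1] == 0:
                warnings.warn(f"categorical '{name}' has one level; dropped")
                continue
            pieces[name] = dummies
            blocks.append((name, list(dummies.columns)))
        else:
            pieces[name] = data[[name]].astype(float)
            blocks.append((name, [name]))
    X = pd.concat([pd.Series(1.0, index=data.index, name="const")]
                  + [pieces[n] for n, _ in blocks], axis=1)
    return X, y, blocks, n_dropped


@dataclass
class OLSFit:
    """Classical least-squares fit with the blockwise term structure kept."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    signed_r: float
    nobs: int
    df_resid: int
    blocks: List[Tuple[str, List[str]]]
    X: pd.DataFrame
    y: pd.Series
    ssr: float
    ess: float
    tss: float
    n_dropped: int = 0

    @property
    def si_beta(self) -> float:
        term, cols = self.blocks[0]
        return float(self.params[cols[0]])

    @property
    def si_pvalue(self) -> float:
        term, cols = self.blocks[0]
        return float(self.pvalues[cols[0]])


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop linearly dependent columns (QR with pivoting)."""
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank == X.shape[1]:
        return X
    keep = []
    cur = np.empty((A.shape[0], 0))
    for j, col in enumerate(X.columns):
        trial = np.column_stack([cur, A[:, j]])
        if np.linalg.matrix_rank(trial) > cur.shape[1]:
            keep.append(col)
            cur = trial
    warnings.warn(f"dropped aliased columns: "
                  f"{sorted(set(X.columns) - set(keep))}")
    return X[keep]


def fit_ols(X: pd.DataFrame, y: pd.Series,
            blocks: Optional[List[Tuple[str, List[str]]]] = None,
            n_dropped: int = 0) -> OLSFit:
    """Ordinary least squares with classical standard errors.

    The signed model correlation is sign(SI coefficient) * sqrt(R^2), with
    SI taken as the first predictor block.
    """
    X = _drop_aliased(X)
    if blocks is None:
        blocks = [(c, [c]) for c in X.columns if c != "const"]
    else:
        blocks = [(t, [c for c in cols if c in X.columns])
                  for t, cols in blocks]
        blocks = [(t, cols) for t, cols in blocks if cols]
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more parameters than observations")
    res = sm.OLS(np.asarray(y, dtype=float),
                 np.asarray(X, dtype=float)).fit()
    params = pd.Series(res.params, index=X.columns)
    first_cols = blocks[0][1]
    signed_r = float(np.sign(params[first_cols[0]]) * np.sqrt(res.rsquared))
    return OLSFit(
        params=params,
        bse=pd.Series(res.bse, index=X.columns),
        tvalues=pd.Series(res.tvalues, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        rsquared=float(res.rsquared), signed_r=signed_r,
        nobs=int(res.nobs), df_resid=int(res.df_resid),
        blocks=blocks, X=X, y=pd.Series(np.asarray(y, dtype=float),
                                        index=X.index),
        ssr=float(res.ssr), ess=float(res.ess),
        tss=float(res.ess + res.ssr), n_dropped=n_dropped)


def sequential_anova(fit: OLSFit) -> pd.DataFrame:
    """Type-I (sequential) ANOVA over the fit's predictor blocks.

    Terms enter in declared order (a categorical enters as its whole dummy
    block); SS_j is the drop in residual SS when the block is added;
    PVE_j = SS_j / total SS.  F uses the full-model MSE.
    """
    Xfull = fit.X.to_numpy(dtype=float)
    y = fit.y.to_numpy(dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    mse = fit.ssr / fit.df_resid if fit.df_resid > 0 else np.nan

    def rss_of(cols: List[str]) -> Tuple[float, int]:
        A = fit.X[cols].to_numpy(dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        return float(resid @ resid), int(rank)

    rows = []
    cols = ["const"]
    rss_prev, rank_prev = rss_of(cols)
    for term, block_cols in fit.blocks:
        cols = cols + block_cols
        rss_cur, rank_cur = rss_of(cols)
        ss = rss_prev - rss_cur
        df = rank_cur - rank_prev
        if df > 0 and np.isfinite(mse) and mse > 0:
            F = (ss / df) / mse
            p = float(stats.f.sf(F, df, fit.df_resid))
        else:
            F, p = np.nan, np.nan
        rows.append({"term": term, "df": df, "sum_sq": ss, "F": F,
                     "p": p, "pve": ss / tss if tss > 0 else np.nan})
        rss_prev, rank_prev = rss_cur, rank_cur
    rows.append({"term": "residual", "df": fit.df_resid, "sum_sq": rss_prev,
                 "F": np.nan, "p": np.nan,
                 "pve": rss_prev / tss if tss > 0 else np.nan})
    return pd.DataFrame(rows).set_index("term")


def associate_si(si: pd.Series, phenotypes: pd.DataFrame,
                 biomarkers: Sequence[str],
                 covariates: Optional[List[Tuple[str, str]]] = None,
                 sample_filter: str = "all",
                 termini_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """One OLS + sequential ANOVA per biomarker; tidy result grid.

    ``sample_filter='exclude-termini'`` drops the AD/CN-labelled samples
    (``termini_ids``) used to train the classifier, mirroring the
    sensitivity analysis outside the training termini.
    """
    if covariates is None:
        covariates = [cv for cv in DEFAULT_COVARIATES
                      if cv[0] in phenotypes.columns]
    table = phenotypes.copy()
    shared = table.index.intersection(si.index)
    table = table.loc[shared]
    si = si.loc[shared]
    if sample_filter == "exclude-termini":
        if termini_ids is None:
            raise ValueError("exclude-termini filter needs termini_ids")
        keep = [i for i in table.index if i not in set(termini_ids)]
        table = table.loc[keep]
        si = si.loc[keep]
    elif sample_filter != "all":
        raise ValueError(f"unknown sample filter '{sample_filter}'")

    if si.nunique() < 2:
        raise ValueError("SI is constant over the selected samples; "
                         "no association can be estimated")
    si_frame = si.rename("SI").to_frame()
    rows = []
    for biomarker in biomarkers:
        if biomarker not in table.columns:
            warnings.warn(f"biomarker '{biomarker}' absent; skipped")
            continue
        spec = RegressionSpec(
            response=biomarker,
            predictors=[("SI", "numeric")] + [cv for cv in covariates
                                              if cv[0] != biomarker],
            log_response=biomarker in LOG_TRANSFORMED,
            sample_filter=sample_filter)
        try:
            X, y, blocks, n_drop = build_design(table, spec,
                                                extra_columns=si_frame)
            fit = fit_ols(X, y, blocks, n_dropped=n_drop)
        except ValueError as err:
            warnings.warn(f"biomarker '{biomarker}' skipped: {err}")
            continue
        anova = sequential_anova(fit)
        row = {"biomarker": biomarker, "signed_R": fit.signed_r,
               "R2": fit.rsquared, "SI_beta": fit.si_beta,
               "SI_p": fit.si_pvalue, "n": fit.nobs,
               "n_dropped": n_drop}
        for term in anova.index:
            if term != "residual":
                row[f"pve_{term}"] = float(anova.loc[term, "pve"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("biomarker")
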
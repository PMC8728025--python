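"""Cell-type marker signatures as smooth functions of the severity index.

Each marker gene's expression is smoothed against SI with a natural cubic
smoothing spline whose penalty is chosen so the effective degrees of freedom
(trace of the smoother matrix) hit a target (default 3).  Per cell type the
(weighted) mean of the smoothed markers is min-max normalized to [0, 1] and
evaluated on an equally spaced SI grid; curves can be computed separately
within each sex stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .containers import ExpressionMatrix


@dataclass
class SmootherConfig:
    df: float = 3.0
    grid_size: int = 100

    def validate(self) -> None:
        if self.df < 2:
            raise ValueError("df must be >= 2")


@dataclass
class SignatureCurve:
    cell_type: str
    stratum: str              # "all" | "male" | "female"
    si_grid: np.ndarray
    values: np.ndarray        # normalized to [0, 1]
    constant: bool = False


class SplineSmoother:
    """Natural cubic smoothing spline with a target effective df.

    Uses the Reinsch formulation: for sorted unique abscissae x with
    duplicate observations averaged under weights w, the fit solves

        (R + lam * D W^{-1} D^T) gamma = D ybar,
        f = ybar - lam * W^{-1} D^T gamma,

    with D the second-difference operator and R the natural-spline band
    matrix.  Because D annihilates linear functions, straight lines are
    reproduced to machine precision at any penalty.  A single generalized
    eigendecomposition of (D W^{-1} D^T, R) gives the effective degrees of
    freedom df(lam) = 2 + sum_i 1/(1 + lam * theta_i) in closed form, so
    the penalty matching the target df is found by bisection to 0.01 df.
    The smoother is linear in the response.
    """

    def __init__(self, x: np.ndarray, config: SmootherConfig = SmootherConfig()):
        config.validate()
        x = np.asarray(x, dtype=float)
        if len(x) < 10:
            raise ValueError("need >= 10 samples with SI")
        ux, inverse, counts = np.unique(x, return_inverse=True,
                                        return_counts=True)
        if config.df >= len(ux):
            raise ValueError("df must be below the number of distinct "
                             "SI values")
        self.config = config
        self.x = x
        self.ux = ux
        self._inverse = inverse
        self._w = counts.astype(float)

        self._D, self._R = self._difference_operators(ux)
        DtW = self._D / self._w[None, :]        # D W^{-1}
        B = DtW @ self._D.T                     # D W^{-1} D^T
        from scipy.linalg import eigh
        theta = eigh((B + B.T) / 2, (self._R + self._R.T) / 2,
                     eigvals_only=True)
        self._theta = np.clip(theta, 0.0, None)
        self.lam = self._solve_lambda(config.df)
        from scipy.linalg import cho_factor
        self._chol = cho_factor(self._R + self.lam * B)

    @staticmethod
    def _difference_operators(x: np.ndarray):
        n = len(x)
        h = np.diff(x)
        if (h <= 0).any():
            raise ValueError("abscissae must be strictly increasing")
        D = np.zeros((n - 2, n))
        R = np.zeros((n - 2, n - 2))
        for i in range(n - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            R[i, i] = (h[i] + h[i + 1]) / 3.0
            if i > 0:
                R[i, i - 1] = R[i - 1, i] = h[i] / 6.0
        return D, R

    def df_of(self, lam: float) -> float:
        return float(2.0 + np.sum(1.0 / (1.0 + lam * self._theta)))

    def _solve_lambda(self, target_df: float, tol: float = 0.01) -> float:
        lo, hi = 1e-14, 1e14
        if self.df_of(lo) < target_df - tol:
            return lo
        if self.df_of(hi) > target_df + tol:
            return hi
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            df = self.df_of(mid)
            if abs(df - target_df) <= tol:
                return mid
            if df > target_df:
                lo = mid
            else:
                hi = mid
        return mid

    def smooth(self, y: np.ndarray) -> np.ndarray:
        """Fitted values at the unique abscissae."""
        from scipy.linalg import cho_solve

        y = np.asarray(y, dtype=float)
        ybar = np.bincount(self._inverse, weights=y) / self._w
        gamma = cho_solve(self._chol, self._D @ ybar)
        return ybar - self.lam * (self._D.T @ gamma) / self._w

    def curve(self, y: np.ndarray,
              grid: Optional[np.ndarray] = None) -> np.ndarray:
        """Smoothed values on an equally spaced grid over the SI range."""
        if grid is None:
            grid = self.grid()
        fitted = self.smooth(y)
        interp = CubicSpline(self.ux, fitted, bc_type="natural")
        return interp(grid)

    def grid(self) -> np.ndarray:
        return np.linspace(self.ux[0], self.ux[-1], self.config.grid_size)


def smooth_gene_vs_si(expression: np.ndarray, si: np.ndarray,
                      config: SmootherConfig = SmootherConfig()):
    """Smooth one gene's expression against SI; returns (grid, values)."""
    smoother = SplineSmoother(si, config)
    grid = smoother.grid()
    return grid, smoother.curve(np.asarray(expression, dtype=float), grid)


def _normalize01(values: np.ndarray):
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:
        return np.full_like(values, 0.5), True
    return (values - lo) / (hi - lo), False


def signature_curve(markers: Dict[str, Sequence[str]],
                    expr: ExpressionMatrix, si: pd.Series,
                    config: SmootherConfig = SmootherConfig(),
                    marker_weights: Optional[Dict[str, Dict[str, float]]] = None,
                    stratum: str = "all") -> Dict[str, SignatureCurve]:
    """Smoothed, [0, 1]-normalized signature per cell type.

    Markers absent from the expression matrix are dropped with a warning;
    marker weights default to uniform.  A constant signature is flagged and
    returned as the 0.5 curve.
    """
    shared = [s for s in expr.sample_ids if s in si.index]
    sub = expr.subset_samples(shared)
    si_vals = si.loc[shared].to_numpy(dtype=float)
    smoother = SplineSmoother(si_vals, config)
    grid = smoother.grid()
    gene_pos = {g: i for i, g in enumerate(sub.gene_ids)}

    curves = {}
    for cell_type, genes in markers.items():
        present = [g for g in genes if g in gene_pos]
        if not present:
            raise ValueError(f"no markers for '{cell_type}' present")
        if len(present) < len(genes):
            warnings.warn(f"{cell_type}: {len(genes) - len(present)} "
                          "markers absent; dropped")
        wmap = (marker_weights or {}).get(cell_type, {})
        ws = np.array([wmap.get(g, 1.0) for g in present], dtype=float)
        ws = ws / ws.sum()
        mean_curve = np.zeros_like(grid)
        for g, w in zip(present, ws):
            mean_curve += w * smoother.curve(sub.values[gene_pos[g]], grid)
        values, constant = _normalize01(mean_curve)
        if constant:
            warnings.warn(f"{cell_type}: constant signature; set to 0.5")
        curves[cell_type] = SignatureCurve(cell_type, stratum, grid, values,
                                           constant)
    return curves


def stratify_by_sex(markers: Dict[str, Sequence[str]],
                    expr: ExpressionMatrix, si: pd.Series,
                    phenotypes: pd.DataFrame,
                    config: SmootherConfig = SmootherConfig()
                    ) -> Dict[str, Dict[str, SignatureCurve]]:
    """Signature curves computed separately within each sex stratum.

    Strata with fewer than 10 samples are skipped with a warning.  Each
    stratum is smoothed and normalized on its own SI range.
    """
    if "msex" not in phenotypes.columns:
        raise KeyError("phenotype table lacks 'msex'")
    out: Dict[str, Dict[str, SignatureCurve]] = {}
    for value, name in ((1, "male"), (0, "female")):
        ids = [s for s in expr.sample_ids
               if s in phenotypes.index and phenotypes.loc[s, "msex"] == value
               and s in si.index]
        if len(ids) < 10:
            warnings.warn(f"stratum '{name}' has {len(ids)} samples; skipped")
            continue
        sub = expr.subset_samples(ids)
        out[name] = signature_curve(markers, sub, si.loc[ids], config,
                                    stratum=name)
    return out


def curves_to_frame(curves) -> pd.DataFrame:
    """Tidy (cell_type, stratum, si, value) table for CSV export."""
    rows = []
    items = []
    if isinstance(curves, dict) and curves and \
            isinstance(next(iter(curves.values())), dict):
        for stratum_curves in curves.values():
            items.extend(stratum_curves.values())
    else:
        items.extend(curves.values())
    for c in items:
        for si_val, v in zip(c.si_grid, c.values):
            rows.append({"cell_type": c.cell_type, "stratum": c.stratum,
                         "si": si_val, "value": v})
    return pd.DataFrame(rows)
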
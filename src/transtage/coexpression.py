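"""Index-gene selection and weighted co-expression module analysis.

The first-layer gene weights of the trained network form a bimodal
distribution on the log scale; the valley between the two modes separates
"index genes" (high weight, carrying the staging signal) from the inert
bulk.  Index genes are then organised into unsigned co-expression modules:
soft-thresholded |Pearson| adjacency at a power chosen by the scale-free
topology criterion, topological overlap similarity, average-linkage
clustering with a simplified dynamic tree cut, eigengene-based module
merging, and module-trait correlation plus Fisher-exact set enrichment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = 0


# ------------------------------------------------------------- weight cut

@dataclass
class WeightCut:
    threshold: float
    method: str                      # "valley" | "manual"
    unimodal_fallback: bool = False
    grid: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None
    modes: Optional[List[float]] = None


def detect_weight_cut(weights: pd.Series, method: str = "valley",
                      manual_threshold: Optional[float] = None,
                      floor: float = 1e-8) -> WeightCut:
    """Locate the cut separating the bimodal log-weight distribution.

    Valley method: Gaussian KDE (Silverman bandwidth) of log10(weight +
    floor); the threshold is the deepest local minimum between the two
    highest density modes.  If the density is unimodal the method degrades
    to the manual threshold (or the median weight) with a prominent flag.
    """
    w = np.asarray(weights, dtype=float)
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method needs manual_threshold")
        return WeightCut(float(manual_threshold), "manual")
    if len(w) < 100:
        raise ValueError("need >= 100 genes for the valley method")
    if np.allclose(w, w[0]):
        raise ValueError("all weights equal; no cut exists")

    lw = np.log10(w + floor)
    kde = stats.gaussian_kde(lw, bw_method="silverman")
    grid = np.linspace(lw.min(), lw.max(), 512)
    dens = kde(grid)
    # local maxima, with one-sided tests at the boundaries: rows shrunk to
    # exactly zero pile up at the left edge of the grid.  Modes below 5% of
    # the peak density are noise, not modes.
    maxima = [i for i in range(1, 511)
              if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]]
    if dens[0] > dens[1]:
        maxima.insert(0, 0)
    if dens[511] > dens[510]:
        maxima.append(511)
    maxima = [i for i in maxima if dens[i] >= 0.05 * dens.max()]
    if len(maxima) < 2:
        warnings.warn("weight distribution looks unimodal; "
                      "falling back to a manual/default threshold")
        thr = manual_threshold if manual_threshold is not None \
            else float(np.median(w))
        return WeightCut(float(thr), "valley", unimodal_fallback=True,
                         grid=grid, density=dens)
    top2 = sorted(sorted(maxima, key=lambda i: dens[i])[-2:])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    threshold = float(10 ** grid[valley] - floor)
    return WeightCut(threshold, "valley", grid=grid, density=dens,
                     modes=[float(10 ** grid[i] - floor) for i in top2])


def select_index_genes(weights: pd.Series, cut: WeightCut) -> List[str]:
    """Genes with weight above the cut, in descending weight order."""
    sel = weights[weights > cut.threshold].sort_values(ascending=False)
    if sel.empty:
        raise ValueError("no genes above the weight cut")
    return list(sel.index)


# ------------------------------------------------------------- network

@dataclass
class CoexprConfig:
    soft_power: int = 4
    min_module_size: int = 30
    deep_split: int = 4
    merge_height: float = 0.35
    candidate_powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12)
    target_r2: float = 0.8
    use_tom: bool = True


def _correlation(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant gene in expression matrix")
    return np.corrcoef(X)


def adjacency_matrix(X: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta with zeroed diagonal."""
    A = np.abs(_correlation(X)) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> Tuple[float, float]:
    """Signed scale-free topology fit index.

    Bins connectivity, regresses log10 p(k) on log10 mean(k) per bin and
    returns (signed R^2, slope); the sign is negative when the slope is
    positive (not scale-free).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _inter, r, _p, _se = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2), float(slope)


def pick_soft_power(X: np.ndarray,
                    candidates: Sequence[int] = CoexprConfig.candidate_powers,
                    target_r2: float = 0.8) -> Tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches the target R^2.

    Falls back to the argmax power with a warning when no candidate reaches
    the target.  Constant genes are excluded up front.
    """
    X = np.asarray(X, dtype=float)
    keep = X.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"excluded {int((~keep).sum())} constant genes")
        X = X[keep]
    if X.shape[0] < 50:
        raise ValueError("need >= 50 genes to assess scale-free topology")
    cor = np.abs(_correlation(X))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in candidates:
        k = (cor ** beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": beta, "sft_r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    ok = table[table["sft_r2"] >= target_r2]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        warnings.warn("no candidate power reaches the scale-free target; "
                      "using the best fit")
        beta = int(table.loc[table["sft_r2"].idxmax(), "power"])
    return beta, table


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix from an (diagonal-zero) adjacency."""
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return tom


def _best_cut(Z: np.ndarray, n_leaves: int, min_size: int):
    """Scan dendrogram cut heights for the partition with the most
    min-size-respecting clusters.

    Among the heights realizing the maximal module count, the cut is taken
    at the midpoint of the widest contiguous interval of such heights:
    high enough that modules have collected their weakly attached members,
    low enough that genes joining only near the root stay unassigned.
    """
    heights = np.unique(Z[:, 2])
    cuts = np.concatenate([(heights[:-1] + heights[1:]) / 2,
                           [heights[-1] + 1.0]])
    n_valid = np.empty(len(cuts), dtype=int)
    for i, h in enumerate(cuts):
        labels = hierarchy.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)
        n_valid[i] = int((sizes >= min_size).sum())
    top = n_valid.max()
    if top == 0:
        return np.zeros(n_leaves, dtype=int)
    # widest contiguous run of cut heights achieving the top module count
    best_run, run_start = None, None
    for i in range(len(cuts) + 1):
        if i < len(cuts) and n_valid[i] == top:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            span = cuts[i - 1] - cuts[run_start]
            if best_run is None or span > best_run[0]:
                best_run = (span, run_start, i - 1)
            run_start = None
    _, lo, hi = best_run
    h_cut = (cuts[lo] + cuts[hi]) / 2.0
    return hierarchy.fcluster(Z, t=h_cut, criterion="distance")


def _dynamic_cut(Z: np.ndarray, D: np.ndarray, min_size: int,
                 deep_split: int) -> np.ndarray:
    """Simplified dynamic tree cut.

    A scan over cut heights picks the partition with the most clusters of
    at least ``min_size`` genes; each resulting cluster is then recursively
    re-scanned (depth bounded by ``deep_split``) to peel off well-separated
    sub-modules.  Genes in clusters below the minimum size are unassigned.
    """
    n = D.shape[0]
    labels = _best_cut(Z, n, min_size)

    def refine(idx: np.ndarray, depth: int) -> List[np.ndarray]:
        if depth <= 0 or len(idx) < 2 * min_size:
            return [idx]
        sub = D[np.ix_(idx, idx)]
        subZ = hierarchy.linkage(squareform(sub, checks=False),
                                 method="average")
        sub_labels = _best_cut(subZ, len(idx), min_size)
        parts = [idx[sub_labels == u] for u in np.unique(sub_labels)]
        big = [p for p in parts if len(p) >= min_size]
        if len(big) < 2:
            return [idx]
        out = []
        for p in parts:
            if len(p) >= min_size:
                out.extend(refine(p, depth - 1))
            else:
                out.append(p)  # stays, will be dropped by size filter later
        return out

    final = np.zeros(n, dtype=int)
    next_label = 1
    for u in np.unique(labels):
        idx = np.where(labels == u)[0]
        if len(idx) < min_size:
            continue
        for part in refine(idx, deep_split):
            if len(part) >= min_size:
                final[part] = next_label
                next_label += 1
    return final


def detect_modules(X: np.ndarray, gene_ids: Sequence[str],
                   config: CoexprConfig = CoexprConfig()):
    """Unsigned WGCNA-style module detection on index-gene expression.

    Returns (assignment Series gene -> module label, linkage matrix).
    Module label 0 means unassigned; positive labels are ranked by module
    size (1 = largest).
    """
    X = np.asarray(X, dtype=float)
    gene_ids = list(gene_ids)
    n = X.shape[0]
    if n < config.min_module_size:
        warnings.warn("fewer genes than the minimum module size; "
                      "everything unassigned")
        return pd.Series(UNASSIGNED, index=gene_ids, name="module"), None
    A = adjacency_matrix(X, config.soft_power)
    sim = tom_similarity(A) if config.use_tom else \
        np.abs(_correlation(X)) ** config.soft_power
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    raw = _dynamic_cut(Z, D, config.min_module_size, config.deep_split)
    assignment = _rank_labels(pd.Series(raw, index=gene_ids, name="module"))
    return assignment, Z


def _rank_labels(assignment: pd.Series) -> pd.Series:
    """Relabel modules by size rank (1 = largest); 0 stays unassigned."""
    sizes = assignment[assignment != UNASSIGNED].value_counts()
    mapping = {old: new for new, old in enumerate(sizes.index, start=1)}
    mapping[UNASSIGNED] = UNASSIGNED
    return assignment.map(mapping).rename("module")


# ------------------------------------------------------------- eigengenes

def compute_eigengenes(assignment: pd.Series, X: np.ndarray,
                       gene_ids: Sequence[str],
                       sample_ids: Sequence[str]):
    """First principal component of each module's standardized expression.

    Eigengenes are standardized across samples and sign-aligned so their
    correlation with the module's mean expression is nonnegative.  Returns
    (eigengene DataFrame samples x modules, variance-explained Series).
    """
    X = np.asarray(X, dtype=float)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    eigs = {}
    var_expl = {}
    for module in sorted(set(assignment) - {UNASSIGNED}):
        genes = list(assignment.index[assignment == module])
        rows = [gene_pos[g] for g in genes]
        M = X[rows, :]
        sd = M.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant gene in module {module}")
        Mz = (M - M.mean(axis=1, keepdims=True)) / sd[:, None]
        U, S, Vt = np.linalg.svd(Mz, full_matrices=False)
        e = Vt[0]
        e = (e - e.mean())
        e_sd = e.std(ddof=1)
        if e_sd > 0:
            e = e / e_sd
        mean_expr = Mz.mean(axis=0)
        if np.corrcoef(e, mean_expr)[0, 1] < 0:
            e = -e
        eigs[f"M{module}"] = e
        var_expl[f"M{module}"] = float(S[0] ** 2 / (S ** 2).sum())
    frame = pd.DataFrame(eigs, index=list(sample_ids))
    return frame, pd.Series(var_expl, name="variance_explained")


def merge_close_modules(assignment: pd.Series, X: np.ndarray,
                        gene_ids: Sequence[str], sample_ids: Sequence[str],
                        merge_height: float = 0.35) -> pd.Series:
    """Iteratively merge module pairs with eigengene correlation >=
    1 - merge_height, recomputing eigengenes after every merge."""
    assignment = assignment.copy()
    threshold = 1.0 - merge_height
    while True:
        modules = sorted(set(assignment) - {UNASSIGNED})
        if len(modules) < 2:
            break
        eigs, _ = compute_eigengenes(assignment, X, gene_ids, sample_ids)
        cor = eigs.corr().to_numpy()
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] < threshold:
            break
        keep = int(eigs.columns[i][1:])
        drop = int(eigs.columns[j][1:])
        assignment[assignment == drop] = keep
    return _rank_labels(assignment)


def module_trait(eigengenes: pd.DataFrame, phenotypes: pd.DataFrame,
                 traits: Sequence[str]) -> pd.DataFrame:
    """Pearson correlation (and two-sided t-test p) per module x trait."""
    shared = eigengenes.index.intersection(phenotypes.index)
    rows = []
    for module in eigengenes.columns:
        for trait in traits:
            if trait not in phenotypes.columns:
                continue
            x = eigengenes.loc[shared, module]
            t = pd.to_numeric(phenotypes.loc[shared, trait], errors="coerce")
            mask = x.notna() & t.notna()
            if t[mask].nunique() < 2:
                rows.append({"module": module, "trait": trait,
                             "r": np.nan, "p": np.nan, "n": int(mask.sum())})
                continue
            r, p = stats.pearsonr(x[mask], t[mask])
            rows.append({"module": module, "trait": trait, "r": float(r),
                         "p": float(p), "n": int(mask.sum())})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- enrichment

def fisher_enrichment(module_genes: Dict[str, Sequence[str]],
                      reference_sets: Dict[str, Sequence[str]],
                      background: Sequence[str]) -> pd.DataFrame:
    """One-sided Fisher enrichment of each module in each reference set.

    Reference sets are intersected with the background; p-values are
    Bonferroni-corrected over all tests performed.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    rows = []
    for mod, genes in module_genes.items():
        genes = set(genes)
        if not genes <= background:
            raise ValueError(f"module '{mod}' not contained in background")
        for set_name, ref in reference_sets.items():
            ref = set(ref) & background
            overlap = len(genes & ref)
            a = overlap
            b = len(genes) - overlap
            c = len(ref) - overlap
            d = len(background) - len(genes) - len(ref) + overlap
            odds, p = stats.fisher_exact([[a, b], [c, d]],
                                         alternative="greater")
            rows.append({"module": mod, "reference_set": set_name,
                         "overlap": overlap, "module_size": len(genes),
                         "set_size": len(ref), "odds_ratio": float(odds),
                         "p": float(p)})
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * n_tests)
    return out


def read_gmt(path) -> Dict[str, List[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
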
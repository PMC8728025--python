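"""Synthetic bulk RNA-seq cohorts with a planted disease-severity continuum.

The generator emulates the structure of post-mortem brain cohorts used for
transcriptomic disease staging: a latent per-donor severity in [0, 1] with
dense clusters at the healthy and end-stage termini, gene modules whose
expression is monotonically coupled to severity (plus module-private
co-regulation so modules are distinguishable by co-expression), ordinal and
continuous neuropathology/cognition phenotypes that are noisy monotone
transforms of severity, demographic covariates, batch effects, and a
"spared tissue" null cohort whose expression carries no severity signal
(the cerebellum analogue).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import ExpressionMatrix

#: Phenotype columns written by the generator (ROSMAP-style naming).
PHENOTYPE_COLUMNS = [
    "cogdx", "braaksc", "ceradsc", "amyloid", "tangles", "nft", "plaq_d",
    "plaq_n", "gpath", "cogn_global", "age_death", "educ", "msex", "race7",
    "apoe4", "PMI", "r_pd", "r_stroke", "dlbdx", "hspath_typ",
    "arteriol_scler",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are the reference study conditions used throughout the test
    suite: 500 donors, 2000 genes, four severity-coupled modules
    (one large down-regulated, three smaller up-regulated), effect size 1.5
    log-CPM across the full severity range, unit residual noise, and 40% of
    donors concentrated near the two termini.
    """

    n_samples: int = 500
    n_genes: int = 2000
    module_sizes: Sequence[int] = (300, 60, 40, 50)
    module_directions: Sequence[int] = (-1, 1, 1, 1)
    effect_size: float = 1.5
    noise_sd: float = 1.0
    #: scale of the module-private latent factor giving within-module
    #: co-expression beyond the shared severity signal
    module_factor_sd: float = 0.5
    terminal_mass: float = 0.4
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    #: global multiplier on phenotype noise scales (0 -> noiseless phenotypes)
    pheno_noise: float = 1.0
    #: severity -> expression link: "linear" or "sigmoid"
    link: str = "linear"
    seed: int = 42

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if len(self.module_sizes) != len(self.module_directions):
            raise ValueError("module_sizes and module_directions lengths differ")
        if any(d not in (-1, 1) for d in self.module_directions):
            raise ValueError("module directions must be +1 or -1")
        if self.noise_sd < 0 or self.module_factor_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if not (0 <= self.terminal_mass < 1):
            raise ValueError("terminal_mass must be in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        if self.link not in ("linear", "sigmoid"):
            raise ValueError("link must be 'linear' or 'sigmoid'")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


#: reference study conditions for acceptance-scale runs
REFERENCE_SPEC = CohortSpec()


@dataclass
class SyntheticCohort:
    """A generated cohort: expression, phenotypes and ground truth."""

    expression: ExpressionMatrix
    phenotypes: pd.DataFrame
    latent_severity: pd.Series
    planted_modules: pd.Series  # per gene; 0 = null gene
    batch: pd.Series
    spec: CohortSpec
    batch_shifts: Optional[pd.DataFrame] = None  # genes x batches additive shifts
    batch_scales: Optional[pd.DataFrame] = None

    def signal_genes(self) -> list:
        return list(self.planted_modules.index[self.planted_modules > 0])

    def write(self, outdir) -> None:
        """Write expression TSV, phenotype CSV and ground-truth CSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.write_tsv(outdir / "expression.tsv")
        pheno = self.phenotypes.copy()
        pheno.index.name = "sample_id"
        pheno.to_csv(outdir / "phenotypes.csv")
        truth_s = self.latent_severity.rename("latent_severity").to_frame()
        truth_s.index.name = "sample_id"
        truth_s["batch"] = self.batch
        truth_s.to_csv(outdir / "truth_samples.csv")
        truth_g = self.planted_modules.rename("module").to_frame()
        truth_g.index.name = "gene_id"
        truth_g.to_csv(outdir / "truth_genes.csv")


def _severity_mixture(rng: np.random.Generator, n: int, terminal_mass: float):
    """Latent severity draw: Beta(1,8)/Beta(8,1) terminal clusters + uniform."""
    comp = rng.choice(3, size=n, p=[terminal_mass / 2, terminal_mass / 2,
                                    1 - terminal_mass])
    s = np.empty(n)
    low = comp == 0
    high = comp == 1
    mid = comp == 2
    s[low] = rng.beta(1.0, 8.0, size=low.sum())
    s[high] = rng.beta(8.0, 1.0, size=high.sum())
    s[mid] = rng.uniform(0.0, 1.0, size=mid.sum())
    return s


def severity_density(x, terminal_mass: float):
    """Mixture density of the latent severity (for analytic checks)."""
    from scipy.stats import beta as beta_dist

    x = np.asarray(x, dtype=float)
    return (terminal_mass / 2 * beta_dist.pdf(x, 1, 8)
            + terminal_mass / 2 * beta_dist.pdf(x, 8, 1)
            + (1 - terminal_mass) * ((x >= 0) & (x <= 1)).astype(float))


def _link(s: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return s
    # sigmoidal link rescaled so f(0)=0, f(1)=1
    raw = expit(10.0 * (s - 0.5))
    lo, hi = expit(-5.0), expit(5.0)
    return (raw - lo) / (hi - lo)


def _phenotypes(rng: np.random.Generator, s: np.ndarray, pn: float,
                sample_ids) -> pd.DataFrame:
    """Noisy monotone phenotype transforms of the latent severity ``s``.

    Ordinal staging scores (Braak-like 0-6, CERAD-like 1-4 with the
    "lower = worse" convention, 4-level clinical diagnosis), log-normal
    pathology burdens, a declining global-cognition score with covariate
    effects, and demographic covariates with a mild severity dependence
    where clinically plausible (APOE4, comorbidity flags).
    """
    n = len(s)
    braaksc = np.clip(np.round(6 * s + rng.normal(0, 0.6 * pn, n)), 0, 6)
    ceradsc = np.clip(np.round(4 - 3 * s + rng.normal(0, 0.5 * pn, n)), 1, 4)
    # diagnosis noise applied before thresholding -> label noise near cuts
    u = s + rng.normal(0, 0.15 * pn, n)
    cogdx = np.digitize(u, [0.30, 0.55, 0.75]) + 1  # 1..4

    def burden(scale):
        return np.exp(scale * s + rng.normal(0, 0.4 * pn, n))

    amyloid = burden(1.5)
    tangles = burden(2.0)
    nft = burden(1.8)
    plaq_d = burden(1.2)
    plaq_n = burden(1.5)
    gpath = burden(1.3)

    msex = rng.binomial(1, 0.5, n)
    age_death = rng.normal(85, 5, n)
    educ = rng.normal(16, 3, n)
    apoe4 = rng.binomial(2, 0.1 + 0.25 * s)
    pmi = np.clip(rng.normal(7, 2, n), 0.5, None)
    race7 = rng.choice([1, 2, 3, 4, 5, 6, 7], size=n,
                       p=[0.85, 0.05, 0.04, 0.03, 0.01, 0.01, 0.01])
    r_pd = rng.binomial(1, 0.03 + 0.05 * s)
    r_stroke = rng.binomial(1, 0.05 + 0.08 * s)
    dlbdx = np.digitize(s + rng.normal(0, 0.3 * pn, n) - 0.7,
                        [0.0, 0.2, 0.35])  # 0..3, mostly 0
    hspath_typ = rng.binomial(1, 0.03 + 0.07 * s)
    arteriol_scler = np.clip(
        np.round(1.2 * s + rng.normal(0, 0.5 * pn, n)), 0, 3)

    cogn_global = (-2.0 * s + 0.02 * (educ - 16) - 0.15 * apoe4
                   + rng.normal(0, 0.4 * pn, n))

    return pd.DataFrame({
        "cogdx": cogdx.astype(int), "braaksc": braaksc.astype(int),
        "ceradsc": ceradsc.astype(int), "amyloid": amyloid,
        "tangles": tangles, "nft": nft, "plaq_d": plaq_d, "plaq_n": plaq_n,
        "gpath": gpath, "cogn_global": cogn_global, "age_death": age_death,
        "educ": educ, "msex": msex.astype(int), "race7": race7.astype(int),
        "apoe4": apoe4.astype(int), "PMI": pmi,
        "r_pd": r_pd.astype(int), "r_stroke": r_stroke.astype(int),
        "dlbdx": dlbdx.astype(int), "hspath_typ": hspath_typ.astype(int),
        "arteriol_scler": arteriol_scler.astype(int),
    }, index=sample_ids)[PHENOTYPE_COLUMNS]


def _module_labels(spec: CohortSpec) -> np.ndarray:
    labels = np.zeros(spec.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(spec.module_sizes, start=1):
        labels[start:start + size] = m
        start += size
    return labels


def generate_cohort(spec: CohortSpec = REFERENCE_SPEC,
                    zero_effect: bool = False) -> SyntheticCohort:
    """Generate a cohort with a planted severity continuum.

    Expression model for gene g of module m with direction d_m:

        x_gi = mu_g + d_m * effect_size * f(s_i)
                    + module_factor_sd * u_{m,i} + eps_gi

    with gene baselines mu_g ~ N(4, 2^2) log-CPM, a module-private latent
    factor u_{m,i} ~ N(0, 1) and residual noise eps ~ N(0, noise_sd^2).
    Null genes carry baseline + noise only.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes

    s = _severity_mixture(rng, n, spec.terminal_mass)
    mu = rng.normal(4.0, 2.0, g)
    labels = _module_labels(spec)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:04d}" for i in range(g)]

    fs = _link(s, spec.link)
    effect = 0.0 if zero_effect else spec.effect_size
    loading = np.zeros(g)
    for m, d in enumerate(spec.module_directions, start=1):
        loading[labels == m] = d * effect

    x = mu[:, None] + loading[:, None] * fs[None, :]
    # module-private factors (severity-independent co-regulation)
    factors = rng.normal(0.0, 1.0, size=(len(spec.module_sizes), n))
    if not zero_effect:
        for m in range(1, len(spec.module_sizes) + 1):
            x[labels == m, :] += spec.module_factor_sd * factors[m - 1]
    x += rng.normal(0.0, spec.noise_sd, size=(g, n)) if spec.noise_sd > 0 \
        else 0.0

    batch = rng.integers(0, spec.n_batches, size=n)
    shifts = rng.normal(0.0, spec.batch_shift_sd, size=(g, spec.n_batches)) \
        if spec.batch_shift_sd > 0 else np.zeros((g, spec.n_batches))
    log_scale_sd = spec.batch_shift_sd / 10.0
    scales = np.exp(rng.normal(0.0, log_scale_sd, size=(g, spec.n_batches))) \
        if spec.batch_shift_sd > 0 else np.ones((g, spec.n_batches))
    if spec.n_batches > 1 and spec.batch_shift_sd > 0:
        centered = x - x.mean(axis=1, keepdims=True)
        x = (x.mean(axis=1, keepdims=True)
             + centered * scales[:, batch] + shifts[:, batch])

    pheno = _phenotypes(rng, s, spec.pheno_noise, sample_ids)
    batch_names = [f"batch{b}" for b in range(spec.n_batches)]
    return SyntheticCohort(
        expression=ExpressionMatrix(x, gene_ids, sample_ids),
        phenotypes=pheno,
        latent_severity=pd.Series(s, index=sample_ids, name="latent_severity"),
        planted_modules=pd.Series(labels, index=gene_ids, name="module"),
        batch=pd.Series([batch_names[b] for b in batch], index=sample_ids,
                        name="batch"),
        spec=spec,
        batch_shifts=pd.DataFrame(shifts, index=gene_ids, columns=batch_names),
        batch_scales=pd.DataFrame(scales, index=gene_ids, columns=batch_names),
    )


def generate_null_cohort(spec: CohortSpec = REFERENCE_SPEC) -> SyntheticCohort:
    """Spared-tissue analogue: phenotypes as usual, expression with no
    severity signal (effect size forced to zero, no module factors).

    The latent severity is still recorded so the absence of signal can be
    verified downstream.
    """
    cohort = generate_cohort(spec, zero_effect=True)
    cohort.planted_modules = pd.Series(
        np.zeros(spec.n_genes, dtype=int),
        index=cohort.planted_modules.index, name="module")
    return cohort


def generate_external_cohort(spec: CohortSpec, reference_gene_ids,
                             permute_genes: bool = False,
                             drop_genes: int = 0) -> SyntheticCohort:
    """A cohort on the reference gene universe with batch contamination.

    Starts from :func:`generate_cohort` under ``spec`` (which should carry
    ``n_batches`` > 1 and a nonzero ``batch_shift_sd`` to emulate an external
    study), restricts to the reference gene IDs, and optionally permutes the
    gene order or drops genes so the harmonization step has work to do.
    """
    reference_gene_ids = list(reference_gene_ids)
    if not reference_gene_ids:
        raise ValueError("reference gene list is empty")
    base = generate_cohort(spec)
    missing = [gid for gid in reference_gene_ids
               if gid not in set(base.expression.gene_ids)]
    if missing:
        raise ValueError(f"{len(missing)} reference genes absent from the "
                         "generated gene universe")
    keep = list(reference_gene_ids)
    rng = np.random.default_rng(spec.seed + 10_007)
    if drop_genes:
        drop_idx = set(rng.choice(len(keep), size=drop_genes, replace=False))
        keep = [gid for i, gid in enumerate(keep) if i not in drop_idx]
    if permute_genes:
        keep = [keep[i] for i in rng.permutation(len(keep))]
    expr = base.expression.subset_genes(keep)
    return SyntheticCohort(
        expression=expr,
        phenotypes=base.phenotypes,
        latent_severity=base.latent_severity,
        planted_modules=base.planted_modules.loc[keep],
        batch=base.batch,
        spec=spec,
        batch_shifts=base.batch_shifts.loc[keep] if base.batch_shifts is not None else None,
        batch_scales=base.batch_scales.loc[keep] if base.batch_scales is not None else None,
    )
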
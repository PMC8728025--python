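"""Statsmodels-style front end: ``StagingModel.fit() -> StagingResults``.

``StagingModel`` holds an expression matrix and a phenotype table; ``fit``
runs the full staging pipeline — terminus labelling, variance gene ordering,
stratified train/test split, Z-scaling frozen on the training set, the
sparsity-regularized classifier, PCA + UMAP embedding, principal-curve
trajectory and severity index — and returns a ``StagingResults`` object
carrying the estimates, diagnostics and the frozen artifacts needed to
project external cohorts.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import association as assoc
from . import coexpression as coex
from . import deepnet, preprocess, trajectory as traj
from .celltype import SmootherConfig, signature_curve, stratify_by_sex
from .containers import ExpressionMatrix
from .simulate import SyntheticCohort


@dataclass
class TrajectoryConfig:
    n_pcs: int = 50
    n_clusters: int = 2
    umap: traj.UMAPConfig = field(default_factory=traj.UMAPConfig)
    max_iter: int = 10
    tol: float = 1e-3


class StagingModel:
    """Disease-staging model for a bulk expression cohort.

    Parameters
    ----------
    expression
        Genes x samples log-CPM matrix.
    phenotypes
        Per-sample table containing at least the terminus-labelling columns
        (cogdx, braaksc, ceradsc) plus any covariates used downstream.
    net_config, traj_config
        Hyperparameters of the classifier and of the embedding/trajectory.
    train_frac, split_seed
        Stratified split of the termini samples.
    """

    def __init__(self, expression: ExpressionMatrix, phenotypes: pd.DataFrame,
                 net_config: Optional[deepnet.TrainingConfig] = None,
                 traj_config: Optional[TrajectoryConfig] = None,
                 train_frac: float = 0.8, split_seed: int = 0):
        missing = [s for s in expression.sample_ids
                   if s not in phenotypes.index]
        if missing:
            raise ValueError(f"{len(missing)} samples lack phenotypes")
        self.expression = expression
        self.phenotypes = phenotypes.loc[list(expression.sample_ids)]
        self.net_config = net_config or deepnet.TrainingConfig()
        self.traj_config = traj_config or TrajectoryConfig()
        self.train_frac = train_frac
        self.split_seed = split_seed

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, **kw) -> "StagingModel":
        return cls(cohort.expression, cohort.phenotypes, **kw)

    @classmethod
    def from_files(cls, expression_tsv, phenotype_csv, **kw) -> "StagingModel":
        expr = ExpressionMatrix.read_tsv(expression_tsv)
        pheno = pd.read_csv(phenotype_csv, index_col=0)
        pheno.index = pheno.index.map(str)
        return cls(expr, pheno, **kw)

    def fit(self) -> "StagingResults":
        expr = preprocess.sort_genes_by_variance(self.expression)
        labels = preprocess.assign_diagnosis(self.phenotypes)
        split = preprocess.split_train_test(labels, self.train_frac,
                                            self.split_seed)
        train_expr = expr.subset_samples(split.train_ids)
        scaler = preprocess.fit_scaler(train_expr)
        z_train = preprocess.apply_scaler(train_expr, scaler)
        y_train = (labels.loc[split.train_ids] == preprocess.AD
                   ).to_numpy(dtype=float)
        z_val = y_val = None
        if split.test_ids:
            z_val = preprocess.apply_scaler(
                expr.subset_samples(split.test_ids), scaler).values.T
            y_val = (labels.loc[split.test_ids] == preprocess.AD
                     ).to_numpy(dtype=float)
        params, history = deepnet.train(z_train.values.T, y_train, z_val,
                                        y_val, self.net_config)
        # whole-cohort hidden representation under the frozen scaler
        z_all = preprocess.apply_scaler(expr, scaler)
        hidden = deepnet.forward_hidden(params, z_all.values.T)
        prob = deepnet.forward_output(params, hidden)
        pca, scores = traj.fit_pca(hidden, self.traj_config.n_pcs)
        umap_model, embedding = traj.fit_umap(scores, self.traj_config.umap)
        clusters = traj.cluster_embedding(embedding,
                                          self.traj_config.n_clusters,
                                          seed=self.traj_config.umap.seed)
        trajectory = traj.fit_trajectory(embedding, clusters,
                                         diagnosis=labels,
                                         classifier_prob=prob,
                                         max_iter=self.traj_config.max_iter,
                                         tol=self.traj_config.tol)
        si = traj.compute_si(trajectory, embedding, expr.sample_ids)
        return StagingResults(
            model=self, params=params, scaler=scaler,
            gene_order=list(expr.gene_ids), labels=labels, split=split,
            history=history, pca=pca, umap_model=umap_model,
            trajectory=trajectory, embedding=pd.DataFrame(
                embedding, index=expr.sample_ids,
                columns=["UMAP1", "UMAP2", "UMAP3"]).assign(cluster=clusters),
            si=si, classifier_prob=pd.Series(prob, index=expr.sample_ids,
                                             name="p_ad"))


class StagingResults:
    """Fitted staging pipeline: estimates, diagnostics and frozen artifacts."""

    def __init__(self, model, params, scaler, gene_order, labels, split,
                 history, pca, umap_model, trajectory, embedding, si,
                 classifier_prob):
        self.model = model
        self.params = params
        self.scaler = scaler
        self.gene_order = gene_order
        self.labels = labels
        self.split = split
        self.history = history
        self.pca = pca
        self.umap_model = umap_model
        self.trajectory = trajectory
        self.embedding = embedding
        self.si = si
        self.classifier_prob = classifier_prob

    # -------------------------------------------------------- diagnostics

    @property
    def train_accuracy(self) -> float:
        return float(self.history["train_accuracy"].iloc[-1])

    @property
    def val_accuracy(self) -> Optional[float]:
        if "val_accuracy" in self.history.columns:
            return float(self.history["val_accuracy"].iloc[-1])
        return None

    def gene_weights(self) -> pd.DataFrame:
        """Per-gene first-layer RSS and max-normalized weight."""
        return deepnet.gene_weight_rss(self.params.W1, self.gene_order)

    def summary(self) -> str:
        lines = [
            "Transcriptome staging results",
            "=" * 34,
            f"samples: {len(self.si)}   genes: {len(self.gene_order)}",
            f"termini: AD={int((self.labels == 'AD').sum())} "
            f"CN={int((self.labels == 'CN').sum())} "
            f"OTHER={int((self.labels == 'OTHER').sum())}",
            f"train/test termini: {len(self.split.train_ids)}/"
            f"{len(self.split.test_ids)}",
            f"train accuracy: {self.train_accuracy:.3f}",
        ]
        if self.val_accuracy is not None:
            lines.append(f"validation accuracy: {self.val_accuracy:.3f}")
        lines += [
            f"trajectory length: {self.trajectory.total_length:.3f}",
            f"SI range: [{self.si.min():.3f}, {self.si.max():.3f}]",
            f"origin cluster: {self.trajectory.origin_cluster} "
            "(control terminus, SI = 0)",
        ]
        return "\n".join(lines)

    # -------------------------------------------------------- projection

    def project(self, expression: ExpressionMatrix,
                batch: Optional[pd.Series] = None,
                refit_pca: bool = False,
                refit_trajectory: bool = False) -> "ProjectionResult":
        """Project an external cohort through the frozen pipeline.

        harmonize genes -> ComBat (if > 1 batch) -> frozen Z-scaling ->
        forward pass -> PCA (frozen rotation by default) -> UMAP transform
        into the training embedding -> SI against the frozen trajectory.
        ``refit_pca``/``refit_trajectory`` re-derive those stages on the
        external cohort instead.
        """
        fill = pd.Series(self.scaler.mean, index=self.scaler.gene_ids)
        expr = preprocess.harmonize_genes(expression, self.gene_order,
                                          fill_values=fill)
        if batch is not None and pd.Series(batch).nunique() > 1:
            expr = preprocess.combat_correct(expr, batch)
        z = preprocess.apply_scaler(expr, self.scaler)
        hidden = deepnet.forward_hidden(self.params, z.values.T)
        prob = deepnet.forward_output(self.params, hidden)
        if refit_pca:
            _, scores = traj.fit_pca(hidden, self.model.traj_config.n_pcs)
        else:
            scores = self.pca.transform(hidden)
        embedding = self.umap_model.transform(scores)
        if refit_trajectory:
            clusters = traj.cluster_embedding(
                embedding, self.model.traj_config.n_clusters,
                seed=self.model.traj_config.umap.seed)
            trajectory = traj.fit_trajectory(embedding, clusters,
                                             classifier_prob=prob)
        else:
            trajectory = self.trajectory
        si = traj.compute_si(trajectory, embedding, expr.sample_ids)
        return ProjectionResult(
            embedding=pd.DataFrame(embedding, index=expr.sample_ids,
                                   columns=["UMAP1", "UMAP2", "UMAP3"]),
            si=si, classifier_prob=pd.Series(prob, index=expr.sample_ids,
                                             name="p_ad"))

    # -------------------------------------------------------- associations

    def associate(self, biomarkers: Sequence[str],
                  phenotypes: Optional[pd.DataFrame] = None,
                  si: Optional[pd.Series] = None,
                  covariates=None, sample_filter: str = "all") -> pd.DataFrame:
        """SI-vs-biomarker regression grid (signed R, SI p, per-term PVE)."""
        phenotypes = phenotypes if phenotypes is not None \
            else self.model.phenotypes
        si = si if si is not None else self.si
        termini = list(self.labels.index[self.labels != preprocess.OTHER])
        return assoc.associate_si(si, phenotypes, biomarkers,
                                  covariates=covariates,
                                  sample_filter=sample_filter,
                                  termini_ids=termini)

    def index_genes(self, method: str = "valley",
                    manual_threshold: Optional[float] = None
                    ) -> Tuple[List[str], coex.WeightCut]:
        weights = self.gene_weights()["weight"]
        cut = coex.detect_weight_cut(weights, method=method,
                                     manual_threshold=manual_threshold)
        return coex.select_index_genes(weights, cut), cut

    def modules(self, index_genes: Optional[Sequence[str]] = None,
                config: Optional[coex.CoexprConfig] = None):
        """Co-expression modules of the index genes on unscaled log-CPM.

        Returns (assignment, eigengenes samples x modules, variance
        explained) after eigengene-correlation merging.
        """
        config = config or coex.CoexprConfig()
        if index_genes is None:
            index_genes, _ = self.index_genes()
        expr = self.model.expression.subset_genes(list(index_genes))
        assignment, _Z = coex.detect_modules(expr.values, expr.gene_ids,
                                             config)
        if (assignment != coex.UNASSIGNED).any() and \
                len(set(assignment) - {coex.UNASSIGNED}) >= 2:
            assignment = coex.merge_close_modules(
                assignment, expr.values, expr.gene_ids, expr.sample_ids,
                config.merge_height)
        if (assignment != coex.UNASSIGNED).any():
            eigs, var_expl = coex.compute_eigengenes(
                assignment, expr.values, expr.gene_ids, expr.sample_ids)
        else:
            eigs, var_expl = pd.DataFrame(index=expr.sample_ids), pd.Series()
        return assignment, eigs, var_expl

    def celltype_curves(self, markers: Dict[str, Sequence[str]],
                        config: Optional[SmootherConfig] = None,
                        by_sex: bool = False):
        config = config or SmootherConfig()
        if by_sex:
            return stratify_by_sex(markers, self.model.expression, self.si,
                                   self.model.phenotypes, config)
        return signature_curve(markers, self.model.expression, self.si,
                               config)

    # -------------------------------------------------------- persistence

    def save(self, outdir) -> None:
        """Model archive: JSON metadata + npz arrays + pickled UMAP state.

        Arrays round-trip bit-exactly; the UMAP reducer is pickled because
        its nearest-neighbour index has no portable text form.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.model.net_config
        meta = {
            "net_config": asdict(cfg),
            "traj_config": {
                "n_pcs": self.model.traj_config.n_pcs,
                "n_clusters": self.model.traj_config.n_clusters,
                "umap": asdict(self.model.traj_config.umap),
            },
            "train_frac": self.model.train_frac,
            "split_seed": self.model.split_seed,
            "gene_order": self.gene_order,
            "split": {"train_ids": self.split.train_ids,
                      "test_ids": self.split.test_ids,
                      "seed": self.split.seed},
            "origin_cluster": self.trajectory.origin_cluster,
            "train_accuracy": self.train_accuracy,
            "val_accuracy": self.val_accuracy,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=1))
        np.savez(outdir / "arrays.npz",
                 W1=self.params.W1, B1=self.params.B1,
                 W2=self.params.W2, B2=self.params.B2,
                 scaler_mean=self.scaler.mean, scaler_sd=self.scaler.sd,
                 pca_center=self.pca.center, pca_rotation=self.pca.rotation,
                 pca_var=self.pca.explained_variance,
                 polyline=self.trajectory.polyline,
                 traj_centroids=self.trajectory.centroids,
                 traj_labels=self.trajectory.cluster_labels)
        with open(outdir / "umap_model.pkl", "wb") as fh:
            pickle.dump(self.umap_model, fh)
        self.history.to_csv(outdir / "history.csv", index=False)
        emb = self.embedding.copy()
        emb["si"] = self.si
        emb["diagnosis"] = self.labels
        emb.index.name = "sample_id"
        emb.to_csv(outdir / "embedding_si.csv")
        pd.DataFrame(self.trajectory.polyline,
                     columns=["UMAP1", "UMAP2", "UMAP3"]
                     ).to_csv(outdir / "trajectory_polyline.csv", index=False)

    @classmethod
    def load(cls, outdir, model: Optional[StagingModel] = None
             ) -> "StagingResults":
        outdir = Path(outdir)
        meta = json.loads((outdir / "metadata.json").read_text())
        arrays = np.load(outdir / "arrays.npz")
        params = deepnet.NetworkParams(arrays["W1"], arrays["B1"],
                                       arrays["W2"], arrays["B2"])
        scaler = preprocess.ScalingStats(meta["gene_order"],
                                         arrays["scaler_mean"],
                                         arrays["scaler_sd"])
        pca = traj.PCAModel(arrays["pca_center"], arrays["pca_rotation"],
                            arrays["pca_var"])
        with open(outdir / "umap_model.pkl", "rb") as fh:
            umap_model = pickle.load(fh)
        trajectory = traj.TrajectoryModel(
            polyline=arrays["polyline"],
            origin_cluster=int(meta["origin_cluster"]),
            cluster_labels=arrays["traj_labels"],
            centroids=arrays["traj_centroids"], mst_edges=[])
        history = pd.read_csv(outdir / "history.csv")
        emb = pd.read_csv(outdir / "embedding_si.csv", index_col=0)
        emb.index = emb.index.map(str)
        split = preprocess.SplitIndex(meta["split"]["train_ids"],
                                      meta["split"]["test_ids"], {},
                                      meta["split"]["seed"])
        labels = emb["diagnosis"]
        si = emb["si"].rename("si")
        if model is None:
            cfg = deepnet.TrainingConfig(**meta["net_config"])
            tcfg = TrajectoryConfig(
                n_pcs=meta["traj_config"]["n_pcs"],
                n_clusters=meta["traj_config"]["n_clusters"],
                umap=traj.UMAPConfig(**meta["traj_config"]["umap"]))
            model = StagingModel.__new__(StagingModel)
            model.net_config = cfg
            model.traj_config = tcfg
            model.train_frac = meta["train_frac"]
            model.split_seed = meta["split_seed"]
            model.expression = None
            model.phenotypes = None
        return cls(model=model, params=params, scaler=scaler,
                   gene_order=meta["gene_order"], labels=labels, split=split,
                   history=history, pca=pca, umap_model=umap_model,
                   trajectory=trajectory,
                   embedding=emb[["UMAP1", "UMAP2", "UMAP3", "cluster"]],
                   si=si,
                   classifier_prob=None)

    def plot_trajectory(self, path=None):
        """Scatter of the first two embedding axes coloured by SI, with the
        principal curve overlaid."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(self.embedding["UMAP1"], self.embedding["UMAP2"],
                        c=self.si, s=8, cmap="viridis")
        ax.plot(self.trajectory.polyline[:, 0],
                self.trajectory.polyline[:, 1], "r-", lw=2)
        fig.colorbar(sc, ax=ax, label="severity index")
        ax.set_xlabel("UMAP1")
        ax.set_ylabel("UMAP2")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


@dataclass
class ProjectionResult:
    """External-cohort projection: embedding, SI and classifier output."""

    embedding: pd.DataFrame
    si: pd.Series
    classifier_prob: pd.Series

    def to_csv(self, path) -> None:
        out = self.embedding.copy()
        out["si"] = self.si
        out["p_ad"] = self.classifier_prob
        out.index.name = "sample_id"
        out.to_csv(path)
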
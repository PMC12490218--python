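"""Model/Results interface for the cisplatin-response program pipeline.

:class:`CisplatinResponseModel` is constructed from a list of experiment
bundles (or a simulation config, or a directory of bundle subdirectories) plus
the analysis parameters; :meth:`~CisplatinResponseModel.fit` runs the full
cascade —

    per-experiment effect-size signatures
    -> universal signature (mean across experiments)
    -> per-cell sensitivity scores in the highest-dose/longest-duration
       stratum and quartile classification
    -> PCA of untreated cells, projection of the classified stratum
    -> per-PC sensitivity and cell-cycle effect sizes, threshold selection
    -> cross-replicate similarity, hierarchical clustering, consensus programs

— and returns a :class:`CisplatinResponseResults` holding every intermediate
table, a ``summary()`` report, and hooks for preranked enrichment and plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import consensus as cons
from . import enrichment as enr
from .programs import (
    PCAModel,
    PCProgram,
    assign_phase,
    fit_control_pca,
    normalize_and_center,
    pc_effect_sizes,
    project_cells,
    select_pcs,
)
from .signature import (
    EffectSignature,
    cis_sen_scores,
    classify_sensitivity,
    extract_signature,
    signature_agreement,
    universal_signature,
)
from .simulate import ExperimentBundle, SimConfig, generate_replicate_set

__all__ = ["CisplatinResponseModel", "CisplatinResponseResults"]


@dataclass
class ExperimentFit:
    """Per-experiment artefacts of one fitted pipeline run."""

    experiment_id: str
    pca: PCAModel
    sensitivity: pd.DataFrame  # stratum cells: cell_id, score, class
    programs: list[PCProgram]
    dropped_genes: list[str]  # zero-variance in control cells
    n_control: int
    n_stratum: int


class CisplatinResponseModel:
    """Discovery of pre-existing programs linked to cisplatin sensitivity.

    Parameters
    ----------
    bundles
        Experiment bundles (counts + per-cell condition metadata).  Use
        :meth:`from_simulation` or :meth:`from_directory` for the common
        construction paths.
    top_n, bottom_n
        Sizes of the up-/down-regulated signature gene sets entering the
        per-cell sensitivity score (shrunk proportionally on small panels).
    sensitivity_fraction
        Quantile fraction for the more-/less-sensitive classes (default
        quartiles).
    n_pcs
        Control-space components retained per experiment.
    d_sens_min, d_phase_max
        Effect-size thresholds for program selection.
    linkage, cut_height, n_clusters
        Hierarchical clustering of selected programs; ``n_clusters`` overrides
        ``cut_height``.
    s_genes, g2m_genes
        Cell-cycle marker lists used only when the metadata has no ``phase``
        column.
    """

    def __init__(
        self,
        bundles: Sequence[ExperimentBundle],
        *,
        top_n: int = 1000,
        bottom_n: int = 10000,
        sensitivity_fraction: float = 0.25,
        n_pcs: int = 10,
        d_sens_min: float = 0.5,
        d_phase_max: float = 0.5,
        linkage: str = "average",
        cut_height: float = 0.7,
        n_clusters: Optional[int] = None,
        min_shared_genes: int = 50,
        s_genes: Optional[Sequence[str]] = None,
        g2m_genes: Optional[Sequence[str]] = None,
        seed: int = 0,
    ) -> None:
        if not bundles:
            raise ValueError("need at least one experiment bundle")
        self.bundles = list(bundles)
        self.top_n = top_n
        self.bottom_n = bottom_n
        self.sensitivity_fraction = sensitivity_fraction
        self.n_pcs = n_pcs
        self.d_sens_min = d_sens_min
        self.d_phase_max = d_phase_max
        self.linkage = linkage
        self.cut_height = cut_height
        self.n_clusters = n_clusters
        self.min_shared_genes = min_shared_genes
        self.s_genes = list(s_genes) if s_genes else None
        self.g2m_genes = list(g2m_genes) if g2m_genes else None
        self.seed = seed

    # ------------------------------------------------------------------ #
    @classmethod
    def from_simulation(cls, config: SimConfig, **kwargs) -> "CisplatinResponseModel":
        """Build the model on a freshly simulated replicate set."""
        return cls(generate_replicate_set(config), seed=config.seed, **kwargs)

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "CisplatinResponseModel":
        """Build the model from a directory of bundle subdirectories."""
        from .io import read_bundle

        root = Path(path)
        subdirs = sorted(d for d in root.iterdir() if (d / "matrix.mtx").exists())
        if not subdirs:
            raise FileNotFoundError(f"no bundle directories under {root}")
        return cls([read_bundle(d) for d in subdirs], **kwargs)

    # ------------------------------------------------------------------ #
    def _stratum_mask(self, bundle: ExperimentBundle) -> np.ndarray:
        """Cells of the highest-dose / longest-duration treated condition."""
        meta = bundle.cell_meta
        treated = meta["dose_fraction"] > 0
        if not treated.any():
            raise ValueError(f"{bundle.experiment_id}: no treated cells")
        dmax = meta.loc[treated, "dose_fraction"].max()
        tmax = meta.loc[treated & (meta["dose_fraction"] == dmax), "duration_h"].max()
        return ((meta["dose_fraction"] == dmax) & (meta["duration_h"] == tmax)).to_numpy()

    def _phases(self, bundle: ExperimentBundle, expr: np.ndarray, genes: Sequence[str]) -> np.ndarray:
        if "phase" in bundle.cell_meta.columns:
            return bundle.cell_meta["phase"].to_numpy(dtype=object)
        if self.s_genes is None or self.g2m_genes is None:
            raise ValueError(
                f"{bundle.experiment_id}: no phase column and no marker lists supplied"
            )
        return assign_phase(expr, genes, self.s_genes, self.g2m_genes, seed=self.seed)

    def fit(self) -> "CisplatinResponseResults":
        """Run the full pipeline and return the results object."""
        signatures = [extract_signature(b) for b in self.bundles]
        agreement = signature_agreement(signatures) if len(signatures) > 1 else None
        universal = universal_signature(signatures)

        fits: list[ExperimentFit] = []
        all_programs: list[PCProgram] = []
        for bundle in self.bundles:
            exp_id = bundle.experiment_id
            control = bundle.mask(dose_fraction=0.0)
            stratum = self._stratum_mask(bundle)

            scores = cis_sen_scores(
                bundle.counts[stratum], universal, self.top_n, self.bottom_n
            )
            calls = classify_sensitivity(
                scores,
                fraction=self.sensitivity_fraction,
                cell_ids=bundle.cell_meta.loc[stratum, "cell_id"].tolist(),
            )

            # control PCA on genes with variance among untreated cells
            ctrl_centered, ctrl_means = normalize_and_center(bundle.counts[control])
            variances = ctrl_centered.var(axis=0)
            keep = variances > 0
            dropped = [g for g, k in zip(bundle.gene_ids, keep) if not k]
            if dropped:
                warnings.warn(
                    f"{exp_id}: {len(dropped)} zero-variance gene(s) dropped from PCA",
                    RuntimeWarning,
                    stacklevel=2,
                )
            genes_kept = [g for g, k in zip(bundle.gene_ids, keep) if k]
            pca = fit_control_pca(
                ctrl_centered[:, keep],
                n_pcs=self.n_pcs,
                gene_ids=genes_kept,
                experiment_id=exp_id,
                gene_means=ctrl_means[keep],
            )

            strat_centered, _ = normalize_and_center(
                bundle.counts[stratum][:, keep], reference_means=ctrl_means[keep]
            )
            strat_scores = project_cells(pca, strat_centered)
            # phase contrasts gain power from every treated cell, not just the
            # classified stratum
            treated = (bundle.cell_meta["dose_fraction"] > 0).to_numpy()
            treated_centered, _ = normalize_and_center(
                bundle.counts[treated][:, keep], reference_means=ctrl_means[keep]
            )
            treated_scores = project_cells(pca, treated_centered)
            if "phase" in bundle.cell_meta.columns:
                phases = bundle.cell_meta.loc[treated, "phase"].to_numpy(dtype=object)
            else:
                phases = self._phases(bundle, treated_centered, genes_kept)

            programs = pc_effect_sizes(
                strat_scores,
                calls["sens_class"].to_numpy(),
                phases,
                model=pca,
                phase_scores=treated_scores,
            )
            select_pcs(
                programs,
                d_sens_min=self.d_sens_min,
                d_phase_max=self.d_phase_max,
                max_pc_index=self.n_pcs,
            )
            all_programs.extend(programs)
            fits.append(
                ExperimentFit(
                    experiment_id=exp_id,
                    pca=pca,
                    sensitivity=calls,
                    programs=programs,
                    dropped_genes=dropped,
                    n_control=int(control.sum()),
                    n_stratum=int(stratum.sum()),
                )
            )

        selected = [p for p in all_programs if p.selected]
        if selected:
            if len(selected) == 1:
                similarity = pd.DataFrame(
                    [[1.0]],
                    index=[selected[0].program_id],
                    columns=[selected[0].program_id],
                )
                labels = pd.Series([1], index=similarity.index, name="cluster")
                consensus_programs = [cons.consensus_program(selected, cluster_id=1)]
            else:
                similarity, labels, consensus_programs = cons.build_consensus(
                    selected,
                    linkage=self.linkage,
                    height=self.cut_height,
                    k=self.n_clusters,
                    min_shared_genes=self.min_shared_genes,
                )
        else:
            similarity = pd.DataFrame()
            labels = pd.Series(dtype=int, name="cluster")
            consensus_programs = []

        return CisplatinResponseResults(
            model=self,
            signatures=signatures,
            agreement=agreement,
            universal=universal,
            experiment_fits=fits,
            programs=all_programs,
            similarity=similarity,
            cluster_labels=labels,
            consensus_programs=consensus_programs,
        )


@dataclass
class CisplatinResponseResults:
    """Artefacts of a fitted pipeline run, with summary/enrichment/plot hooks."""

    model: CisplatinResponseModel
    signatures: list[EffectSignature]
    agreement: Optional[pd.DataFrame]
    universal: EffectSignature
    experiment_fits: list[ExperimentFit]
    programs: list[PCProgram]
    similarity: pd.DataFrame
    cluster_labels: pd.Series
    consensus_programs: list[cons.ConsensusProgram]

    # ------------------------------------------------------------------ #
    @property
    def selected_programs(self) -> list[PCProgram]:
        return [p for p in self.programs if p.selected]

    def program_table(self) -> pd.DataFrame:
        """One row per candidate PC with effect sizes and selection flag."""
        rows = []
        for p in self.programs:
            rows.append(
                {
                    "program_id": p.program_id,
                    "experiment_id": p.experiment_id,
                    "pc_index": p.pc_index,
                    "explained_variance": p.explained_variance,
                    "d_sensitivity": p.d_sensitivity,
                    "d_G1_vs_S": p.d_phase[0],
                    "d_G1_vs_G2M": p.d_phase[1],
                    "d_S_vs_G2M": p.d_phase[2],
                    "selected": p.selected,
                }
            )
        return pd.DataFrame(rows)

    def sensitivity_table(self) -> pd.DataFrame:
        """Per-cell sensitivity calls of the contrast stratum, all experiments."""
        frames = []
        for f in self.experiment_fits:
            t = f.sensitivity.copy()
            t.insert(0, "experiment_id", f.experiment_id)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def run_gsea(
        self,
        collection: enr.GeneSetCollection,
        cluster_id: Optional[int] = None,
        n_perm: int = 1000,
        min_size: int = 15,
        max_size: int = 500,
        fdr_max: float = 0.05,
        gene_ratio_min: float = 0.4,
        seed: Optional[int] = None,
    ) -> dict[int, dict]:
        """Preranked enrichment on consensus median-weight rankings.

        Returns ``{cluster_id: {"results": [...], "filtered": [...]}}`` for the
        requested cluster (or every cluster when ``cluster_id`` is None).
        """
        seed = self.model.seed if seed is None else seed
        out = {}
        for cp in self.consensus_programs:
            if cluster_id is not None and cp.cluster_id != cluster_id:
                continue
            results = enr.gsea_preranked(
                cp.ranking(),
                collection,
                n_perm=n_perm,
                min_size=min_size,
                max_size=max_size,
                seed=seed + cp.cluster_id,
            )
            out[cp.cluster_id] = {
                "results": results,
                "filtered": enr.filter_results(results, fdr_max, gene_ratio_min),
            }
        return out

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "Cisplatin response program discovery",
            "=" * 52,
            f"experiments:            {len(self.experiment_fits)}",
            f"candidate PCs:          {len(self.programs)}",
            f"selected PCs:           {len(self.selected_programs)}"
            f"  (|d_sens| > {self.model.d_sens_min}, phase |d| < {self.model.d_phase_max})",
            f"consensus clusters:     {len(self.consensus_programs)}",
            "",
            f"{'experiment':<14}{'control':>9}{'stratum':>9}{'selected PCs':>14}",
        ]
        for f in self.experiment_fits:
            n_sel = sum(p.selected for p in f.programs)
            lines.append(
                f"{f.experiment_id:<14}{f.n_control:>9}{f.n_stratum:>9}{n_sel:>14}"
            )
        if self.agreement is not None:
            off = self.agreement.to_numpy()[~np.eye(len(self.agreement), dtype=bool)]
            lines += [
                "",
                f"signature agreement (pairwise Pearson r): "
                f"median {np.nanmedian(off):.3f}, min {np.nanmin(off):.3f}",
            ]
        for cp in self.consensus_programs:
            lines.append(
                f"cluster {cp.cluster_id}: {cp.n_members} member PC(s), "
                f"{len(cp.median_weights)} shared genes"
            )
        return "\n".join(lines)

    # plotting hangs off the results object -------------------------------- #
    def plot_similarity_heatmap(self, ax=None):
        from .plotting import similarity_heatmap

        return similarity_heatmap(self.similarity, self.cluster_labels, ax=ax)

    def plot_score_distribution(self, experiment_id: Optional[str] = None, ax=None):
        from .plotting import score_boxplot

        table = self.sensitivity_table()
        if experiment_id is not None:
            table = table[table["experiment_id"] == experiment_id]
        return score_boxplot(table, ax=ax)
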
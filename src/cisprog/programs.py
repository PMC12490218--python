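"""Control-anchored principal-component programs and effect-size selection.

PCA is fitted to untreated cells only, so the components describe pre-existing
cell-to-cell heterogeneity rather than treatment-induced shifts.  Treated
cells are then projected into that space; a component is kept as a candidate
sensitivity program when it separates more-sensitive from less-sensitive cells
(|Cohen's d| above a threshold) while separating none of the cell-cycle phase
pairs (G1 vs S, G1 vs G2/M, S vs G2/M all below a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signature import LESS_SENSITIVE, MORE_SENSITIVE, cohens_d, log_normalize

__all__ = [
    "PCAModel",
    "PCProgram",
    "normalize_and_center",
    "fit_control_pca",
    "project_cells",
    "pc_effect_sizes",
    "select_pcs",
    "assign_phase",
]

PHASE_PAIRS = (("G1", "S"), ("G1", "G2M"), ("S", "G2M"))


@dataclass
class PCAModel:
    """PCA of centered control-cell expression (orthonormal gene loadings)."""

    gene_means: np.ndarray  # per-gene control means on the normalized scale
    loadings: np.ndarray  # genes x K, orthonormal columns
    explained_variance: np.ndarray  # per-PC, non-increasing
    gene_ids: list[str]
    experiment_id: str = ""

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]


@dataclass
class PCProgram:
    """One control PC with its sensitivity and cell-cycle effect sizes."""

    experiment_id: str
    pc_index: int  # 1-based rank within the experiment
    loadings: pd.Series  # per-gene loading values
    d_sensitivity: float = np.nan
    d_phase: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    explained_variance: float = np.nan
    selected: bool = False

    @property
    def program_id(self) -> str:
        return f"{self.experiment_id}_PC{self.pc_index}"


def normalize_and_center(
    counts: np.ndarray,
    reference_means: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts-per-10k log1p expression minus per-gene reference means.

    With ``reference_means=None`` the matrix is centered on its own column
    means (fitting); passing the control means anchors treated cells to the
    control space (projection).  Returns ``(centered, means_used)``.  Cells
    with zero total count are flagged with a warning and zeroed after
    centering (they carry no usable signal).
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    zero_cells = counts.sum(axis=1) == 0
    expr = log_normalize(counts)
    if reference_means is None:
        means = expr[~zero_cells].mean(axis=0) if (~zero_cells).any() else expr.mean(axis=0)
    else:
        means = np.asarray(reference_means, dtype=float)
        if means.shape != (counts.shape[1],):
            raise ValueError(
                f"reference_means length {means.size} != {counts.shape[1]} genes"
            )
    centered = expr - means
    if zero_cells.any():
        warnings.warn(
            f"{int(zero_cells.sum())} cell(s) with zero total count excluded (zeroed)",
            RuntimeWarning,
            stacklevel=2,
        )
        centered[zero_cells] = 0.0
    return centered, means


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column positive."""
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def fit_control_pca(
    control_expr: np.ndarray,
    n_pcs: int = 10,
    gene_ids: Optional[Sequence[str]] = None,
    experiment_id: str = "",
    gene_means: Optional[np.ndarray] = None,
) -> PCAModel:
    """Top principal components of an already-centered control matrix.

    Computed from the SVD of the centered matrix; no variance scaling.
    Deterministic up to sign, fixed so each loading vector's
    largest-magnitude entry is positive.  ``n_pcs`` above the matrix rank is
    reduced with a warning.
    """
    x = np.asarray(control_expr, dtype=float)
    n, g = x.shape
    if n < n_pcs + 1:
        raise ValueError(f"need at least n_pcs+1={n_pcs + 1} control cells, got {n}")
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    tol = svals.max(initial=0.0) * max(n, g) * np.finfo(float).eps
    rank = int((svals > tol).sum())
    if rank < n_pcs:
        warnings.warn(
            f"matrix rank {rank} < requested {n_pcs} PCs: reducing",
            RuntimeWarning,
            stacklevel=2,
        )
        n_pcs = rank
    loadings = _fix_signs(vt[:n_pcs].T)
    explained = svals[:n_pcs] ** 2 / (n - 1)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if gene_means is None:
        gene_means = np.zeros(g)
    return PCAModel(
        gene_means=np.asarray(gene_means, dtype=float),
        loadings=loadings,
        explained_variance=explained,
        gene_ids=list(gene_ids),
        experiment_id=experiment_id,
    )


def project_cells(model: PCAModel, expr: np.ndarray) -> np.ndarray:
    """Scores of cells in the control PC space.

    ``expr`` must be centered on ``model.gene_means`` over the model's gene
    universe; scores are the plain dot products with the loadings.
    """
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    if expr.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"expression has {expr.shape[1]} genes, model expects "
            f"{model.loadings.shape[0]} ({model.experiment_id or 'unnamed'})"
        )
    return expr @ model.loadings


def pc_effect_sizes(
    scores: np.ndarray,
    sens_labels: Sequence[str],
    phase_labels: Sequence[str],
    model: Optional[PCAModel] = None,
    experiment_id: str = "",
    phase_scores: Optional[np.ndarray] = None,
) -> list[PCProgram]:
    """Per-PC |Cohen's d| for the sensitivity contrast and each phase pair.

    The sensitivity contrast uses only cells labeled more-/less-sensitive;
    phase contrasts use all projected cells of the experiment — pass their
    scores as ``phase_scores`` (with matching ``phase_labels``) when they are
    a wider set than the classified stratum in ``scores``.  Absolute values
    are recorded because the PC sign is arbitrary.  A phase with <2 cells
    yields a NaN d for its pairs (treated as 0 by selection) with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    sens = np.asarray(sens_labels, dtype=object)
    phase = np.asarray(phase_labels, dtype=object)
    if phase_scores is None:
        phase_scores = scores
    else:
        phase_scores = np.atleast_2d(np.asarray(phase_scores, dtype=float))
        if phase_scores.shape[1] != scores.shape[1]:
            raise ValueError("phase_scores must have the same PCs as scores")
    if sens.size != scores.shape[0] or phase.size != phase_scores.shape[0]:
        raise ValueError("label lengths must match the number of projected cells")

    more = sens == MORE_SENSITIVE
    less = sens == LESS_SENSITIVE
    if more.sum() < 2 or less.sum() < 2:
        raise ValueError("need >=2 cells in each sensitivity group")

    missing_pairs = []
    programs = []
    if model is not None:
        experiment_id = experiment_id or model.experiment_id
    for k in range(scores.shape[1]):
        col = scores[:, k]
        pcol = phase_scores[:, k]
        d_sens = abs(cohens_d(col[more], col[less]))
        d_ph = []
        for pa, pb in PHASE_PAIRS:
            ma, mb = phase == pa, phase == pb
            if ma.sum() < 2 or mb.sum() < 2:
                d_ph.append(np.nan)
                missing_pairs.append((pa, pb))
            else:
                d = cohens_d(pcol[ma], pcol[mb])
                d_ph.append(abs(d) if not np.isnan(d) else np.nan)
        if model is not None:
            load = pd.Series(model.loadings[:, k], index=model.gene_ids)
            ev = float(model.explained_variance[k])
        else:
            load = pd.Series(dtype=float)
            ev = np.nan
        programs.append(
            PCProgram(
                experiment_id=experiment_id,
                pc_index=k + 1,
                loadings=load,
                d_sensitivity=float(d_sens) if not np.isnan(d_sens) else np.nan,
                d_phase=tuple(d_ph),
                explained_variance=ev,
            )
        )
    if missing_pairs:
        warnings.warn(
            f"phase pair(s) with <2 cells: effect flagged missing and treated as 0 "
            f"for selection ({sorted(set(missing_pairs))})",
            RuntimeWarning,
            stacklevel=2,
        )
    return programs


def select_pcs(
    programs: Sequence[PCProgram],
    d_sens_min: float = 0.5,
    d_phase_max: float = 0.5,
    max_pc_index: int = 10,
) -> list[PCProgram]:
    """Flag programs separating sensitivity groups but not cell-cycle phases.

    selected <=> |d_sensitivity| > d_sens_min and every phase |d| < d_phase_max
    (missing phase effects count as 0); only the first ``max_pc_index`` PCs of
    each experiment are eligible.  Returns the selected programs; the
    ``selected`` flag is set in place on all inputs.
    """
    selected = []
    for prog in programs:
        phase_ok = all((0.0 if np.isnan(d) else d) < d_phase_max for d in prog.d_phase)
        sens_ok = not np.isnan(prog.d_sensitivity) and prog.d_sensitivity > d_sens_min
        prog.selected = bool(sens_ok and phase_ok and prog.pc_index <= max_pc_index)
        if prog.selected:
            selected.append(prog)
    return selected


def assign_phase(
    expr: np.ndarray,
    gene_ids: Sequence[str],
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    seed: int = 0,
) -> np.ndarray:
    """Marker-based cell-cycle phase call (fallback when labels are absent).

    Each cell's S and G2/M scores are the mean normalized expression over the
    marker genes minus the mean over a size-matched random background (seeded).
    The phase is the argmax of the two scores, or G1 when both are <= 0.
    """
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    index = pd.Index(gene_ids)
    rng = np.random.default_rng(seed)
    scores = {}
    for name, markers in (("S", s_genes), ("G2M", g2m_genes)):
        idx = index.get_indexer([g for g in markers if g in index])
        idx = idx[idx >= 0]
        if idx.size == 0:
            raise ValueError(f"no {name} marker genes found in the gene universe")
        pool = np.setdiff1d(np.arange(len(index)), idx)
        bg = rng.choice(pool, size=min(idx.size, pool.size), replace=False)
        scores[name] = expr[:, idx].mean(axis=1) - expr[:, bg].mean(axis=1)
    s, g2m = scores["S"], scores["G2M"]
    phase = np.where(s >= g2m, "S", "G2M").astype(object)
    phase[(s <= 0) & (g2m <= 0)] = "G1"
    return np.asarray(phase, dtype=object)
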
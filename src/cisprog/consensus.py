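"""Cross-replicate consensus of selected PC programs.

Selected components from independent replicate experiments that describe the
same underlying transcriptional program have strongly correlated gene
loadings (up to sign).  Programs are therefore compared by the absolute
Pearson correlation of their loading vectors, clustered hierarchically on
1 - |r|, and each cluster is summarised by a sign-aligned mean loading vector
and per-gene median weights; the median weights are the ranking fed to
preranked enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .programs import PCProgram

__all__ = [
    "ConsensusProgram",
    "loading_similarity",
    "cluster_programs",
    "consensus_program",
    "build_consensus",
]

MIN_SHARED_GENES = 50


@dataclass
class ConsensusProgram:
    """A cluster of PC programs with sign-aligned mean/median gene weights."""

    cluster_id: int
    member_pcs: list[tuple[str, int]]  # (experiment_id, pc_index)
    mean_loadings: pd.Series
    median_weights: pd.Series
    sign_reference: str

    @property
    def n_members(self) -> int:
        return len(self.member_pcs)

    def ranking(self) -> pd.Series:
        """Genes ranked by median weight, descending (enrichment input)."""
        return self.median_weights.sort_values(ascending=False, kind="stable")


def _sorted_programs(programs: Sequence[PCProgram]) -> list[PCProgram]:
    return sorted(programs, key=lambda p: p.program_id)


def loading_similarity(
    programs: Sequence[PCProgram],
    min_shared_genes: int = MIN_SHARED_GENES,
) -> pd.DataFrame:
    """|Pearson r| between loading vectors on pairwise gene intersections.

    Entries with fewer than ``min_shared_genes`` shared genes are NaN with a
    warning (too few genes for a stable correlation).  Programs are ordered
    lexicographically by id so the matrix is input-order invariant.
    """
    programs = _sorted_programs(programs)
    if len(programs) < 2:
        raise ValueError("need at least 2 programs")
    ids = [p.program_id for p in programs]
    n = len(programs)
    sim = np.eye(n)
    flagged = False
    for i in range(n):
        for j in range(i + 1, n):
            a, b = programs[i].loadings, programs[j].loadings
            shared = a.index.intersection(b.index)
            if len(shared) < min_shared_genes:
                sim[i, j] = sim[j, i] = np.nan
                flagged = True
                continue
            r = np.corrcoef(a.loc[shared], b.loc[shared])[0, 1]
            sim[i, j] = sim[j, i] = abs(r)
    if flagged:
        warnings.warn(
            f"program pair(s) share < {min_shared_genes} genes: similarity flagged missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(sim, index=ids, columns=ids)


def cluster_programs(
    similarity: pd.DataFrame,
    linkage: str = "average",
    height: Optional[float] = 0.7,
    k: Optional[int] = None,
) -> pd.Series:
    """Agglomerative clustering of programs on distance 1 - similarity.

    Cut either at a fixed distance ``height`` (default 0.7) or into exactly
    ``k`` clusters; ``k`` overrides ``height`` when given.  Missing similarity
    entries are imputed as distance 1 with a warning.  Returns cluster labels
    (1-based) indexed by program id.
    """
    sim = similarity.to_numpy(dtype=float).copy()
    if sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, equal_nan=True):
        raise ValueError("similarity matrix must be symmetric")
    if np.isnan(sim).any():
        warnings.warn(
            "missing similarity entries imputed as maximal distance",
            RuntimeWarning,
            stacklevel=2,
        )
        sim = np.where(np.isnan(sim), 0.0, sim)
    if sim.shape[0] == 1:
        return pd.Series([1], index=similarity.index, name="cluster")
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    if k is not None:
        labels = fcluster(z, t=k, criterion="maxclust")
    else:
        labels = fcluster(z, t=height, criterion="distance")
    # renumber clusters in order of first appearance for stable output
    remap: dict[int, int] = {}
    stable = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        stable.append(remap[lab])
    return pd.Series(stable, index=similarity.index, name="cluster")


def consensus_program(
    members: Sequence[PCProgram], cluster_id: int = 1
) -> ConsensusProgram:
    """Sign-aligned per-gene mean and median of a cluster's loading vectors.

    Members are aligned to the lexicographically first member (flipped when
    their Pearson correlation with it is negative) and summarised on the gene
    intersection of all members.
    """
    if not members:
        raise ValueError("need at least one member program")
    members = _sorted_programs(members)
    ref = members[0]
    shared = ref.loadings.index
    for m in members[1:]:
        shared = shared.intersection(m.loadings.index)
    if len(shared) == 0:
        raise ValueError("member programs share no genes")
    aligned = []
    for m in members:
        v = m.loadings.loc[shared].to_numpy(dtype=float)
        if m is not ref:
            r = np.corrcoef(ref.loadings.loc[shared], v)[0, 1]
            if r < 0:
                v = -v
        aligned.append(v)
    stack = np.vstack(aligned)
    return ConsensusProgram(
        cluster_id=cluster_id,
        member_pcs=[(m.experiment_id, m.pc_index) for m in members],
        mean_loadings=pd.Series(stack.mean(axis=0), index=shared),
        median_weights=pd.Series(np.median(stack, axis=0), index=shared),
        sign_reference=ref.program_id,
    )


def build_consensus(
    programs: Sequence[PCProgram],
    linkage: str = "average",
    height: Optional[float] = 0.7,
    k: Optional[int] = None,
    min_shared_genes: int = MIN_SHARED_GENES,
) -> tuple[pd.DataFrame, pd.Series, list[ConsensusProgram]]:
    """Similarity -> clustering -> per-cluster consensus in one call."""
    programs = _sorted_programs(programs)
    if len(programs) == 1:
        sim = pd.DataFrame([[1.0]], index=[programs[0].program_id], columns=[programs[0].program_id])
        labels = pd.Series([1], index=sim.index, name="cluster")
    else:
        sim = loading_similarity(programs, min_shared_genes=min_shared_genes)
        labels = cluster_programs(sim, linkage=linkage, height=height, k=k)
    by_id = {p.program_id: p for p in programs}
    consensus = []
    for cid in sorted(labels.unique()):
        members = [by_id[pid] for pid in labels.index[labels == cid]]
        consensus.append(consensus_program(members, cluster_id=int(cid)))
    return sim, labels, consensus
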
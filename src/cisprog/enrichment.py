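"""Preranked gene-set enrichment with a gene-label permutation null.

The enrichment score is the classic weighted Kolmogorov–Smirnov running-sum
statistic: walking down a ranking of genes, in-set genes increment the sum in
proportion to |weight|^p (p = 1 by default) normalized over the set, genes
outside the set decrement it by 1/(N - N_hit), and the score is the running
sum's largest absolute deviation.  Significance comes from permuting gene
labels (equivalently, drawing random same-size sets of ranked positions);
normalized scores divide by the mean |permuted score| of the same sign, and
p-values are adjusted across sets with Benjamini–Hochberg.  A result's
GeneRatio is the leading-edge fraction of the set, used together with the
adjusted p-value to filter reportable sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "GseaResult",
    "read_gmt",
    "enrichment_score",
    "gsea_preranked",
    "filter_results",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), duplicates within a set removed."""

    sets: dict[str, list[str]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    set_size_used: int
    leading_edge: list[str]
    gene_ratio: float


class GmtFormatError(ValueError):
    pass


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicated gene(s) in set {name!r} dropped",
                    RuntimeWarning,
                    stacklevel=2,
                )
            sets[name] = deduped
    return GeneSetCollection(sets=sets, source=str(path))


def _candidate_extrema(
    hit_weights: np.ndarray, hit_positions: np.ndarray, n_genes: int
) -> tuple[float, float]:
    """Max/min of the running sum from hit weights and sorted hit positions.

    Positions are 1-based.  The running sum's local maxima occur immediately
    after a hit and local minima immediately before one; the sum returns to 0
    at the end of the ranking.
    """
    k = hit_positions.size
    miss_step = 1.0 / (n_genes - k) if n_genes > k else 0.0
    cum = np.cumsum(hit_weights)
    total = cum[-1]
    if total <= 0:  # degenerate all-zero weights: hits count equally
        cum = np.arange(1, k + 1, dtype=float) / k
    else:
        cum = cum / total
    misses_before = (hit_positions - np.arange(1, k + 1)) * miss_step
    after_hit = cum - misses_before
    before_hit = np.concatenate(([0.0], cum[:-1])) - misses_before
    return float(after_hit.max()), float(before_hit.min())


def enrichment_score(
    ranking: pd.Series | Sequence[tuple[str, float]],
    gene_set: Sequence[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a gene set against a ranking.

    ``ranking`` maps genes to weights, sorted by weight descending.  Returns
    ``(es, running_statistic, leading_edge)``: the score is the running sum's
    largest absolute deviation (positive preferred on exact ties); the leading
    edge contains the in-set genes at or before a positive extremum, or
    strictly after a negative one.  Raises if the set and ranking share no
    genes.
    """
    if not isinstance(ranking, pd.Series):
        ranking = pd.Series({g: w for g, w in ranking})
    genes = ranking.index.to_numpy(dtype=object)
    weights = ranking.to_numpy(dtype=float)
    if np.any(np.diff(weights) > 1e-12):
        raise ValueError("ranking must be sorted by weight, descending")
    n = genes.size
    in_set = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranking")

    w_abs = np.abs(weights) ** weight_exponent
    steps = np.zeros(n)
    if w_abs[in_set].sum() > 0:
        steps[in_set] = w_abs[in_set] / w_abs[in_set].sum()
    else:
        steps[in_set] = 1.0 / k
    if n > k:
        steps[~in_set] = -1.0 / (n - k)
    running = np.cumsum(steps)

    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = genes[: i_max + 1][in_set[: i_max + 1]]
    else:
        es = float(running[i_min])
        leading = genes[i_min + 1 :][in_set[i_min + 1 :]]
    return es, running, list(leading)


def gsea_preranked(
    ranking: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> list[GseaResult]:
    """Preranked GSEA over a collection with a seeded permutation null.

    Sets are filtered by size after intersecting with the ranking.  For each
    retained set, the null distribution comes from ``n_perm`` random draws of
    the same number of ranked positions (gene-label permutation);
    ``p = (1 + #{same-sign |ES_perm| >= |ES|}) / (1 + #same-sign)`` and
    ``NES = ES / mean(|ES_perm| of the same sign)``.  FDR is Benjamini–
    Hochberg across the retained sets.
    """
    ranking = ranking.sort_values(ascending=False, kind="stable")
    if ranking.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    genes = ranking.index.to_numpy(dtype=object)
    n = genes.size
    w_abs = np.abs(ranking.to_numpy(dtype=float)) ** weight_exponent
    rng = np.random.default_rng(seed)

    retained: list[tuple[str, np.ndarray]] = []
    for name, members in collection.sets.items():
        in_set = np.isin(genes, np.asarray(list(members), dtype=object))
        k = int(in_set.sum())
        if min_size <= k <= max_size:
            retained.append((name, np.flatnonzero(in_set)))
    if not retained:
        warnings.warn("no gene set passed the size filter", RuntimeWarning, stacklevel=2)
        return []

    results = []
    for name, hit_idx in retained:
        es, _, leading = enrichment_score(
            ranking, genes[hit_idx], weight_exponent=weight_exponent
        )
        k = hit_idx.size
        # permutation null: random position sets of size k
        perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        perm_pos.sort(axis=1)
        perm_w = w_abs[perm_pos]
        cum = np.cumsum(perm_w, axis=1)
        totals = cum[:, -1:]
        safe = np.where(totals > 0, totals, 1.0)
        cum = np.where(totals > 0, cum / safe, np.arange(1, k + 1) / k)
        miss_step = 1.0 / (n - k) if n > k else 0.0
        misses_before = (perm_pos + 1 - np.arange(1, k + 1)) * miss_step
        after_hit = cum - misses_before
        before_hit = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - misses_before
        perm_max = after_hit.max(axis=1)
        perm_min = before_hit.min(axis=1)
        perm_es = np.where(perm_max >= -perm_min, perm_max, perm_min)

        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0 / (1.0 + 0.0)
            nes = np.nan
        else:
            exceed = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
            p = (1.0 + exceed) / (1.0 + n_same)
            denom = float(np.abs(perm_es[same_sign]).mean())
            nes = es / denom if denom > 0 else np.nan
        results.append(
            GseaResult(
                set_name=name,
                es=es,
                nes=float(nes),
                p_value=float(p),
                fdr=np.nan,
                set_size_used=k,
                leading_edge=leading,
                gene_ratio=len(leading) / k,
            )
        )

    pvals = np.array([r.p_value for r in results])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return results


def filter_results(
    results: Sequence[GseaResult],
    fdr_max: float = 0.05,
    gene_ratio_min: float = 0.4,
) -> list[GseaResult]:
    """Reportable results: adjusted p below ``fdr_max`` and GeneRatio above
    ``gene_ratio_min``."""
    return [r for r in results if r.fdr < fdr_max and r.gene_ratio > gene_ratio_min]


def results_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    """Tabular view of GSEA results."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "set_size_used": [r.set_size_used for r in results],
            "gene_ratio": [r.gene_ratio for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
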
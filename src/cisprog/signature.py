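"""Cisplatin expression signatures, per-cell sensitivity scores and classes.

The signature of one experiment is the per-gene Cohen's d between all
cisplatin-treated cells (every dose and duration pooled) and untreated cells
(control and vehicle pooled), computed on library-size-normalised
log-transformed expression.  Averaging the signatures of all experiments gives
the universal signature.  The per-cell sensitivity score (CisSenScore) is the
log2 ratio of raw counts falling in the most up-regulated signature genes to
counts in the most down-regulated ones; within the highest-dose/longest
duration stratum of each experiment, cells in the top quartile of scores are
called more-sensitive and the bottom quartile less-sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import ExperimentBundle

__all__ = [
    "EffectSignature",
    "cohens_d",
    "cohens_d_matrix",
    "log_normalize",
    "extract_signature",
    "signature_agreement",
    "universal_signature",
    "signature_gene_sets",
    "cis_sen_score",
    "cis_sen_scores",
    "classify_sensitivity",
    "MORE_SENSITIVE",
    "LESS_SENSITIVE",
    "UNLABELED",
]

MORE_SENSITIVE = "more_sensitive"
LESS_SENSITIVE = "less_sensitive"
UNLABELED = "unlabeled"


@dataclass
class EffectSignature:
    """Per-gene treated-minus-control effect sizes for one experiment.

    ``d_values`` are NaN for genes with zero pooled variance (flagged
    missing, never infinite).
    """

    experiment_id: str
    gene_ids: list[str]
    d_values: np.ndarray
    n_treated: int
    n_control: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d_values = np.asarray(self.d_values, dtype=float)
        if len(self.d_values) != len(self.gene_ids):
            raise ValueError("d_values length must equal gene_ids length")

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.d_values, index=self.gene_ids, name=self.experiment_id)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference (a minus b) with pooled SD.

    Returns NaN when the pooled SD is zero. Antisymmetric in its arguments and
    invariant under common shift and common positive scaling.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def cohens_d_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Cohen's d between two cells-x-features matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 rows")
    na, nb = a.shape[0], b.shape[0]
    pooled_var = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(pooled_var)
    d[pooled_var <= 0] = np.nan
    return d


def log_normalize(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log1p of counts-per-``scale`` (default counts per 10,000).

    Cells with zero total count yield all-zero rows (flagged upstream).
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cp = np.where(totals > 0, counts / totals * scale, 0.0)
    return np.log1p(cp)


def extract_signature(bundle: ExperimentBundle) -> EffectSignature:
    """Per-gene Cohen's d of treated (all doses/durations) vs untreated cells."""
    required = {"condition", "dose_fraction"}
    if not required <= set(bundle.cell_meta.columns):
        raise ValueError(f"cell metadata lacks columns {sorted(required)}")
    treated = bundle.cell_meta["dose_fraction"].to_numpy() > 0
    if treated.sum() < 2 or (~treated).sum() < 2:
        raise ValueError("need >=2 treated and >=2 untreated cells")
    expr = log_normalize(bundle.counts)
    d = cohens_d_matrix(expr[treated], expr[~treated])
    return EffectSignature(
        experiment_id=bundle.experiment_id,
        gene_ids=list(bundle.gene_ids),
        d_values=d,
        n_treated=int(treated.sum()),
        n_control=int((~treated).sum()),
    )


def signature_agreement(signatures: Sequence[EffectSignature]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix between signatures.

    Missing-flag (NaN) genes are dropped pairwise; pairs with fewer than two
    shared non-missing genes get a NaN entry.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    ids = [s.experiment_id for s in signatures]
    table = pd.concat([s.series for s in signatures], axis=1)
    n = len(signatures)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pair = table.iloc[:, [i, j]].dropna()
            if len(pair) < 2:
                r = np.nan
            else:
                r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=ids, columns=ids)


def universal_signature(signatures: Sequence[EffectSignature]) -> EffectSignature:
    """Per-gene mean of effect sizes over experiments (NaNs ignored per gene)."""
    if not signatures:
        raise ValueError("need at least one signature")
    table = pd.concat([s.series for s in signatures], axis=1)
    mean_d = table.mean(axis=1, skipna=True)
    return EffectSignature(
        experiment_id="universal",
        gene_ids=list(mean_d.index),
        d_values=mean_d.to_numpy(),
        n_treated=int(sum(s.n_treated for s in signatures)),
        n_control=int(sum(s.n_control for s in signatures)),
    )


def signature_gene_sets(
    signature: EffectSignature, top_n: int = 1000, bottom_n: int = 10000
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Indices of the highest- and lowest-effect-size genes of a signature.

    Genes are ordered by effect size with ties broken by gene id; NaN genes are
    excluded.  When the panel has fewer than ``top_n + bottom_n`` usable genes,
    both sets shrink proportionally to 5% (top) and 50% (bottom) of the usable
    genes, recorded in the returned metadata.
    """
    if top_n < 1 or bottom_n < 1:
        raise ValueError("top_n and bottom_n must be >= 1")
    d = signature.d_values
    valid = np.flatnonzero(~np.isnan(d))
    gene_keys = np.asarray(signature.gene_ids, dtype=object)[valid]
    # descending d, ties by gene id ascending
    order = valid[np.lexsort((gene_keys, -d[valid]))]
    n_valid = order.size
    scaled = top_n + bottom_n > n_valid
    if scaled:
        top_eff = max(1, int(round(0.05 * n_valid)))
        bottom_eff = max(1, int(round(0.50 * n_valid)))
    else:
        top_eff, bottom_eff = top_n, bottom_n
    info = {
        "top_n_used": top_eff,
        "bottom_n_used": bottom_eff,
        "scaled_to_panel": scaled,
        "n_valid_genes": int(n_valid),
    }
    return order[:top_eff], order[-bottom_eff:], info


def cis_sen_scores(
    counts: np.ndarray,
    signature: EffectSignature,
    top_n: int = 1000,
    bottom_n: int = 10000,
) -> np.ndarray:
    """Per-cell CisSenScore over a cells-x-genes raw count matrix.

    log2((1 + counts in the ``top_n`` highest-effect genes) /
    (1 + counts in the ``bottom_n`` lowest-effect genes)); the large bottom
    set controls for total-count variation.
    """
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[1] != len(signature.gene_ids):
        raise ValueError("counts column count does not match signature gene universe")
    top_idx, bottom_idx, _ = signature_gene_sets(signature, top_n, bottom_n)
    top_sum = counts[:, top_idx].sum(axis=1)
    bottom_sum = counts[:, bottom_idx].sum(axis=1)
    return np.log2((1.0 + top_sum) / (1.0 + bottom_sum))


def cis_sen_score(
    counts_row: np.ndarray,
    signature: EffectSignature,
    top_n: int = 1000,
    bottom_n: int = 10000,
) -> float:
    """CisSenScore of a single cell (see :func:`cis_sen_scores`)."""
    return float(cis_sen_scores(np.atleast_2d(counts_row), signature, top_n, bottom_n)[0])


def classify_sensitivity(
    scores: np.ndarray,
    fraction: float = 0.25,
    cell_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Quantile classification of cells into sensitivity groups.

    Cells at or above the upper ``1 - fraction`` quantile (linear-interpolation
    quantiles) are ``more_sensitive``, at or below the lower ``fraction``
    quantile ``less_sensitive``, the rest ``unlabeled``.  Ties that would
    inflate a class beyond its quota — including fully degenerate score
    vectors — are resolved by stable cell order, with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 cells to classify")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]

    lo = np.quantile(scores, fraction)
    hi = np.quantile(scores, 1.0 - fraction)
    labels = np.full(n, UNLABELED, dtype=object)
    quota = int(round(fraction * n))

    if np.allclose(scores, scores[0]):
        warnings.warn(
            "degenerate score distribution: classes assigned by stable cell order",
            RuntimeWarning,
            stacklevel=2,
        )
        order = np.argsort(scores, kind="stable")
        labels[order[:quota]] = LESS_SENSITIVE
        labels[order[-quota:]] = MORE_SENSITIVE
    else:
        more = scores >= hi
        less = scores <= lo
        overlap = more & less
        more &= ~overlap
        less &= ~overlap
        for mask, label, extreme_first in ((more, MORE_SENSITIVE, False), (less, LESS_SENSITIVE, True)):
            idx = np.flatnonzero(mask)
            if idx.size > quota + 1:
                warnings.warn(
                    f"score ties at the {label} boundary: trimming to quota by stable order",
                    RuntimeWarning,
                    stacklevel=2,
                )
                key = scores[idx] if extreme_first else -scores[idx]
                idx = idx[np.argsort(key, kind="stable")][:quota]
            labels[idx] = label

    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "cis_sen_score": scores,
            "sens_class": labels,
            "top_fraction_used": fraction,
        }
    )
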
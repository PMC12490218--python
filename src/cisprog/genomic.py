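"""Gene-dosage perturbation scores, detection power, and size factors.

Three small quantitative tools that accompany the single-cell pipeline:

* **Gene dosage** — the number of intact copies of a gene divided by the
  genome's reference (modal) copy number.  A dosage at or below 0.5 (at least
  half the copies lost) or at or above 2.0 (at least doubled) is called
  perturbed, and a pathway's perturbation score sums |log2 dosage| over its
  perturbed genes, so a single-copy loss and a single doubling contribute
  symmetrically (1 each).
* **Poisson detection power** — the probability of observing a recurrent
  alteration at least ``k_min`` times in a cohort of ``n`` tumors when it
  occurs at population frequency ``freq``, with the hit count modeled as
  Poisson(n * freq).
* **Composition-weighted size factors** — per-sample normalisation factors
  for bulk expression built from an external per-sample scale factor times
  the fraction of the sample attributable to the cell population of interest,
  normalised to geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DosageRecord",
    "DOSAGE_FLOOR",
    "gene_dosage",
    "pathway_perturbation_score",
    "poisson_detection_power",
    "composition_size_factors",
]

# dosage assigned to homozygous deletions so log2 stays finite; any positive
# value below the 0.5 perturbation threshold preserves the call
DOSAGE_FLOOR = 2.0**-5

LOW_THRESHOLD = 0.5
HIGH_THRESHOLD = 2.0


@dataclass(frozen=True)
class DosageRecord:
    """Dosage of intact copies of one gene relative to the reference CN."""

    gene: str
    intact_copies: float
    reference_cn: float
    dosage: float
    perturbed: bool


def gene_dosage(gene: str, intact_copies: float, reference_cn: float) -> DosageRecord:
    """Dosage = intact copies / reference copy number, with perturbation call.

    Perturbed iff dosage <= 0.5 or >= 2.0 (both boundaries inclusive).  A zero
    dosage (homozygous deletion) is floored at 2^-5 so downstream log2 scores
    stay finite; the perturbation call is made before flooring.
    """
    if reference_cn <= 0:
        raise ValueError("reference_cn must be positive")
    if intact_copies < 0:
        raise ValueError("intact_copies must be non-negative")
    dosage = intact_copies / reference_cn
    perturbed = dosage <= LOW_THRESHOLD or dosage >= HIGH_THRESHOLD
    if dosage == 0:
        dosage = DOSAGE_FLOOR
    return DosageRecord(
        gene=gene,
        intact_copies=float(intact_copies),
        reference_cn=float(reference_cn),
        dosage=float(dosage),
        perturbed=bool(perturbed),
    )


def pathway_perturbation_score(records: Sequence[DosageRecord]) -> float:
    """Sum of |log2 dosage| over the perturbed genes of a pathway.

    Non-perturbed genes contribute nothing; an empty or unperturbed pathway
    scores 0.  Additive over disjoint gene lists.
    """
    return float(sum(abs(np.log2(r.dosage)) for r in records if r.perturbed))


def dosage_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised dosage records from a table with columns
    ``gene, intact_copies, reference_cn`` (extra columns pass through)."""
    records = [
        gene_dosage(str(row.gene), float(row.intact_copies), float(row.reference_cn))
        for row in frame.itertuples(index=False)
    ]
    out = frame.copy()
    out["dosage"] = [r.dosage for r in records]
    out["perturbed"] = [r.perturbed for r in records]
    return out


def poisson_detection_power(n: int, freq: float, k_min: int = 2) -> float:
    """P(X >= k_min) for X ~ Poisson(n * freq): cohort detection power.

    ``n`` is the cohort size, ``freq`` the population frequency of the
    alteration, and ``k_min`` the minimum number of observations counted as a
    detection (default 2, i.e. a recurrent alteration).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not 0 <= freq <= 1:
        raise ValueError("freq must be within [0, 1]")
    if k_min < 0:
        raise ValueError("k_min must be non-negative")
    if k_min == 0:
        return 1.0
    return float(stats.poisson.sf(k_min - 1, mu=n * freq))


def composition_size_factors(
    scale: Sequence[float], abundance: Sequence[float]
) -> np.ndarray:
    """Per-sample size factors: scale x abundance over their geometric mean."""
    scale = np.asarray(scale, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if scale.size == 0 or scale.shape != abundance.shape:
        raise ValueError("scale and abundance must be equal-length, non-empty")
    if np.any(scale <= 0) or np.any(abundance <= 0):
        raise ValueError("scale and abundance must be positive")
    product = scale * abundance
    return product / stats.gmean(product)
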
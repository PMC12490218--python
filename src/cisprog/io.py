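"""Reading and writing experiment bundles (MatrixMarket + TSV sidecars).

Layout of a bundle directory::

    matrix.mtx        cells x genes integer counts, MatrixMarket coordinate
    barcodes.tsv      one cell id per line
    features.tsv      one gene id per line
    cell_meta.tsv     cell_id, condition, dose_fraction, duration_h,
                      replicate, archetype, phase
    ground_truth/     optional planted-truth sidecars (TSV)
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import ExperimentBundle, GroundTruth

__all__ = ["write_bundle", "read_bundle", "BundleFormatError"]

META_COLUMNS = [
    "cell_id",
    "condition",
    "dose_fraction",
    "duration_h",
    "replicate",
    "archetype",
    "phase",
]


class BundleFormatError(ValueError):
    """Raised when bundle files are missing, malformed or inconsistent."""


def write_bundle(bundle: ExperimentBundle, directory: str | os.PathLike) -> Path:
    """Write a bundle to ``directory`` (created if needed); returns the path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(d / "matrix.mtx", sparse.coo_matrix(bundle.counts), field="integer")
    pd.Series(bundle.cell_meta["cell_id"]).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(bundle.gene_ids).to_csv(d / "features.tsv", sep="\t", index=False, header=False)
    bundle.cell_meta.to_csv(d / "cell_meta.tsv", sep="\t", index=False)

    if bundle.ground_truth is not None:
        gt = bundle.ground_truth
        gtd = d / "ground_truth"
        gtd.mkdir(exist_ok=True)
        gt.program_loadings.to_csv(gtd / "program_loadings.tsv", sep="\t")
        gt.cell_activities.to_csv(gtd / "cell_activities.tsv", sep="\t")
        pd.DataFrame(
            {
                "gene_id": bundle.gene_ids,
                "response": gt.response_vector,
            }
        ).to_csv(gtd / "response_vector.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "cell_id": bundle.cell_meta["cell_id"],
                "responsiveness": gt.cell_responsiveness,
                "phase": gt.phase_labels,
            }
        ).to_csv(gtd / "cell_truth.tsv", sep="\t", index=False)
    return d


def read_bundle(directory: str | os.PathLike) -> ExperimentBundle:
    """Read a bundle directory written by :func:`write_bundle`.

    Validates that the matrix dimensions match the sidecars and that counts
    are non-negative integers; inverse of ``write_bundle`` on counts and
    metadata.
    """
    d = Path(directory)
    for fname in ("matrix.mtx", "barcodes.tsv", "features.tsv", "cell_meta.tsv"):
        if not (d / fname).exists():
            raise BundleFormatError(f"missing file: {d / fname}")

    counts = spio.mmread(d / "matrix.mtx")
    counts = np.asarray(sparse.coo_matrix(counts).todense())
    if np.any(counts < 0):
        raise BundleFormatError(f"{d / 'matrix.mtx'}: negative count entries")
    counts = counts.astype(np.int64)

    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    meta = pd.read_csv(d / "cell_meta.tsv", sep="\t")

    if counts.shape[0] != len(barcodes):
        raise BundleFormatError(
            f"{d / 'barcodes.tsv'}: {len(barcodes)} barcodes but matrix has "
            f"{counts.shape[0]} rows"
        )
    if counts.shape[1] != len(genes):
        raise BundleFormatError(
            f"{d / 'features.tsv'}: {len(genes)} features but matrix has "
            f"{counts.shape[1]} columns"
        )
    if len(meta) != len(barcodes) or list(meta["cell_id"]) != list(map(str, barcodes)):
        raise BundleFormatError(f"{d / 'cell_meta.tsv'}: cell ids disagree with barcodes.tsv")

    truth = None
    gtd = d / "ground_truth"
    if gtd.is_dir():
        loadings = pd.read_csv(gtd / "program_loadings.tsv", sep="\t", index_col=0)
        acts = pd.read_csv(gtd / "cell_activities.tsv", sep="\t", index_col=0)
        resp = pd.read_csv(gtd / "response_vector.tsv", sep="\t")
        cell_truth = pd.read_csv(gtd / "cell_truth.tsv", sep="\t")
        truth = GroundTruth(
            program_loadings=loadings,
            cell_activities=acts,
            response_vector=resp["response"].to_numpy(),
            cell_responsiveness=cell_truth["responsiveness"].to_numpy(),
            phase_labels=cell_truth["phase"].to_numpy(),
        )

    return ExperimentBundle(counts=counts, cell_meta=meta, gene_ids=genes, ground_truth=truth)
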
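"""Epigenomic feature contracts: track summarization and pluggable extractors.

A gene's raw epigenomic representation is a track matrix of 896 genomic bins
(128 bp each, covering the central 114,688 bp window around the TSS) by 5313
tracks, as produced by a sequence-to-epigenome model. The per-gene feature
vector is the column mean over the four central bins (447-450, 1-based) —
the local TSS region.

Two extractors implement the contract:

* ``FileBackedExtractor`` reads precomputed track matrices / personalized
  vectors from an HDF5 container (``tracks/<gene>`` for reference matrices,
  ``personalized/<gene>/<individual>`` for per-individual vectors). Running
  the upstream sequence model is out of scope.
* ``SyntheticExtractor`` serves vectors from the synthetic generator and is a
  pure function of (gene, genotype, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GeneAnnotation, GenotypePanel
from .synthetic_data import FeatureSet, SimConfig, simulate_features

N_BINS = 896
N_TRACKS = 5313
DEFAULT_BINS = (447, 450)  # 1-based inclusive central four bins


@dataclass
class TrackMatrix:
    """Binned track predictions for one gene (bins x tracks)."""

    gene_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("track matrix must be 2-D (bins x tracks)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("track matrix contains non-finite values")


@dataclass
class FeatureVector:
    """Length-D epigenomic representation of a gene (optionally per individual)."""

    gene_id: str
    values: np.ndarray
    individual_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector contains non-finite values")


def summarize_tracks(tm: TrackMatrix, bins: tuple[int, int] = DEFAULT_BINS) -> FeatureVector:
    """Column-wise mean over a 1-based inclusive bin range (default 447-450)."""
    lo, hi = bins
    n_bins = tm.matrix.shape[0]
    if not (1 <= lo <= hi <= n_bins):
        raise ValueError(f"bins {bins} out of range [1, {n_bins}] (1-based inclusive)")
    return FeatureVector(gene_id=tm.gene_id, values=tm.matrix[lo - 1 : hi].mean(axis=0))


class FileBackedExtractor:
    """Serve features from an HDF5 container of precomputed arrays."""

    def __init__(self, path, bins: tuple[int, int] = DEFAULT_BINS):
        import h5py

        self._h5 = h5py.File(path, "r")
        self.bins = bins

    def close(self) -> None:
        self._h5.close()

    def reference(self, gene_id: str) -> FeatureVector:
        key = f"tracks/{gene_id}"
        if key not in self._h5:
            raise KeyError(f"no features for gene {gene_id!r}")
        tm = TrackMatrix(gene_id=gene_id, matrix=self._h5[key][()])
        return summarize_tracks(tm, self.bins)

    def personalized(self, gene_id: str, individual_id: str) -> FeatureVector:
        key = f"personalized/{gene_id}/{individual_id}"
        if key not in self._h5:
            raise KeyError(f"no personalized features for {gene_id!r}/{individual_id!r}")
        return FeatureVector(gene_id=gene_id, values=self._h5[key][()],
                             individual_id=individual_id)


class SyntheticExtractor:
    """Serve features computed by the synthetic generator.

    Deterministic in (config seed, gene, individual); vectors for a whole
    panel are materialized once and cached.
    """

    def __init__(self, config: SimConfig, panel: GenotypePanel, truth):
        self.config = config
        self.panel = panel
        self.truth = truth
        self._features: FeatureSet = simulate_features(panel, truth, config)
        self._ind_index = {ind: i for i, ind in enumerate(self._features.individual_ids)}

    def reference(self, gene_id: str) -> FeatureVector:
        if gene_id not in self._features.reference:
            raise KeyError(f"no features for gene {gene_id!r}")
        return FeatureVector(gene_id=gene_id, values=self._features.reference[gene_id])

    def personalized(self, gene_id: str, individual_id: str) -> FeatureVector:
        if gene_id not in self._features.personalized:
            raise KeyError(f"no features for gene {gene_id!r}")
        if individual_id not in self._ind_index:
            raise KeyError(f"individual {individual_id!r} not in panel")
        row = self._features.personalized[gene_id][self._ind_index[individual_id]]
        return FeatureVector(gene_id=gene_id, values=row, individual_id=individual_id)

    def personalized_matrix(self, gene_id: str) -> np.ndarray:
        """(n_individuals, D) matrix for one gene, panel order."""
        if gene_id not in self._features.personalized:
            raise KeyError(f"no features for gene {gene_id!r}")
        return self._features.personalized[gene_id]


def extract_reference(extractor, gene_id: str, annotation: GeneAnnotation) -> FeatureVector:
    """Reference feature vector for an annotated gene."""
    annotation.record(gene_id)  # raises KeyError if unannotated
    return extractor.reference(gene_id)


def extract_personalized(extractor, gene_id: str, individual_id: str,
                         panel: GenotypePanel) -> FeatureVector:
    """Personalized feature vector for one individual in the panel."""
    if individual_id not in panel.individual_ids:
        raise KeyError(f"individual {individual_id!r} not in panel")
    return extractor.personalized(gene_id, individual_id)
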
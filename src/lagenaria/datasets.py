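"""Packaged study data: the published band matrices and reference
tables for the ten Egyptian bottle gourd cultivars (S1..S10).

* ``protein_sds_page`` — 17 SDS-PAGE protein bands (kDa), presence/absence.
* ``isozyme_pod`` / ``isozyme_ppo`` — 5 peroxidase / 5 polyphenol-oxidase
  bands (relative mobility Rm) with density grades 1-3.
* ``scot_similarity`` — the published 10x10 Jaccard matrix from the
  SCoT fingerprints (the underlying 44-band SCoT matrix itself was not
  published; the similarity matrix is the primary data).
* ``scot_primer_counts`` — the published per-primer amplification
  summary (band counts and index values as printed).
* ``scot_unique_markers`` — the published genotype-specific SCoT bands.
* ``*_similarity_published`` — the published protein and pooled
  protein+isozyme Jaccard matrices, kept as reference values that the
  pipeline recomputes from the band matrices.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .bandmatrix import BandMatrix, read_band_matrix
from .similarity import SimilarityMatrix, read_similarity

__all__ = [
    "data_path",
    "protein_sds_page",
    "isozyme_pod",
    "isozyme_ppo",
    "scot_similarity",
    "scot_primer_counts",
    "scot_unique_markers",
    "protein_similarity_published",
    "pooled_similarity_published",
]


def _base(data_dir: str | Path | None = None) -> Path:
    return Path(data_dir) if data_dir else Path(str(resources.files(__package__))) / "data"


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return _base() / name


def protein_sds_page(data_dir: str | Path | None = None) -> BandMatrix:
    """17 protein bands x 10 cultivars (SDS-PAGE)."""
    return read_band_matrix(_base(data_dir) / "protein_sds_page.csv")


def isozyme_pod(data_dir: str | Path | None = None) -> BandMatrix:
    """5 peroxidase bands x 10 cultivars, density grades 1-3."""
    return read_band_matrix(_base(data_dir) / "isozyme_pod.csv", values="intensity")


def isozyme_ppo(data_dir: str | Path | None = None) -> BandMatrix:
    """5 polyphenol-oxidase bands x 10 cultivars, density grades 1-3."""
    return read_band_matrix(_base(data_dir) / "isozyme_ppo.csv", values="intensity")


def scot_similarity() -> SimilarityMatrix:
    """Published Jaccard similarity from the 8-primer SCoT fingerprints."""
    return read_similarity(data_path("scot_similarity.csv"))


def scot_primer_counts() -> pd.DataFrame:
    """Published per-primer SCoT summary (counts and indices as printed)."""
    return pd.read_csv(data_path("scot_primer_counts.csv"))


def scot_unique_markers() -> pd.DataFrame:
    """Published genotype-specific SCoT markers."""
    return pd.read_csv(data_path("scot_unique_markers.csv"))


def protein_similarity_published() -> SimilarityMatrix:
    """Published protein-marker Jaccard matrix (reference values)."""
    return read_similarity(data_path("protein_similarity_published.csv"))


def pooled_similarity_published() -> SimilarityMatrix:
    """Published pooled protein+isozyme Jaccard matrix (reference values).

    One published cell, (S2, S7), is internally inconsistent with the
    published band matrices: S7's band profile is identical to those of
    S3/S4/S5/S10, so its similarity against S2 must equal theirs
    (0.852); the table prints 0.825 for that single cell (a digit
    transposition). Comparisons should treat that cell accordingly.
    """
    return read_similarity(data_path("pooled_similarity_published.csv"))
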
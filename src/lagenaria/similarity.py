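"""Pairwise genotype similarity from binary band data.

For two genotype columns let a = shared presences, b = presences only
in the first, c = presences only in the second, d = shared absences.

* Jaccard:         a / (a + b + c)   -- shared absences ignored
* Dice:            2a / (2a + b + c)
* simple matching: (a + d) / (a + b + c + d)

Jaccard is the coefficient used throughout the cultivar analysis; the
alternatives are provided for comparison. A pair with empty union
(a + b + c = 0) is assigned similarity 0 with a warning; it cannot
occur in a valid band matrix alone (no all-zero loci) but can for a
genotype carrying no bands at all in a subset view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .bandmatrix import BandMatrix

__all__ = [
    "SimilarityMatrix",
    "SimilarityReport",
    "jaccard",
    "alt_coefficients",
    "similarity_report",
    "round_half_up",
    "read_similarity",
    "write_similarity",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding, matching how the reference tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SimilarityMatrix:
    """Symmetric genotype x genotype coefficient matrix, diagonal 1."""

    genotypes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = list(self.genotypes)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotypes)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} genotypes"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be exactly 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def value(self, x: str, y: str) -> float:
        return float(self.values[self.genotypes.index(x), self.genotypes.index(y)])

    def to_frame(self, ndigits: int | None = None) -> pd.DataFrame:
        vals = self.values
        if ndigits is not None:
            vals = np.vectorize(lambda v: round_half_up(v, ndigits))(vals)
        return pd.DataFrame(vals, index=self.genotypes, columns=self.genotypes)

    def distance(self) -> np.ndarray:
        """Complement distance d = 1 - s."""
        return 1.0 - self.values


@dataclass(frozen=True)
class SimilarityReport:
    """Off-diagonal extremes of a similarity matrix; ties exhaustive."""

    min_value: float
    min_pairs: list[tuple[str, str]]
    max_value: float
    max_pairs: list[tuple[str, str]]


def _counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return a, b, c, d


def _pairwise(matrix: BandMatrix, method: str) -> SimilarityMatrix:
    if matrix.n_genotypes < 2:
        raise ValueError("similarity requires at least 2 genotypes")
    n = matrix.n_genotypes
    cols = matrix.presence.T
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b, c, d = _counts(cols[i], cols[j])
            if method == "jaccard":
                union = a + b + c
                if union == 0:
                    warnings.warn(
                        f"genotypes {matrix.genotypes[i]!r} and "
                        f"{matrix.genotypes[j]!r} share no observed bands; "
                        "Jaccard similarity set to 0",
                        stacklevel=3,
                    )
                    v = 0.0
                else:
                    v = a / union
            elif method == "dice":
                denom = 2 * a + b + c
                v = 2 * a / denom if denom else 0.0
            elif method == "simple_matching":
                v = (a + d) / (a + b + c + d)
            else:
                raise ValueError(f"unknown similarity method {method!r}")
            s[i, j] = s[j, i] = v
    return SimilarityMatrix(matrix.genotypes, s)


def jaccard(matrix: BandMatrix) -> SimilarityMatrix:
    """Jaccard similarity over all genotype pairs of a band matrix."""
    return _pairwise(matrix, "jaccard")


def alt_coefficients(matrix: BandMatrix, method: str) -> SimilarityMatrix:
    """Alternative binary coefficients: ``dice`` or ``simple_matching``."""
    if method not in ("dice", "simple_matching"):
        raise ValueError(f"unknown similarity method {method!r}")
    return _pairwise(matrix, method)


def similarity_report(s: SimilarityMatrix) -> SimilarityReport:
    """Minimum and maximum off-diagonal similarity with all attaining pairs."""
    n = s.n
    iu = np.triu_indices(n, k=1)
    vals = s.values[iu]
    lo, hi = vals.min(), vals.max()
    min_pairs = []
    max_pairs = []
    for i, j, v in zip(*iu, vals):
        pair = (s.genotypes[i], s.genotypes[j])
        if np.isclose(v, lo, atol=1e-12):
            min_pairs.append(pair)
        if np.isclose(v, hi, atol=1e-12):
            max_pairs.append(pair)
    return SimilarityReport(float(lo), min_pairs, float(hi), max_pairs)


# -- I/O -------------------------------------------------------------------


def write_similarity(
    s: SimilarityMatrix,
    path: str | Path,
    lower: bool = True,
    ndigits: int | None = 3,
) -> Path:
    """Write as delimited text; lower-triangular (as conventionally
    printed) or full square."""
    path = Path(path)
    df = s.to_frame(ndigits)
    if lower:
        mask = np.triu(np.ones(df.shape, dtype=bool), k=1)
        df = df.mask(mask)
    df.to_csv(path, float_format=None)
    return path


def read_similarity(path: str | Path) -> SimilarityMatrix:
    """Read a similarity matrix written by :func:`write_similarity`,
    or any labelled square/lower-triangular delimited table."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != labels:
        raise ValueError(f"{path}: row and column labels differ")
    vals = df.to_numpy(dtype=float)
    upper = np.triu_indices(len(labels), k=1)
    if np.isnan(vals[upper]).all():
        vals[upper] = vals.T[upper]
    if np.isnan(vals).any():
        raise ValueError(f"{path}: missing entries")
    return SimilarityMatrix(labels, vals)
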
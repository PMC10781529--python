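"""Binary band-matrix data model and I/O.

Dominant molecular markers (SCoT amplicons, SDS-PAGE protein bands,
native-gel isozymes) are scored per genotype as band present (1) or
absent (0). The resulting loci x genotypes presence/absence grid,
together with per-locus metadata (assay, primer/enzyme group, band
size), is the universal input of every downstream computation.

File dialect: delimited text (comma or tab, auto-detected), one row per
locus, columns ``locus_id, assay, group, size_label, <genotype_1> ...
<genotype_n>``. Entries are 0/1 (presence) or 0-3 (intensity grades
mirroring absent / + / ++ / +++ band density on the gel).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Locus",
    "BandMatrix",
    "BandMatrixError",
    "read_band_matrix",
    "write_band_matrix",
    "collapse_intensity",
    "pool",
]

ASSAYS = ("protein", "isozyme", "scot")

METADATA_COLUMNS = ("locus_id", "assay", "group", "size_label")


class BandMatrixError(ValueError):
    """Raised for malformed files or invalid matrix structure."""


@dataclass(frozen=True)
class Locus:
    """One scored band.

    ``size_label`` is the band size in the assay's native unit:
    molecular weight in kDa for protein bands, fragment length in bp
    for SCoT amplicons, or relative mobility Rm (a unitless fraction in
    [0, 1]) for isozymes.
    """

    locus_id: str
    assay: str
    group: str
    size_label: float

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise BandMatrixError(
                f"locus {self.locus_id!r}: unknown assay {self.assay!r}; "
                f"expected one of {ASSAYS}"
            )
        if self.assay == "isozyme":
            if not (0.0 <= self.size_label <= 1.0):
                raise BandMatrixError(
                    f"locus {self.locus_id!r}: Rm {self.size_label} outside [0, 1]"
                )
        elif self.size_label <= 0:
            raise BandMatrixError(
                f"locus {self.locus_id!r}: band size {self.size_label} must be positive"
            )


@dataclass
class BandMatrix:
    """Loci x genotypes presence/absence grid with per-locus metadata.

    ``presence`` has shape (n_loci, n_genotypes) with entries in {0, 1}.
    ``intensity``, if supplied, mirrors ``presence`` with grades {0..3};
    a positive grade implies presence and grade 0 implies absence.
    """

    genotypes: list[str]
    loci: list[Locus]
    presence: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = list(self.genotypes)
        self.loci = list(self.loci)
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.int8)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def validate(self) -> None:
        if not self.genotypes:
            raise BandMatrixError("matrix has no genotypes")
        if not self.loci:
            raise BandMatrixError("matrix has no loci")
        if len(set(self.genotypes)) != len(self.genotypes):
            dupes = sorted({g for g in self.genotypes if self.genotypes.count(g) > 1})
            raise BandMatrixError(f"duplicate genotype labels: {dupes}")
        ids = self.locus_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BandMatrixError(f"duplicate locus ids: {dupes}")
        if self.presence.shape != (self.n_loci, self.n_genotypes):
            raise BandMatrixError(
                f"presence shape {self.presence.shape} does not match "
                f"{self.n_loci} loci x {self.n_genotypes} genotypes"
            )
        bad = ~np.isin(self.presence, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise BandMatrixError(
                f"presence entry {self.presence[r, c]} at locus "
                f"{self.loci[r].locus_id!r}, genotype {self.genotypes[c]!r} "
                "is not 0/1"
            )
        zero_rows = np.flatnonzero(self.presence.sum(axis=1) == 0)
        if zero_rows.size:
            names = [self.loci[i].locus_id for i in zero_rows]
            raise BandMatrixError(
                f"loci observed in zero genotypes are not loci: {names}"
            )
        if self.intensity is not None:
            if self.intensity.shape != self.presence.shape:
                raise BandMatrixError("intensity shape does not match presence")
            if (~np.isin(self.intensity, (0, 1, 2, 3))).any():
                raise BandMatrixError("intensity grades must be in {0, 1, 2, 3}")
            if ((self.intensity > 0) != (self.presence > 0)).any():
                raise BandMatrixError(
                    "intensity > 0 must coincide exactly with presence = 1"
                )

    def subset_groups(self, groups: Iterable[str]) -> "BandMatrix":
        """Matrix restricted to loci whose group is in ``groups``."""
        wanted = set(groups)
        idx = [i for i, loc in enumerate(self.loci) if loc.group in wanted]
        if not idx:
            raise BandMatrixError(f"no loci in groups {sorted(wanted)}")
        return BandMatrix(
            genotypes=self.genotypes,
            loci=[self.loci[i] for i in idx],
            presence=self.presence[idx],
            intensity=None if self.intensity is None else self.intensity[idx],
        )

    def reorder_genotypes(self, order: Sequence[str]) -> "BandMatrix":
        if sorted(order) != sorted(self.genotypes):
            raise BandMatrixError(
                f"genotype sets differ: {sorted(order)} vs {sorted(self.genotypes)}"
            )
        pos = [self.genotypes.index(g) for g in order]
        return BandMatrix(
            genotypes=list(order),
            loci=self.loci,
            presence=self.presence[:, pos],
            intensity=None if self.intensity is None else self.intensity[:, pos],
        )

    def band_counts(self) -> dict[str, int]:
        """Bands observed per genotype (column sums of presence)."""
        sums = self.presence.sum(axis=0)
        return {g: int(s) for g, s in zip(self.genotypes, sums)}

    def equals(self, other: "BandMatrix") -> bool:
        if self.genotypes != other.genotypes or self.loci != other.loci:
            return False
        if not np.array_equal(self.presence, other.presence):
            return False
        if (self.intensity is None) != (other.intensity is None):
            return False
        if self.intensity is not None and not np.array_equal(
            self.intensity, other.intensity
        ):
            return False
        return True


# -- I/O -------------------------------------------------------------------


def _sniff_delimiter(sample: str) -> str:
    # comma or tab only; the formats in the field are one of the two
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_band_matrix(
    path: str | Path,
    values: Literal["auto", "presence", "intensity"] = "auto",
) -> BandMatrix:
    """Read a band matrix from delimited text.

    With ``values="auto"`` a file containing any grade > 1 is treated as
    intensity-graded; grades collapse to presence via grade >= 1.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text.splitlines()[0] if text else "")
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise BandMatrixError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    if [h.lower() for h in header[:4]] != list(METADATA_COLUMNS):
        raise BandMatrixError(
            f"{path}: header must start with {METADATA_COLUMNS}, got {header[:4]}"
        )
    genotypes = header[4:]
    if not genotypes:
        raise BandMatrixError(f"{path}: no genotype columns after metadata")
    if len(set(genotypes)) != len(genotypes):
        raise BandMatrixError(f"{path}: duplicate genotype columns in header")

    loci: list[Locus] = []
    grid: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        row = [c.strip() for c in row]
        if len(row) != len(header):
            raise BandMatrixError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        locus_id, assay, group, size_label = row[:4]
        try:
            size = float(size_label)
        except ValueError as exc:
            raise BandMatrixError(
                f"{path}:{lineno}: size_label {size_label!r} is not numeric"
            ) from exc
        loci.append(Locus(locus_id, assay.lower(), group, size))
        entries = []
        for g, cell in zip(genotypes, row[4:]):
            try:
                v = int(cell)
            except ValueError as exc:
                raise BandMatrixError(
                    f"{path}:{lineno}: entry {cell!r} in column {g!r} is not an integer"
                ) from exc
            entries.append(v)
        grid.append(entries)

    raw = np.array(grid, dtype=np.int8)
    upper = 3 if values == "intensity" or (values == "auto" and raw.max() > 1) else 1
    if raw.min() < 0 or raw.max() > upper:
        r, c = np.argwhere((raw < 0) | (raw > upper))[0]
        raise BandMatrixError(
            f"{path}: entry {raw[r, c]} at locus {loci[r].locus_id!r}, "
            f"genotype {genotypes[c]!r} outside 0..{upper}"
        )
    if upper == 3:
        return BandMatrix(genotypes, loci, (raw > 0).astype(np.int8), raw)
    return BandMatrix(genotypes, loci, raw)


def write_band_matrix(matrix: BandMatrix, path: str | Path, delimiter: str = ",") -> Path:
    """Write a matrix as delimited text (metadata columns, then genotypes).

    When the matrix carries intensity grades, grades 0-3 are written;
    otherwise 0/1 presence. Output is re-readable by
    :func:`read_band_matrix` and the round-trip is the identity.
    """
    matrix.validate()
    path = Path(path)
    grid = matrix.intensity if matrix.intensity is not None else matrix.presence
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(list(METADATA_COLUMNS) + matrix.genotypes)
        for loc, row in zip(matrix.loci, grid):
            w.writerow(
                [loc.locus_id, loc.assay, loc.group, f"{loc.size_label:g}"]
                + [int(v) for v in row]
            )
    return path


# -- transforms ------------------------------------------------------------


def collapse_intensity(matrix: BandMatrix) -> BandMatrix:
    """Collapse intensity grades to presence/absence (grade >= 1 -> 1).

    Band densities are gel observations; every similarity and
    polymorphism statistic is computed from presence alone. Idempotent:
    collapsing an already-binary matrix returns an equal matrix.
    """
    return BandMatrix(
        genotypes=matrix.genotypes,
        loci=matrix.loci,
        presence=(matrix.presence > 0).astype(np.int8),
        intensity=None,
    )


def pool(matrices: Sequence[BandMatrix]) -> BandMatrix:
    """Concatenate assays over a shared genotype panel.

    All inputs must cover the identical genotype set; order may differ
    and is aligned by label to the first matrix's order. Loci are
    concatenated in input order with metadata preserved. Intensity is
    dropped unless every input carries it.
    """
    if not matrices:
        raise BandMatrixError("pool of zero matrices")
    first = matrices[0]
    ref = set(first.genotypes)
    aligned = [first]
    for i, m in enumerate(matrices[1:], start=2):
        if set(m.genotypes) != ref:
            missing = sorted(ref - set(m.genotypes))
            extra = sorted(set(m.genotypes) - ref)
            raise BandMatrixError(
                f"matrix {i} genotype set differs from matrix 1: "
                f"missing {missing}, unexpected {extra}"
            )
        aligned.append(m.reorder_genotypes(first.genotypes))
    keep_intensity = all(m.intensity is not None for m in aligned)
    return BandMatrix(
        genotypes=first.genotypes,
        loci=[loc for m in aligned for loc in m.loci],
        presence=np.vstack([m.presence for m in aligned]),
        intensity=(
            np.vstack([m.intensity for m in aligned]) if keep_intensity else None
        ),
    )
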
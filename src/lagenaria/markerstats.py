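"""Per-locus classification and primer informativeness indices.

For a dominant marker, the only observable at a locus is the band
frequency p = (genotypes carrying the band) / (genotypes scored). Loci
are classified monomorphic (p = 1), polymorphic (0 < p < 1), and -- as
fingerprinting subclasses of polymorphic -- unique-positive (band in
exactly one genotype, an M+ marker) or unique-negative (band absent
from exactly one genotype, an M- marker).

Per primer/enzyme group the standard dominant-marker informativeness
summaries are:

* PIC  = mean over bands of 2p(1-p); bounded by 0.5, attained at p = 0.5
* EMR  = PBN * (PBN / TBN), the effective multiplex ratio
* MI   = PIC * EMR, the marker index
* Rp   = sum over bands of Ib, with band informativeness
  Ib = 1 - 2|0.5 - p|
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .bandmatrix import BandMatrix

__all__ = [
    "LocusStats",
    "PrimerSummary",
    "locus_stats",
    "polymorphism_percent",
    "genotype_specific_markers",
    "primer_summary",
    "summary_frame",
    "pic_group",
    "emr_group",
    "rp_group",
]

LocusClass = Literal["monomorphic", "polymorphic", "unique_positive", "unique_negative"]


@dataclass(frozen=True)
class LocusStats:
    """Frequency and class of one band across the genotype panel.

    ``p`` is kept as an exact rational count/n; ``pic_locus`` and ``ib``
    are evaluated from it without intermediate rounding.
    """

    locus_id: str
    group: str
    count: int
    n: int
    klass: LocusClass

    @property
    def p(self) -> Fraction:
        return Fraction(self.count, self.n)

    @property
    def pic_locus(self) -> float:
        p = self.count / self.n
        return 2.0 * p * (1.0 - p)

    @property
    def ib(self) -> float:
        p = self.count / self.n
        return 1.0 - 2.0 * abs(0.5 - p)

    @property
    def is_polymorphic(self) -> bool:
        # unique classes count as polymorphic
        return self.klass != "monomorphic"


@dataclass(frozen=True)
class PrimerSummary:
    """One row of the per-primer amplification summary.

    ``bsr`` is the (min, max) band size over the group's loci, in the
    assay's native unit (bp for SCoT, kDa for protein, Rm for isozyme).
    """

    group: str
    tbn: int
    mbn: int
    pbn: int
    p_pct: float
    ub: int
    pic: float
    emr: float
    mi: float
    rp: float
    bsr: tuple[float, float]


def _classify(count: int, n: int) -> LocusClass:
    if count == n:
        return "monomorphic"
    if count == 1:
        # at n = 2 a singleton band is both present-in-one and
        # absent-from-one; positive polarity takes precedence
        return "unique_positive"
    if count == n - 1:
        return "unique_negative"
    return "polymorphic"


def locus_stats(matrix: BandMatrix) -> list[LocusStats]:
    """Classify every locus and record its exact band frequency."""
    n = matrix.n_genotypes
    out = []
    for loc, row in zip(matrix.loci, matrix.presence):
        count = int(row.sum())
        out.append(LocusStats(loc.locus_id, loc.group, count, n, _classify(count, n)))
    return out


def polymorphism_percent(
    matrix: BandMatrix, by_group: bool = False
) -> float | dict[str, float]:
    """Percentage of polymorphic loci, overall or per group.

    Returns the unrounded value 100 * PBN / TBN; report-boundary
    rounding (2 decimals) is applied by the callers that format tables.
    """
    stats = locus_stats(matrix)
    if not by_group:
        return 100.0 * sum(s.is_polymorphic for s in stats) / len(stats)
    out: dict[str, float] = {}
    for group in dict.fromkeys(s.group for s in stats):
        sub = [s for s in stats if s.group == group]
        out[group] = 100.0 * sum(s.is_polymorphic for s in sub) / len(sub)
    return out


def genotype_specific_markers(matrix: BandMatrix) -> pd.DataFrame:
    """Unique bands usable to fingerprint single genotypes.

    Each unique-positive locus contributes a row for its sole carrier;
    each unique-negative locus a row for its sole non-carrier. Columns:
    genotype, polarity, group, size_label. Genotypes without unique
    loci do not appear.
    """
    rows = []
    for loc, row, st in zip(matrix.loci, matrix.presence, locus_stats(matrix)):
        if st.klass == "unique_positive":
            carrier = matrix.genotypes[int(np.flatnonzero(row == 1)[0])]
            rows.append((carrier, "positive", loc.group, loc.size_label))
        elif st.klass == "unique_negative":
            absentee = matrix.genotypes[int(np.flatnonzero(row == 0)[0])]
            rows.append((absentee, "negative", loc.group, loc.size_label))
    return pd.DataFrame(rows, columns=["genotype", "polarity", "group", "size_label"])


# -- per-primer indices ----------------------------------------------------


def pic_group(freqs: Sequence[float]) -> float:
    """Polymorphism information content of a primer: mean of 2p(1-p)."""
    freqs = list(freqs)
    if not freqs:
        raise ValueError("PIC of an empty band set is undefined")
    if any(not (0.0 <= p <= 1.0) for p in freqs):
        raise ValueError(f"band frequencies must lie in [0, 1]: {freqs}")
    return float(np.mean([2.0 * p * (1.0 - p) for p in freqs]))


def emr_group(tbn: int, pbn: int) -> float:
    """Effective multiplex ratio: PBN * (PBN / TBN)."""
    if tbn <= 0:
        raise ValueError("EMR undefined for a primer with no bands")
    if not (0 <= pbn <= tbn):
        raise ValueError(f"need 0 <= PBN <= TBN, got PBN={pbn}, TBN={tbn}")
    return pbn * (pbn / tbn)


def rp_group(freqs: Sequence[float]) -> float:
    """Resolving power: sum over bands of Ib = 1 - 2|0.5 - p|."""
    freqs = list(freqs)
    if not freqs:
        raise ValueError("Rp of an empty band set is undefined")
    if any(not (0.0 <= p <= 1.0) for p in freqs):
        raise ValueError(f"band frequencies must lie in [0, 1]: {freqs}")
    return float(sum(1.0 - 2.0 * abs(0.5 - p) for p in freqs))


def primer_summary(matrix: BandMatrix) -> list[PrimerSummary]:
    """Per-group band counts and informativeness indices.

    Groups appear in first-occurrence order of the matrix's loci. The
    MI = PIC * EMR identity holds to machine precision by construction.
    """
    stats = locus_stats(matrix)
    by_group: dict[str, list[tuple[LocusStats, float]]] = {}
    for loc, st in zip(matrix.loci, stats):
        by_group.setdefault(st.group, []).append((st, loc.size_label))
    out = []
    for group, members in by_group.items():
        sts = [st for st, _ in members]
        sizes = [size for _, size in members]
        tbn = len(sts)
        pbn = sum(st.is_polymorphic for st in sts)
        mbn = tbn - pbn
        ub = sum(st.klass in ("unique_positive", "unique_negative") for st in sts)
        freqs = [st.count / st.n for st in sts]
        pic = pic_group(freqs)
        emr = emr_group(tbn, pbn)
        out.append(
            PrimerSummary(
                group=group,
                tbn=tbn,
                mbn=mbn,
                pbn=pbn,
                p_pct=100.0 * pbn / tbn,
                ub=ub,
                pic=pic,
                emr=emr,
                mi=pic * emr,
                rp=rp_group(freqs),
                bsr=(min(sizes), max(sizes)),
            )
        )
    return out


def summary_frame(summaries: Iterable[PrimerSummary]) -> pd.DataFrame:
    """Tabulate summaries with a totals row (TBN/MBN/PBN/UB sums) and an
    averages row (arithmetic mean of P%, PIC, EMR, MI, Rp over groups)."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no primer summaries to tabulate")
    rows = [
        {
            "group": s.group,
            "tbn": s.tbn,
            "mbn": s.mbn,
            "pbn": s.pbn,
            "p_pct": s.p_pct,
            "ub": s.ub,
            "pic": s.pic,
            "emr": s.emr,
            "mi": s.mi,
            "rp": s.rp,
            "bsr_min": s.bsr[0],
            "bsr_max": s.bsr[1],
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    totals = {
        "group": "Total",
        "tbn": df["tbn"].sum(),
        "mbn": df["mbn"].sum(),
        "pbn": df["pbn"].sum(),
        "ub": df["ub"].sum(),
    }
    averages = {
        "group": "Average",
        **{c: df[c].mean() for c in ("p_pct", "pic", "emr", "mi", "rp")},
    }
    return pd.concat(
        [df, pd.DataFrame([totals, averages])], ignore_index=True
    )
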
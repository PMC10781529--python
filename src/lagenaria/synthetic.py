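"""Seedable generator of dominant-marker band matrices.

Emulates the structure of scored gel data for a cultivar panel: bands
grouped under primers, per-band presence frequencies, optional planted
genotype clusters, and optional injected unique (fingerprinting)
bands — so every pipeline stage can be exercised against a known
ground truth.

Defaults mirror the study panel this package reproduces: 10 genotypes
and 44 SCoT bands across 8 primers sized (7, 3, 3, 3, 11, 7, 4, 6),
with per-band presence probabilities drawn uniformly on [0.3, 0.95]
(the observed band frequencies of such dominant-marker panels span
roughly this range; a lower floor would mostly produce near-empty
bands that a gel scorer would not call loci).

Noise model: with a cluster plan, each cluster receives a template
band profile and each member deviates from it by independent per-band
Bernoulli(delta) flips — the simplest defensible model of scoring
dropout and ghost bands. Planted unique bands are exact (not subject
to noise) so truth recovery is well-defined.

Randomness: a single integer seed feeds one ``numpy`` Generator; the
stream order is (1) per-band frequencies, (2) cluster templates in
plan order, (3) presence entries row-major with all-zero rows
resampled in place, (4) unique-injection placements. The order is part
of the public contract so matrices are stable across releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bandmatrix import BandMatrix, Locus

__all__ = ["SyntheticSpec", "PlantedTruth", "generate", "planted_truth"]

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("SCoT-1", 7),
    ("SCoT-2", 3),
    ("SCoT-6", 3),
    ("SCoT-8", 3),
    ("SCoT-9", 11),
    ("SCoT-11", 7),
    ("SCoT-12", 4),
    ("SCoT-14", 6),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic band matrix.

    ``freq_model`` is either ``("fixed", p)`` or ``("uniform", lo, hi)``
    giving the per-band presence probability law. ``cluster_plan``, if
    set, is ``(partition, delta)`` where partition lists genotype index
    groups and delta is the per-band flip probability of a member
    against its cluster template. ``unique_positive``/``unique_negative``
    count extra planted fingerprinting bands.
    """

    n_genotypes: int = 10
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    freq_model: tuple = ("uniform", 0.3, 0.95)
    cluster_plan: tuple[tuple[tuple[int, ...], ...], float] | None = None
    unique_positive: int = 0
    unique_negative: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 1:
            raise ValueError("need at least one genotype")
        if not self.groups or any(k < 1 for _, k in self.groups):
            raise ValueError("every group needs at least one band")
        kind = self.freq_model[0]
        if kind == "fixed":
            (p,) = self.freq_model[1:]
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"fixed frequency {p} outside [0, 1]")
        elif kind == "uniform":
            lo, hi = self.freq_model[1:]
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"uniform bounds ({lo}, {hi}) invalid")
        else:
            raise ValueError(f"unknown freq_model {kind!r}")
        if (self.unique_positive or self.unique_negative) and self.n_genotypes < 2:
            raise ValueError("unique bands need at least 2 genotypes")
        if self.cluster_plan is not None:
            partition, delta = self.cluster_plan
            if not (0.0 <= delta <= 1.0):
                raise ValueError(f"delta {delta} outside [0, 1]")
            seen = sorted(i for block in partition for i in block)
            if seen != list(range(self.n_genotypes)):
                raise ValueError(
                    "cluster plan must partition genotype indices "
                    f"0..{self.n_genotypes - 1}, got {seen}"
                )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated matrix: the planted genotype
    partition (one block when no cluster plan) and the planted unique
    markers as (genotype, polarity, locus_id) rows."""

    partition: tuple[frozenset[str], ...]
    unique_markers: tuple[tuple[str, str, str], ...]


def _genotype_labels(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def _draw_freqs(spec: SyntheticSpec, rng: np.random.Generator, k: int) -> np.ndarray:
    kind = spec.freq_model[0]
    if kind == "fixed":
        return np.full(k, float(spec.freq_model[1]))
    lo, hi = spec.freq_model[1:]
    return rng.uniform(lo, hi, size=k)


def _synthesize(spec: SyntheticSpec) -> tuple[BandMatrix, PlantedTruth]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genotypes
    genotypes = _genotype_labels(n)
    n_bands = sum(k for _, k in spec.groups)
    freqs = _draw_freqs(spec, rng, n_bands)

    if spec.cluster_plan is not None:
        partition, delta = spec.cluster_plan
        templates = {
            block: (rng.random((n_bands,)) < freqs).astype(np.int8)
            for block in partition
        }
        presence = np.zeros((n_bands, n), dtype=np.int8)
        for block in partition:
            for g in block:
                flips = rng.random(n_bands) < delta
                presence[:, g] = np.where(
                    flips, 1 - templates[block], templates[block]
                )
        truth_partition = tuple(
            frozenset(genotypes[i] for i in block) for block in partition
        )
    else:
        presence = (rng.random((n_bands, n)) < freqs[:, None]).astype(np.int8)
        truth_partition = (frozenset(genotypes),)

    # a band never observed is not a locus: resample empty rows
    for row in range(n_bands):
        while presence[row].sum() == 0:
            if spec.freq_model[0] == "fixed" and spec.freq_model[1] == 0.0:
                raise ValueError("frequency 0 can never produce an observed band")
            presence[row] = (rng.random(n) < max(freqs[row], 1.0 / n)).astype(np.int8)

    loci: list[Locus] = []
    sizes_used = 0
    for gname, k in spec.groups:
        for b in range(k):
            sizes_used += 1
            loci.append(
                Locus(f"{gname}_b{b + 1}", "scot", gname, 100.0 + 10.0 * sizes_used)
            )

    # planted unique bands, appended after the regular groups
    markers: list[tuple[str, str, str]] = []
    extra_rows = []
    group_names = [g for g, _ in spec.groups]
    for j in range(spec.unique_positive):
        carrier = int(rng.integers(n))
        row = np.zeros(n, dtype=np.int8)
        row[carrier] = 1
        locus_id = f"UPOS_{j + 1}"
        gname = group_names[j % len(group_names)]
        loci.append(Locus(locus_id, "scot", gname, 2000.0 + 10.0 * j))
        extra_rows.append(row)
        markers.append((genotypes[carrier], "positive", locus_id))
    for j in range(spec.unique_negative):
        absentee = int(rng.integers(n))
        row = np.ones(n, dtype=np.int8)
        row[absentee] = 0
        locus_id = f"UNEG_{j + 1}"
        gname = group_names[(spec.unique_positive + j) % len(group_names)]
        loci.append(Locus(locus_id, "scot", gname, 3000.0 + 10.0 * j))
        extra_rows.append(row)
        markers.append((genotypes[absentee], "negative", locus_id))
    if extra_rows:
        presence = np.vstack([presence, np.array(extra_rows, dtype=np.int8)])

    matrix = BandMatrix(genotypes=genotypes, loci=loci, presence=presence)
    return matrix, PlantedTruth(truth_partition, tuple(markers))


def generate(spec: SyntheticSpec) -> BandMatrix:
    """Generate the band matrix for a spec; reproducible given the seed."""
    return _synthesize(spec)[0]


def planted_truth(spec: SyntheticSpec) -> PlantedTruth:
    """Ground truth for the same spec (same seed, same stream)."""
    return _synthesize(spec)[1]
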
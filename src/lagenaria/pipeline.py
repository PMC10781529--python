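"""End-to-end orchestration: load -> summarize -> similarity -> pool ->
tree -> markers, plus the packaged-study reproduction checks.

``run_analysis`` drives one configured run over any set of band
matrices and writes a deterministic report bundle. ``reproduce_study``
recomputes every desk-reproducible published number of the packaged
bottle gourd study from its band matrices and compares computed
against published.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .bandmatrix import BandMatrix, collapse_intensity, pool, read_band_matrix
from .clustering import cut, to_newick, upgma
from .markerstats import (
    genotype_specific_markers,
    locus_stats,
    polymorphism_percent,
    primer_summary,
    summary_frame,
)
from .similarity import (
    alt_coefficients,
    jaccard,
    round_half_up,
    similarity_report,
    write_similarity,
)

__all__ = ["RunConfig", "run_analysis", "Check", "ReproductionReport", "reproduce_study"]

METHODS = ("jaccard", "dice", "simple_matching")


@dataclass
class RunConfig:
    """One analysis run.

    ``inputs`` maps an assay tag (used to name outputs) to a band
    matrix file. Rounding is applied only at the reporting boundary:
    similarity to ``round_similarity`` decimals, percentages to
    ``round_percent``.
    """

    inputs: dict[str, str | Path]
    outdir: str | Path
    method: str = "jaccard"
    round_similarity: int = 3
    round_percent: int = 2
    cut_k: int | None = None
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method {self.method!r} not in {METHODS}")
        if not self.inputs:
            raise ValueError("no input matrices configured")
        missing = [str(p) for p in self.inputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input files not found: {missing}")


def _similarity(matrix: BandMatrix, method: str):
    if method == "jaccard":
        return jaccard(matrix)
    return alt_coefficients(matrix, method)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Per assay: locus stats, primer summary, genotype-specific markers,
    similarity matrix, UPGMA Newick tree. With more than one input, the
    pooled (concatenated) matrix additionally yields pooled similarity,
    tree and an extremes report. A manifest records every parameter and
    input checksum. Returns the manifest dict.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "method": config.method,
        "round_similarity": config.round_similarity,
        "round_percent": config.round_percent,
        "cut_k": config.cut_k,
        "seed": config.seed,
        "inputs": {},
        "outputs": [],
        "counts": {},
    }

    matrices: dict[str, BandMatrix] = {}
    for tag, path in config.inputs.items():
        path = Path(path)
        m = read_band_matrix(path)
        matrices[tag] = m
        manifest["inputs"][tag] = {"path": str(path), "sha256": _sha256(path)}
        manifest["counts"][tag] = {
            "loci": m.n_loci,
            "genotypes": m.n_genotypes,
        }

    genosets = {tag: frozenset(m.genotypes) for tag, m in matrices.items()}
    if len(set(genosets.values())) > 1:
        raise ValueError(f"inconsistent genotype sets across inputs: {genosets}")

    def emit(path: Path) -> Path:
        manifest["outputs"].append(str(path))
        return path

    rp = config.round_percent
    for tag, m in matrices.items():
        binary = collapse_intensity(m) if m.intensity is not None else m
        stats = pd.DataFrame(
            [
                {
                    "locus_id": s.locus_id,
                    "group": s.group,
                    "count": s.count,
                    "n": s.n,
                    "p": s.count / s.n,
                    "class": s.klass,
                }
                for s in locus_stats(binary)
            ]
        )
        stats.to_csv(emit(outdir / f"{tag}_locus_stats.csv"), index=False)
        summ = summary_frame(primer_summary(binary))
        summ["p_pct"] = summ["p_pct"].round(rp)
        summ.to_csv(emit(outdir / f"{tag}_primer_summary.csv"), index=False)
        genotype_specific_markers(binary).to_csv(
            emit(outdir / f"{tag}_markers.csv"), index=False
        )
        s = _similarity(binary, config.method)
        write_similarity(
            s, emit(outdir / f"{tag}_similarity.csv"), ndigits=config.round_similarity
        )
        tree = upgma(s)
        emit(outdir / f"{tag}_upgma.nwk").write_text(to_newick(tree) + "\n")
        if config.cut_k:
            clusters = cut(tree, config.cut_k)
            emit(outdir / f"{tag}_clusters_k{config.cut_k}.txt").write_text(
                "\n".join(",".join(sorted(c)) for c in clusters) + "\n"
            )

    if len(matrices) > 1:
        pooled = pool(
            [
                collapse_intensity(m) if m.intensity is not None else m
                for m in matrices.values()
            ]
        )
        manifest["counts"]["pooled"] = {
            "loci": pooled.n_loci,
            "genotypes": pooled.n_genotypes,
        }
        s = _similarity(pooled, config.method)
        write_similarity(
            s, emit(outdir / "pooled_similarity.csv"), ndigits=config.round_similarity
        )
        tree = upgma(s)
        emit(outdir / "pooled_upgma.nwk").write_text(to_newick(tree) + "\n")
        rep = similarity_report(s)
        emit(outdir / "pooled_extremes.json").write_text(
            json.dumps(
                {
                    "min": round_half_up(rep.min_value, config.round_similarity),
                    "min_pairs": sorted(map(list, rep.min_pairs)),
                    "max": round_half_up(rep.max_value, config.round_similarity),
                    "max_pairs": sorted(map(list, rep.max_pairs)),
                },
                indent=2,
            )
            + "\n"
        )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# -- packaged-study reproduction ------------------------------------------


@dataclass(frozen=True)
class Check:
    name: str
    computed: object
    expected: object
    passed: bool


@dataclass
class ReproductionReport:
    checks: list[Check] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, computed, expected) -> None:
        if isinstance(computed, float) and isinstance(expected, float):
            ok = abs(computed - expected) < 5e-4
        else:
            ok = computed == expected
        self.checks.append(Check(name, computed, expected, ok))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "check": c.name,
                    "computed": str(c.computed),
                    "published": str(c.expected),
                    "pass": c.passed,
                }
                for c in self.checks
            ]
        )


def _matches_published(computed, published, skip: set[tuple[str, str]] = frozenset()):
    """Cells of a computed similarity matrix equal to the published one
    after half-up rounding to 3 decimals; returns list of mismatches."""
    bad = []
    for i, x in enumerate(published.genotypes):
        for j, y in enumerate(published.genotypes):
            if j <= i or (x, y) in skip or (y, x) in skip:
                continue
            c = round_half_up(computed.value(x, y), 3)
            p = round_half_up(published.value(x, y), 3)
            if abs(c - p) > 1e-9:
                bad.append((x, y, c, p))
    return bad


def reproduce_study(data_dir: str | Path | None = None) -> ReproductionReport:
    """Recompute every desk-reproducible published number from the
    packaged band matrices and compare with the published values.

    ``data_dir`` overrides the packaged band-matrix directory (used to
    demonstrate sensitivity to data corruption); published reference
    tables are always the packaged ones.
    """
    rep = ReproductionReport()

    protein = datasets.protein_sds_page(data_dir)
    stats = locus_stats(protein)
    rep.add("protein: loci", protein.n_loci, 17)
    rep.add(
        "protein: polymorphism %",
        round_half_up(polymorphism_percent(protein), 2),
        29.41,
    )
    rep.add(
        "protein: monomorphic bands",
        sum(s.klass == "monomorphic" for s in stats),
        12,
    )
    rep.add("protein: polymorphic bands", sum(s.is_polymorphic for s in stats), 5)
    counts = protein.band_counts()
    rep.add("protein: min bands per cultivar", min(counts.values()), 15)
    rep.add("protein: S2 attains the minimum", counts["S2"], min(counts.values()))
    markers = genotype_specific_markers(protein)
    rep.add(
        "protein: negative unique markers",
        sorted(
            (r.genotype, r.size_label)
            for r in markers.itertuples()
            if r.polarity == "negative"
        ),
        [("S2", 11.0), ("S6", 23.0), ("S8", 100.0), ("S8", 126.0)],
    )
    rep.add(
        "protein: positive unique markers",
        int((markers["polarity"] == "positive").sum()),
        0,
    )

    s_prot = jaccard(protein)
    pub_prot = datasets.protein_similarity_published()
    rep.add(
        "protein similarity: cells matching published (of 45)",
        45 - len(_matches_published(s_prot, pub_prot)),
        45,
    )
    prot_rep = similarity_report(s_prot)
    rep.add(
        "protein similarity: minimum",
        round_half_up(prot_rep.min_value, 3),
        0.765,
    )
    rep.add(
        "protein similarity: minimum pair",
        ("S2", "S8") in prot_rep.min_pairs,
        True,
    )
    rep.add("protein similarity: (S1,S2)", round_half_up(s_prot.value("S1", "S2"), 3), 0.882)
    rep.add("protein similarity: (S2,S9)", round_half_up(s_prot.value("S2", "S9"), 3), 0.938)

    pod = collapse_intensity(datasets.isozyme_pod(data_dir))
    ppo = collapse_intensity(datasets.isozyme_ppo(data_dir))
    for tag, m in (("POD", pod), ("PPO", ppo)):
        rep.add(f"{tag}: bands", m.n_loci, 5)
        rep.add(
            f"{tag}: polymorphism %",
            round_half_up(polymorphism_percent(m), 2),
            20.0,
        )
        rm06 = [i for i, loc in enumerate(m.loci) if loc.size_label == 0.6]
        carriers = {
            g for g, v in zip(m.genotypes, m.presence[rm06[0]]) if v == 1
        }
        rep.add(f"{tag}: Rm 0.6 band carried only by S1, S2", sorted(carriers), ["S1", "S2"])

    pooled = pool([protein, pod, ppo])
    rep.add("pooled: loci", pooled.n_loci, 27)
    s_pool = jaccard(pooled)
    pub_pool = datasets.pooled_similarity_published()
    rep.add(
        "pooled similarity: cells matching published (of 44 consistent cells)",
        44 - len(_matches_published(s_pool, pub_pool, skip={("S2", "S7")})),
        44,
    )
    # the single published cell inconsistent with the published band
    # data: S7's profile is identical to S3's, so (S2,S7) must equal
    # (S2,S3); the table prints a transposed digit there
    rep.add(
        "pooled similarity: (S2,S7) equals (S2,S3) (identical profiles)",
        round_half_up(s_pool.value("S2", "S7"), 3),
        round_half_up(s_pool.value("S2", "S3"), 3),
    )
    pool_rep = similarity_report(s_pool)
    rep.add("pooled similarity: minimum", round_half_up(pool_rep.min_value, 3), 0.778)
    rep.add("pooled similarity: minimum pair", ("S2", "S8") in pool_rep.min_pairs, True)
    rep.add("pooled similarity: maximum", round_half_up(pool_rep.max_value, 3), 1.0)
    ones = sorted({g for p in pool_rep.max_pairs for g in p})
    rep.add(
        "pooled similarity: maximum attained among S3,S4,S5,S7,S10",
        ones,
        sorted(["S3", "S4", "S5", "S7", "S10"]),
    )
    rep.add("pooled similarity: (S3,S9)", round_half_up(s_pool.value("S3", "S9"), 3), 0.960)

    scot = datasets.scot_primer_counts()
    rep.add("SCoT: total bands", int(scot["tbn"].sum()), 44)
    rep.add("SCoT: polymorphic bands", int(scot["pbn"].sum()), 22)
    rep.add(
        "SCoT: overall polymorphism %",
        round_half_up(100.0 * scot["pbn"].sum() / scot["tbn"].sum(), 2),
        50.0,
    )
    rep.add(
        "SCoT: mean of per-primer polymorphism % (as printed)",
        round_half_up(float(scot["p_pct"].mean()), 2),
        45.15,
    )
    mono = scot[scot["pbn"] == 0]
    rep.add("SCoT: PIC of the all-monomorphic primer", float(mono["pic"].iloc[0]), 0.0)

    s_scot = datasets.scot_similarity()
    scot_rep = similarity_report(s_scot)
    rep.add("SCoT similarity: minimum", round_half_up(scot_rep.min_value, 3), 0.675)
    rep.add("SCoT similarity: minimum pair", scot_rep.min_pairs, [("S5", "S9")])
    rep.add("SCoT similarity: maximum", round_half_up(scot_rep.max_value, 3), 0.889)
    rep.add("SCoT similarity: maximum pair", scot_rep.max_pairs, [("S5", "S7")])
    tree = upgma(s_scot)
    first = tree.merges[0]
    rep.add(
        "SCoT UPGMA: first merge pair",
        tuple(sorted(tree.members(first.left) | tree.members(first.right))),
        ("S5", "S7"),
    )
    rep.add("SCoT UPGMA: first merge distance", round_half_up(first.height, 3), 0.111)

    return rep
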
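import numpy as np
import pytest

from lagenaria import datasets
from lagenaria.bandmatrix import BandMatrix, Locus, collapse_intensity
from lagenaria.clustering import Dendrogram, Merge
from lagenaria.similarity import SimilarityMatrix


@pytest.fixture(scope="session")
def protein():
    return datasets.protein_sds_page()


@pytest.fixture(scope="session")
def pod():
    return datasets.isozyme_pod()


@pytest.fixture(scope="session")
def ppo():
    return datasets.isozyme_ppo()


@pytest.fixture(scope="session")
def pod_binary(pod):
    return collapse_intensity(pod)


@pytest.fixture(scope="session")
def ppo_binary(ppo):
    return collapse_intensity(ppo)


@pytest.fixture(scope="session")
def scot_sim():
    return datasets.scot_similarity()


def make_matrix(presence, genotypes=None, group="G", assay="scot", intensity=None):
    """Small ad-hoc matrix from a 2-D 0/1 (or 0-3) array."""
    presence = np.asarray(presence, dtype=np.int8)
    n_loci, n_gen = presence.shape
    genotypes = genotypes or [f"g{i + 1}" for i in range(n_gen)]
    loci = [Locus(f"L{i + 1}", assay, group, 100.0 + i) for i in range(n_loci)]
    return BandMatrix(genotypes, loci, presence, intensity)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1, 1, 0], [1, 0, 1], [1, 1, 1]])


def random_similarity(rng, n, tie_free=False):
    """Random symmetric similarity matrix on labelled leaves."""
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    if tie_free:
        # perturb to break exact ties in initial distances
        iu = np.triu_indices(n, 1)
        d[iu] += rng.permutation(len(iu[0])) * 1e-7
        d = np.triu(d, 1) + np.triu(d, 1).T
    labels = [f"t{i:02d}" for i in range(n)]
    return SimilarityMatrix(labels, 1.0 - d)


def brute_force_upgma(s: SimilarityMatrix) -> Dendrogram:
    """Independent UPGMA oracle: recomputes every inter-cluster average
    from the original leaf distance matrix at every step (no distance
    update formula), with the same lexicographic tie-break."""
    d0 = s.distance()
    labels = s.genotypes
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    clusters: dict[int, frozenset[str]] = {i: frozenset((labels[i],)) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                pairs = [
                    d0[index[x], index[y]] for x in clusters[i] for y in clusters[j]
                ]
                avg = sum(pairs) / len(pairs)
                key = (avg, *sorted((min(clusters[i]), min(clusters[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j, avg)
        _, i, j, avg = best
        merges.append(Merge(i, j, avg))
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        next_id += 1
    return Dendrogram(list(labels), merges)
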
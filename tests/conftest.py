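import numpy as np
import pytest

from walnutpg.datamodel import GenotypeDataset, Locus


def make_dataset(pop_calls, motif=2, raw=False, loci=None):
    """Build a dataset from {pop: [((a, b), (c, d), ...), ...]} genotype rows.

    Each individual's entry is a tuple of per-locus (allele, allele) pairs
    in bp; (0, 0) is missing.
    """
    pops = list(pop_calls)
    n_loci = len(next(iter(pop_calls.values()))[0])
    individuals, pop_index, rows = [], [], []
    for pi, (pop, inds) in enumerate(pop_calls.items()):
        for k, geno in enumerate(inds):
            individuals.append(f"{pop}_{k + 1}")
            pop_index.append(pi)
            rows.append(geno)
    return GenotypeDataset(
        loci=loci or [Locus(f"L{l + 1}", motif) for l in range(n_loci)],
        populations=pops,
        individuals=individuals,
        pop_index=np.array(pop_index),
        calls=np.array(rows, dtype=np.int64),
        raw=raw,
    )


def random_dataset(rng, n_pops=None, n_loci=None, max_ind=6, motif=2):
    """A random small dataset on a proper motif ladder, with some missing."""
    n_pops = n_pops or int(rng.integers(2, 4))
    n_loci = n_loci or int(rng.integers(1, 4))
    offsets = rng.integers(50, 90, size=n_loci) * motif
    pop_calls = {}
    for p in range(n_pops):
        n_ind = int(rng.integers(1, max_ind + 1))
        inds = []
        for _ in range(n_ind):
            geno = []
            for l in range(n_loci):
                if rng.random() < 0.1:
                    geno.append((0, 0))
                else:
                    a, b = offsets[l] + motif * rng.integers(0, 8, size=2)
                    geno.append((int(a), int(b)))
            inds.append(tuple(geno))
        pop_calls[f"P{p + 1}"] = inds
    return make_dataset(pop_calls, motif=motif)


@pytest.fixture
def two_pop_two_locus():
    """Tiny deterministic 2-pop, 2-locus dataset."""
    return make_dataset({
        "P1": [((100, 102), (140, 140)), ((100, 100), (140, 142))],
        "P2": [((102, 102), (142, 142)), ((100, 102), (140, 142))],
    })


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
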
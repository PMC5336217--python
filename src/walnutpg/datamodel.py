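"""Core containers for diploid microsatellite (SSR) genotype data.

Allele calls are fragment sizes in base pairs.  A genotype is a diploid
pair of sizes; the pair is missing as a unit (SSR scoring either yields
both alleles of an individual at a locus or neither).  The missing
sentinel is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = 0


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its repeat-motif length in bp."""

    name: str
    motif: int = 2

    def __post_init__(self) -> None:
        if self.motif < 1:
            raise ValueError(f"locus {self.name}: motif length must be >= 1")


@dataclass(frozen=True)
class PopulationMetadata:
    """Georeferenced sampling site."""

    population: str
    latitude: float
    longitude: float
    elevation: float = float("nan")
    country: str | None = None
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"{self.population}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"{self.population}: longitude {self.longitude} outside [-180, 180]"
            )


@dataclass
class GenotypeDataset:
    """Diploid allele-size calls for individuals x loci with population labels.

    Parameters
    ----------
    loci:
        Ordered locus descriptors.
    populations:
        Ordered unique population IDs.
    individuals:
        Individual IDs, one per row of ``calls``.
    pop_index:
        For each individual, the index of its population in ``populations``.
    calls:
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele sizes
        in bp, 0 meaning missing (both haplotypes of a pair or neither).
    raw:
        If True, no motif-ladder consistency is asserted for allele sizes.
    """

    loci: list[Locus]
    populations: list[str]
    individuals: list[str]
    pop_index: np.ndarray
    calls: np.ndarray
    raw: bool = False

    def __post_init__(self) -> None:
        self.pop_index = np.asarray(self.pop_index, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.validate()

    # -- basic shape ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def validate(self) -> None:
        n, L = self.n_individuals, self.n_loci
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population IDs")
        if n and (self.pop_index.min() < 0 or self.pop_index.max() >= len(self.populations)):
            raise ValueError("pop_index out of range of population list")
        if np.any(self.calls < 0):
            raise ValueError("negative allele size")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half_missing):
            i, l = np.argwhere(half_missing)[0]
            raise ValueError(
                f"individual {self.individuals[i]} locus {self.loci[l].name}: "
                "single-allele missingness (the diploid pair is missing as a unit)"
            )
        if not self.raw:
            for l, locus in enumerate(self.loci):
                sizes = np.unique(self.calls[:, l, :])
                sizes = sizes[sizes != MISSING]
                if sizes.size > 1 and np.any((sizes - sizes[0]) % locus.motif):
                    raise ValueError(
                        f"locus {locus.name}: allele sizes {sizes.tolist()} are not on "
                        f"a ladder of motif length {locus.motif} (set raw=True to skip)"
                    )

    # -- accessors -----------------------------------------------------
    def population_of(self, i: int) -> str:
        return self.populations[self.pop_index[i]]

    def pop_rows(self, population: str) -> np.ndarray:
        """Row indices of the individuals belonging to *population*."""
        try:
            p = self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None
        return np.flatnonzero(self.pop_index == p)

    def locus_index(self, name: str) -> int:
        for l, locus in enumerate(self.loci):
            if locus.name == name:
                return l
        raise KeyError(f"unknown locus {name!r}")

    def allele_counts(self, l: int, rows: np.ndarray | None = None) -> dict[int, int]:
        """Gene-copy counts per allele at locus *l* over the given rows."""
        sub = self.calls[:, l, :] if rows is None else self.calls[rows][:, l, :]
        alleles, counts = np.unique(sub[sub != MISSING], return_counts=True)
        return dict(zip(alleles.tolist(), counts.tolist()))

    def counts_by_population(self, l: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (sorted allele sizes, matrix[n_pops, n_alleles] of gene-copy counts)."""
        flat = self.calls[:, l, :]
        present = flat != MISSING
        alleles = np.unique(flat[present])
        mat = np.zeros((self.n_populations, alleles.size), dtype=np.int64)
        idx = np.searchsorted(alleles, flat)
        for p in range(self.n_populations):
            rows = self.pop_index == p
            sub_idx = idx[rows][present[rows]]
            np.add.at(mat[p], sub_idx, 1)
        return alleles, mat

    def n_typed(self, l: int, rows: np.ndarray | None = None) -> int:
        """Number of individuals with a non-missing genotype at locus *l*."""
        sub = self.calls[:, l, 0] if rows is None else self.calls[rows, l, 0]
        return int(np.count_nonzero(sub != MISSING))

    def subset_populations(self, keep: list[str]) -> "GenotypeDataset":
        keep_idx = [self.populations.index(p) for p in keep]
        mask = np.isin(self.pop_index, keep_idx)
        remap = {old: new for new, old in enumerate(keep_idx)}
        return GenotypeDataset(
            loci=list(self.loci),
            populations=list(keep),
            individuals=[ind for ind, m in zip(self.individuals, mask) if m],
            pop_index=np.array([remap[p] for p in self.pop_index[mask]]),
            calls=self.calls[mask].copy(),
            raw=self.raw,
        )

    def merge_populations(self, groups: dict[str, list[str]]) -> "GenotypeDataset":
        """Pool populations into named groups (used to form ABC gene pools)."""
        flat: list[str] = [p for ps in groups.values() for p in ps]
        if len(set(flat)) != len(flat):
            raise ValueError("a population appears in more than one group")
        new_pops = list(groups)
        assign = {}
        for g, (name, members) in enumerate(groups.items()):
            for p in members:
                assign[self.populations.index(p)] = g
        mask = np.isin(self.pop_index, list(assign))
        return GenotypeDataset(
            loci=list(self.loci),
            populations=new_pops,
            individuals=[ind for ind, m in zip(self.individuals, mask) if m],
            pop_index=np.array([assign[p] for p in self.pop_index[mask]]),
            calls=self.calls[mask].copy(),
            raw=self.raw,
        )

    def repeat_units(self, l: int) -> np.ndarray:
        """Allele calls at locus *l* in repeat units (modal-offset normalised).

        Sizes are mapped to ``(size - offset) / motif`` where the offset is
        the common remainder of all sizes modulo the motif length.  Missing
        stays 0.  Raises if the sizes are off-ladder.
        """
        motif = self.loci[l].motif
        sub = self.calls[:, l, :]
        present = sub != MISSING
        sizes = sub[present]
        if sizes.size == 0:
            return np.zeros_like(sub)
        rem = np.unique(sizes % motif)
        if rem.size > 1:
            raise ValueError(
                f"locus {self.loci[l].name}: sizes have inconsistent remainders "
                f"{rem.tolist()} modulo motif {motif}"
            )
        out = np.zeros_like(sub)
        out[present] = (sizes - rem[0]) // motif + 1
        return out

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            loci=list(self.loci),
            populations=list(self.populations),
            individuals=list(self.individuals),
            pop_index=self.pop_index.copy(),
            calls=self.calls.copy(),
            raw=self.raw,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.loci == other.loci
            and self.populations == other.populations
            and self.individuals == other.individuals
            and np.array_equal(self.pop_index, other.pop_index)
            and np.array_equal(self.calls, other.calls)
        )


def check_allele_bookkeeping(ds: GenotypeDataset) -> None:
    """Assert Σ_pop allele counts == 2 x non-missing individuals per locus."""
    for l in range(ds.n_loci):
        _, mat = ds.counts_by_population(l)
        total = int(mat.sum())
        expect = 2 * ds.n_typed(l)
        if total != expect:
            raise AssertionError(
                f"locus {ds.loci[l].name}: {total} gene copies != {expect}"
            )
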
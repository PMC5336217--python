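"""Readers and writers for the plain-text formats the pipeline touches.

GenePop dialect notes
---------------------
GenePop files carry no explicit population names and no locus metadata, so
the writer embeds both losslessly while remaining readable by standard
parsers:

* each individual line is ``<population>|<individual> ,  <codes>`` — the
  identifier before the comma is free text in GenePop, and the ``|``
  separator lets the reader recover both IDs;
* each locus line is ``<name> motif=<bp>``; plain locus lines (no
  annotation) are accepted, in which case the dataset is flagged ``raw``
  (no motif-ladder validation) with motif defaulting to 1.

Codes are written 3-digit; 2- or 3-digit files are accepted on read.
Missing genotypes are the all-zeros code, for the pair as a unit.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, Locus, PopulationMetadata

logger = logging.getLogger(__name__)


class GenePopParseError(ValueError):
    """Malformed GenePop content; the message names the offending line."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path) -> GenotypeDataset:
    """Parse a GenePop (.gen) file into a :class:`GenotypeDataset`."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopParseError(f"{path}: empty file")
    # line 1 is the title; locus lines follow until the first "pop"
    loci: list[Locus] = []
    raw = False
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        line = lines[i].strip()
        if not line:
            raise GenePopParseError(f"{path}:{i + 1}: blank line in locus list")
        # one or several comma-separated locus names per line
        for tok in line.split(","):
            tok = tok.strip()
            if not tok:
                raise GenePopParseError(f"{path}:{i + 1}: empty locus name")
            m = re.fullmatch(r"(\S+)\s+motif=(\d+)", tok)
            if m:
                loci.append(Locus(m.group(1), int(m.group(2))))
            else:
                if " " in tok:
                    raise GenePopParseError(
                        f"{path}:{i + 1}: malformed locus line {tok!r}"
                    )
                loci.append(Locus(tok, 1))
                raw = True
        i += 1
    if i == len(lines):
        raise GenePopParseError(f"{path}: no 'pop' separator found")
    if not loci:
        raise GenePopParseError(f"{path}:2: no loci declared before first 'pop'")

    populations: list[str] = []
    individuals: list[str] = []
    pop_index: list[int] = []
    genotypes: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_counter = 0
    cur_pop: int | None = None

    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_counter += 1
            cur_pop = None
            continue
        if "," not in line:
            raise GenePopParseError(
                f"{path}:{lineno + 1}: expected '<ident> , <genotypes>'"
            )
        ident, _, rest = line.partition(",")
        ident = ident.strip()
        codes = rest.split()
        if len(codes) != len(loci):
            raise GenePopParseError(
                f"{path}:{lineno + 1}: {len(codes)} genotypes for {len(loci)} loci"
            )
        if "|" in ident:
            pop_name, _, ind_name = ident.partition("|")
        else:
            pop_name, ind_name = f"Pop{pop_counter}", ident
        if cur_pop is None:
            if pop_name in populations:
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: duplicate population {pop_name!r}"
                )
            populations.append(pop_name)
            cur_pop = len(populations) - 1
        row: list[tuple[int, int]] = []
        for l, code in enumerate(codes):
            if len(code) not in (4, 6) or not code.isdigit():
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: bad genotype code {code!r}"
                )
            w = len(code) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: allele-code width {w} != {width} "
                    "(inconsistent 2/3-digit encoding)"
                )
            a, b = int(code[:w]), int(code[w:])
            if (a == 0) != (b == 0):
                raise GenePopParseError(
                    f"{path}:{lineno + 1}: half-missing genotype {code!r} at "
                    f"locus {loci[l].name}"
                )
            row.append((a, b))
        individuals.append(ind_name)
        pop_index.append(cur_pop)
        genotypes.append(row)

    if not genotypes:
        raise GenePopParseError(f"{path}: no individuals")
    calls = np.array(genotypes, dtype=np.int64)
    return GenotypeDataset(
        loci=loci,
        populations=populations,
        individuals=individuals,
        pop_index=np.array(pop_index),
        calls=calls,
        raw=raw,
    )


def write_genepop(ds: GenotypeDataset, path: str | Path, title: str = "walnutpg export") -> None:
    """Write *ds* as a GenePop file re-readable by :func:`read_genepop`.

    Raises if any allele size needs more than 3 digits, or if any
    population would be written empty (GenePop forbids empty pops).
    """
    if ds.calls.max(initial=0) > 999:
        big = int(ds.calls.max())
        raise ValueError(f"allele size {big} not representable in 3 digits")
    counts = np.bincount(ds.pop_index, minlength=ds.n_populations)
    if np.any(counts == 0):
        empty = ds.populations[int(np.argmin(counts))]
        raise ValueError(f"population {empty!r} has no individuals (GenePop forbids empty pop)")
    out = [title]
    for locus in ds.loci:
        out.append(f"{locus.name} motif={locus.motif}")
    order = np.argsort(ds.pop_index, kind="stable")
    last_pop = -1
    for i in order:
        if ds.pop_index[i] != last_pop:
            out.append("pop")
            last_pop = int(ds.pop_index[i])
        codes = " ".join(
            f"{a:03d}{b:03d}" for a, b in ds.calls[i]
        )
        out.append(f"{ds.populations[last_pop]}|{ds.individuals[i]} ,  {codes}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Population metadata tables
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "population": {"population", "pop", "id", "population_id", "site"},
    "latitude": {"latitude", "lat"},
    "longitude": {"longitude", "lon", "long", "lng"},
    "elevation": {"elevation", "elev", "altitude", "alt"},
    "country": {"country", "country_code"},
    "n_samples": {"n_samples", "n", "samples", "size"},
}


def read_population_table(path: str | Path) -> list[PopulationMetadata]:
    """Read a delimited metadata table (population, lat, lon, elevation, ...)."""
    text = Path(path).read_text().strip()
    if not text:
        logger.warning("%s: empty population table", path)
        return []
    df = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    cols: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for c in df.columns:
            if c.strip().lower() in aliases:
                cols[canonical] = c
                break
    for required in ("population", "latitude", "longitude"):
        if required not in cols:
            raise ValueError(f"{path}: no column recognisable as {required!r}")
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row[cols["population"]]).strip()
        if pid in seen:
            raise ValueError(f"{path}: duplicate population ID {pid!r}")
        seen.add(pid)
        records.append(
            PopulationMetadata(
                population=pid,
                latitude=float(row[cols["latitude"]]),
                longitude=float(row[cols["longitude"]]),
                elevation=float(row[cols["elevation"]]) if "elevation" in cols else float("nan"),
                country=str(row[cols["country"]]).strip() if "country" in cols else None,
                n_samples=int(row[cols["n_samples"]]) if "n_samples" in cols else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# STRUCTURE output files
# ---------------------------------------------------------------------------

def read_structure_runs(paths: list[str | Path]):
    """Parse STRUCTURE ``_f`` output files.

    Returns a list of ``(K, ln_prob, QMatrix)`` tuples, one per file, with K
    inferred from the width of the inferred-ancestry block.
    """
    from .cluster import QMatrix  # local import to keep layering acyclic

    runs = []
    for path in paths:
        lines = Path(path).read_text().splitlines()
        ln_prob = None
        block_start = None
        for i, line in enumerate(lines):
            if "Estimated Ln Prob of Data" in line:
                ln_prob = float(line.split("=")[-1])
            if "Inferred ancestry of individuals" in line:
                block_start = i
        if block_start is None:
            raise ValueError(f"{path}: no 'Inferred ancestry of individuals' block")
        if ln_prob is None:
            raise ValueError(f"{path}: no 'Estimated Ln Prob of Data' line")
        ids: list[str] = []
        q_rows: list[list[float]] = []
        for line in lines[block_start + 1:]:
            s = line.strip()
            if not s:
                if q_rows:
                    break
                continue
            if s.lower().startswith("label"):
                continue
            if ":" not in s:
                break
            head, _, tail = s.partition(":")
            toks = head.split()
            if len(toks) < 2:
                raise ValueError(f"{path}: malformed ancestry row {s!r}")
            ids.append(toks[1])
            q_rows.append([float(t) for t in tail.split()])
        if not q_rows:
            raise ValueError(f"{path}: empty ancestry block")
        q = np.array(q_rows)
        bad = np.abs(q.sum(axis=1) - 1.0) > 1e-3
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"{path}: Q row for {ids[i]} sums to {q[i].sum():.4f} (not 1 +/- 1e-3)"
            )
        runs.append((q.shape[1], ln_prob, QMatrix(entities=ids, q=q, ln_prob=ln_prob)))
    return runs


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialise a :class:`walnutpg.phylo.Tree` to a newick file."""
    Path(path).write_text(tree.to_newick() + "\n")
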
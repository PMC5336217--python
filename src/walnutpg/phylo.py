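"""Nei's (1978) unbiased genetic distance and neighbor-joining trees.

The distance uses the small-sample-corrected gene identities
J_X = (2N sum x_i^2 - 1)/(2N - 1) within populations and
J_XY = sum x_i y_i between them, averaged over loci before taking
D = -ln( J_XY / sqrt(J_X J_Y) ).  Neighbor joining is the Saitou-Nei
Q-criterion agglomeration with a deterministic smallest-index tie-break.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    length: float | None = None       # branch length to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def to_newick(self) -> str:
        for leaf in self.leaves():
            if not leaf.label:
                raise ValueError("unlabeled leaf; newick requires leaf labels")

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.length is not None:
                core += f":{node.length:.10g}"
            return core

        return fmt(self.root) + ";"

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix (sums of branch lengths)."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                below = {node.label: 0.0}
            else:
                parts = [walk(c) for c in node.children]
                for i in range(len(parts)):
                    for j in range(i + 1, len(parts)):
                        for la, da in parts[i].items():
                            for lb, db in parts[j].items():
                                dists.setdefault(la, {})[lb] = da + db
                                dists.setdefault(lb, {})[la] = da + db
                below = {}
                for part in parts:
                    below.update(part)
            if node.length:
                below = {k: v + node.length for k, v in below.items()}
            return below

        walk(self.root)
        labels = sorted(dists)
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for a in labels:
            for b in labels:
                if a != b:
                    mat.loc[a, b] = dists[a][b]
        return mat


# ---------------------------------------------------------------------------
# Nei's unbiased distance
# ---------------------------------------------------------------------------

def nei_unbiased_distance(ds: GenotypeDataset) -> pd.DataFrame:
    """Nei-1978 unbiased genetic distance matrix between populations.

    Negative unbiased within identities (possible in tiny samples) are
    floored at 1/(allele count); negative distances are clamped to zero.
    A pair with between-identity zero gets ``inf`` with a warning.
    """
    pops = ds.populations
    counts = np.bincount(ds.pop_index, minlength=len(pops))
    if counts.size == 0 or counts.min() < 2:
        raise ValueError("every population needs >= 2 individuals")
    # per locus: frequencies and unbiased identities per pop
    jx = np.zeros((len(pops), ds.n_loci))
    jx_ok = np.zeros((len(pops), ds.n_loci), dtype=bool)
    freqs: list[np.ndarray | None] = []
    for l in range(ds.n_loci):
        alleles, mat = ds.counts_by_population(l)
        if alleles.size == 0:
            freqs.append(None)
            continue
        two_n = mat.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = mat / two_n[:, None]
        freqs.append(p)
        for k in range(len(pops)):
            if two_n[k] >= 2:
                j = (two_n[k] * np.sum(p[k] ** 2) - 1.0) / (two_n[k] - 1.0)
                if j <= 0:
                    j = 1.0 / alleles.size
                jx[k, l] = j
                jx_ok[k, l] = True
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            jxy_terms, jx_terms, jy_terms = [], [], []
            for l in range(ds.n_loci):
                if freqs[l] is None or not (jx_ok[i, l] and jx_ok[j, l]):
                    continue
                p = freqs[l]
                jxy_terms.append(float(np.sum(p[i] * p[j])))
                jx_terms.append(jx[i, l])
                jy_terms.append(jx[j, l])
            if not jxy_terms:
                raise ValueError(f"no shared typed locus for pair ({pops[i]}, {pops[j]})")
            jxy_bar = float(np.mean(jxy_terms))
            jx_bar = float(np.mean(jx_terms))
            jy_bar = float(np.mean(jy_terms))
            if jxy_bar <= 0.0:
                logger.warning(
                    "pair (%s, %s): no shared alleles; distance infinite",
                    pops[i], pops[j],
                )
                d = math.inf
            else:
                d = -math.log(jxy_bar / math.sqrt(jx_bar * jy_bar))
                if d < 0.0:
                    d = 0.0
            out.iloc[i, j] = out.iloc[j, i] = d
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(distances: pd.DataFrame) -> Tree:
    """Saitou-Nei neighbor joining with smallest-index tie-breaking.

    Requires a symmetric, finite, zero-diagonal matrix with >= 3 labels.
    Negative branch lengths are kept but logged.  The final edge between
    the last two nodes is split evenly, which preserves all leaf-to-leaf
    path lengths.
    """
    labels = list(distances.index)
    d = distances.to_numpy(dtype=float).copy()
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    if not np.all(np.isfinite(d)):
        raise ValueError(
            "infinite/NaN distance entries; resolve them (e.g. drop the "
            "offending populations) before tree building"
        )
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix not symmetric")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    active = list(range(len(labels)))
    negative = False
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2.0) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest-index pair among minima
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        ai, aj = min((min(i, j), max(i, j)) for i, j in ties)
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2.0))
        lj = dij - li
        if li < 0 or lj < 0:
            negative = True
        parent = TreeNode()
        ci, cj = nodes[active[ai]], nodes[active[aj]]
        ci.length, cj.length = li, lj
        parent.children = [ci, cj]
        new_d = 0.5 * (sub[ai, :] + sub[aj, :] - dij)
        gi, gj = active[ai], active[aj]
        d = np.pad(d, ((0, 1), (0, 1)))
        for pos, a in enumerate(active):
            d[-1, a] = d[a, -1] = new_d[pos]
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]
    a, b = active
    dab = d[a, b]
    na, nb = nodes[a], nodes[b]
    na.length = nb.length = 0.5 * dab
    if dab < 0:
        negative = True
    root = TreeNode(children=[na, nb])
    if negative:
        logger.warning("negative branch length(s) in NJ tree")
    return Tree(root=root)
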
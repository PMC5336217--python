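"""Post-processing of Bayesian clustering runs and IDW landscape surfaces.

Covers the Evanno delta-K choice of cluster number, CLUMPP-style
full-search alignment and averaging of repeated runs, hard membership
classification at a Q threshold, inverse-distance-weighted interpolation
of per-cluster membership onto a raster grid, and composite (RGB) maps
overlaying the per-cluster surfaces.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ADMIXED = "admixed"

# fixed palette for composite maps (RGB in [0,1]); cosmetic, configurable
DEFAULT_PALETTE = [
    (0.894, 0.102, 0.110),
    (0.216, 0.494, 0.722),
    (0.302, 0.686, 0.290),
    (0.596, 0.306, 0.639),
    (1.000, 0.498, 0.000),
    (1.000, 1.000, 0.200),
    (0.651, 0.337, 0.157),
    (0.969, 0.506, 0.749),
]


@dataclass
class QMatrix:
    """Membership proportions of entities (individuals or populations) in
    K clusters, with the run's log-likelihood when known."""

    entities: list[str]
    q: np.ndarray
    ln_prob: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.entities):
            raise ValueError("Q shape does not match entity list")
        if np.any(self.q < -1e-12) or np.any(self.q > 1 + 1e-12):
            raise ValueError("Q values outside [0, 1]")
        bad = np.abs(self.q.sum(axis=1) - 1.0) > 1e-3
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"Q row {self.entities[i]} sums to {self.q[i].sum():.4f}"
            )

    @property
    def k(self) -> int:
        return self.q.shape[1]


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno(runs: list[tuple[int, float]]) -> tuple[pd.DataFrame, int]:
    """Evanno second-difference statistic over repeated clustering runs.

    ``runs`` holds (K, log-likelihood) records with >= 2 runs per K over a
    contiguous K range of length >= 3.  Returns the per-K table (mean and
    sd of L, |L''|, delta K) and the interior K maximising delta K.
    """
    by_k: dict[int, list[float]] = {}
    for k, ln in runs:
        by_k.setdefault(int(k), []).append(float(ln))
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    few = [k for k in ks if len(by_k[k]) < 2]
    if few:
        raise ValueError(f"need >= 2 runs per K; too few at K={few}")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            lpp, dk = np.nan, np.nan
        else:
            lpp = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
            if sd[k] == 0:
                logger.warning("sd(L) = 0 at K=%d; delta K undefined", k)
                dk = np.nan
            else:
                dk = lpp / sd[k]
        rows.append({"K": k, "mean_L": mean[k], "sd_L": sd[k],
                     "abs_Lpp": lpp, "delta_K": dk})
    table = pd.DataFrame(rows).set_index("K")
    interior = table["delta_K"].dropna()
    if interior.empty:
        raise ValueError("delta K undefined at every interior K")
    return table, int(interior.idxmax())


# ---------------------------------------------------------------------------
# Run alignment (CLUMPP FullSearch equivalent)
# ---------------------------------------------------------------------------

def align_runs(runs: list[QMatrix]) -> QMatrix:
    """Align repeated runs of equal K by exhaustive column permutation and
    return the element-wise average (rows renormalised).

    The first run is the reference; each other run gets the permutation
    minimising the summed squared difference.  Exhaustive search over K!
    permutations requires K <= 8.
    """
    if not runs:
        raise ValueError("no runs")
    ref = runs[0]
    k = ref.k
    if k > 8:
        raise ValueError(
            f"K={k} > 8: exhaustive permutation search infeasible "
            "(a greedy mode is not implemented)"
        )
    for r in runs[1:]:
        if r.k != k:
            raise ValueError("runs differ in K")
        if r.entities != ref.entities:
            raise ValueError("runs must list the same entities in the same order")
    total = ref.q.copy()
    for r in runs[1:]:
        best = None
        best_cost = math.inf
        for perm in itertools.permutations(range(k)):
            cost = float(np.sum((r.q[:, perm] - ref.q) ** 2))
            if cost < best_cost - 1e-15:
                best_cost = cost
                best = perm
        total += r.q[:, best]
    avg = total / len(runs)
    avg = avg / avg.sum(axis=1, keepdims=True)
    return QMatrix(entities=list(ref.entities), q=avg)


def classify_membership(
    q: QMatrix, threshold: float = 0.75
) -> pd.Series:
    """Assign each entity to a cluster index (0-based) if its maximum
    membership reaches *threshold*, else the label ``"admixed"``."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    best = q.q.argmax(axis=1)
    ok = q.q[np.arange(len(q.entities)), best] >= threshold
    labels = [int(b) if o else ADMIXED for b, o in zip(best, ok)]
    return pd.Series(labels, index=q.entities, name="cluster")


# ---------------------------------------------------------------------------
# Rasters and IDW interpolation
# ---------------------------------------------------------------------------

@dataclass
class Raster:
    """A single- or multi-band regular grid.

    ``values`` has shape (rows, cols) or (bands, rows, cols); row 0 is the
    top row.  ``x0, y0`` locate the lower-left corner of the grid.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D or 3-D (bands first)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.shape
        xs = self.x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = self.y0 + (rows - np.arange(rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.x0, other.x0)
            and math.isclose(self.y0, other.y0)
            and math.isclose(self.cell_size, other.cell_size)
        )


def idw_surface(
    points: list[tuple[float, float, float]],
    x0: float,
    y0: float,
    cell_size: float,
    rows: int,
    cols: int,
    power: float = 2.0,
    mode: str = "planar",
) -> Raster:
    """Inverse-distance-weighted interpolation onto a regular grid.

    z(cell) = sum z_i d_i^-p / sum d_i^-p over all points (a convex
    combination, so the surface stays within the data range and passes
    exactly through data points).  ``mode="greatcircle"`` treats (x, y)
    as (longitude, latitude) in degrees and uses haversine distances.
    """
    if not points:
        raise ValueError("need at least one point")
    if power <= 0:
        raise ValueError("power must be > 0")
    pts = np.asarray(points, dtype=float)
    xy = pts[:, :2]
    seen: dict[tuple[float, float], float] = {}
    for x, y, z in pts:
        key = (round(x, 9), round(y, 9))
        if key in seen and not math.isclose(seen[key], z, abs_tol=1e-12):
            raise ValueError(f"coincident points at {key} with different values")
        seen[key] = z
    grid = Raster(x0=x0, y0=y0, cell_size=cell_size,
                  values=np.zeros((rows, cols)))
    gx, gy = grid.cell_centers()
    if mode == "planar":
        d = np.sqrt(
            (gx[..., None] - xy[None, None, :, 0]) ** 2
            + (gy[..., None] - xy[None, None, :, 1]) ** 2
        )
    elif mode == "greatcircle":
        lon1, lat1 = np.radians(gx)[..., None], np.radians(gy)[..., None]
        lon2 = np.radians(xy[None, None, :, 0])
        lat2 = np.radians(xy[None, None, :, 1])
        h = (np.sin((lat2 - lat1) / 2) ** 2
             + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
        d = 2.0 * 6371.0 * np.arcsin(np.sqrt(h))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = pts[:, 2]
    at_point = d < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w = np.where(at_point.any(axis=-1, keepdims=True), at_point.astype(float), w)
    grid.values = (w * z).sum(axis=-1) / w.sum(axis=-1)
    return grid


def composite_map(
    surfaces: list[Raster],
    colors: list[tuple[float, float, float]] | None = None,
    tol: float = 0.05,
) -> Raster:
    """Blend K per-cluster Q surfaces into a 3-band RGB raster.

    Cell color = sum_k Q_k(cell) * color_k, channels clipped to [0, 1].
    All surfaces must share the grid and per-cell sums must not exceed
    1 + *tol*.
    """
    if not surfaces:
        raise ValueError("no surfaces")
    base = surfaces[0]
    for s in surfaces[1:]:
        if not base.same_grid(s):
            raise ValueError("surfaces are not on the same grid")
    k = len(surfaces)
    if colors is None:
        if k > len(DEFAULT_PALETTE):
            raise ValueError(f"default palette has {len(DEFAULT_PALETTE)} colors; "
                             f"pass explicit colors for K={k}")
        colors = DEFAULT_PALETTE[:k]
    stack = np.stack([s.values for s in surfaces])
    sums = stack.sum(axis=0)
    if np.any(sums > 1.0 + tol) or np.any(sums < -tol):
        raise ValueError("per-cell Q sums outside [0, 1 + tol]")
    rgb = np.einsum("kij,kc->cij", stack, np.asarray(colors, dtype=float))
    rgb = np.clip(rgb, 0.0, 1.0)
    return Raster(x0=base.x0, y0=base.y0, cell_size=base.cell_size, values=rgb)


# ---------------------------------------------------------------------------
# ESRI ASCII grid output
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a single-band raster as an ESRI ASCII grid (plain text)."""
    if raster.values.ndim != 2:
        raise ValueError("ASCII grids are single-band; write bands separately")
    rows, cols = raster.shape
    header = (
        f"ncols {cols}\nnrows {rows}\n"
        f"xllcorner {raster.x0:.10g}\nyllcorner {raster.y0:.10g}\n"
        f"cellsize {raster.cell_size:.10g}\nNODATA_value {raster.nodata:.10g}\n"
    )
    body = "\n".join(
        " ".join(f"{v:.6g}" for v in row) for row in raster.values
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> Raster:
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    values = np.loadtxt(lines[i:])
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return Raster(
        x0=header["xllcorner"], y0=header["yllcorner"],
        cell_size=header["cellsize"], values=values,
        nodata=header.get("nodata_value", -9999.0),
    )
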
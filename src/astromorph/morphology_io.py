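"""Reading, writing, validation and stereological sampling of 3-D cell reconstructions.

Reconstructed astrocytes are exchanged as SWC files (7 whitespace-delimited
columns: id, type, x, y, z, radius, parent; ``#`` starts a comment; the root's
parent is ``-1``).  Coordinates are micrometres.  The ``type`` column is passed
through uninterpreted so glial reconstructions tagged 7 or with custom codes are
accepted unchanged.

The probe-grid machinery implements systematic-random stereological sampling:
small square probes placed on a regular lattice over a region contour, with the
cells whose somata fall inside a probe selected for reconstruction (and, for an
empty probe, the nearest soma outside it).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "CellMorphology",
    "ProbeGrid",
    "ValidationReport",
    "SWCError",
    "read_swc",
    "write_swc",
    "validate_tree",
    "correct_z_shrinkage",
    "place_probe_grid",
    "select_cells",
]

ROOT_PARENT = -1


class SWCError(ValueError):
    """Malformed or structurally invalid SWC content."""


@dataclass
class CellMorphology:
    """One reconstructed cell: a rooted tree of measured nodes.

    Node arrays are aligned; ``parents`` holds the parent's *node id*
    (``-1`` marks the root).  All coordinates and radii are in μm.
    """

    cell_id: str
    ids: np.ndarray            # (n,) int
    parents: np.ndarray        # (n,) int, -1 for the root
    xyz: np.ndarray            # (n, 3) float, μm
    radius: np.ndarray         # (n,) float, μm
    type_tag: np.ndarray       # (n,) int, uninterpreted
    species: str = ""
    individual: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.type_tag = np.asarray(self.type_tag, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[int, int]:
        """Map node id -> positional index."""
        return {int(i): k for k, i in enumerate(self.ids)}

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> list of child node ids (in file order)."""
        out: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for i, p in zip(self.ids, self.parents):
            if p != ROOT_PARENT:
                out.setdefault(int(p), []).append(int(i))
        return out

    @property
    def root_id(self) -> int:
        roots = self.ids[self.parents == ROOT_PARENT]
        if len(roots) != 1:
            raise SWCError(f"cell {self.cell_id!r} has {len(roots)} roots")
        return int(roots[0])


@dataclass
class ValidationReport:
    ok: bool
    issues: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class ProbeGrid:
    """Square sampling probes centred on a randomly offset regular lattice."""

    probe_side: float
    spacing: float
    origin_offset: tuple[float, float]
    probes: np.ndarray          # (m, 2) probe centres, μm
    contour: np.ndarray         # (k, 2) closed polygon vertices, μm


def read_swc(path: str | Path | io.TextIOBase, cell_id: str | None = None,
             species: str = "", individual: str = "") -> CellMorphology:
    """Parse a 7-column SWC file into a validated :class:`CellMorphology`.

    Raises :class:`SWCError` with the offending line number on malformed lines
    and on structural defects (orphan parents, duplicate ids, multiple roots).
    """
    if isinstance(path, (str, Path)):
        name = Path(path).stem
        with open(path) as fh:
            lines = fh.readlines()
    else:
        name = "cell"
        lines = path.readlines()
    if cell_id is None:
        cell_id = name

    ids, parents, xyz, radius, ttag = [], [], [], [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            tag = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            par = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from None
        ids.append(nid)
        ttag.append(tag)
        xyz.append((x, y, z))
        radius.append(r)
        parents.append(par)

    if not ids:
        raise SWCError("no data lines in SWC input")
    cell = CellMorphology(cell_id, np.array(ids), np.array(parents),
                          np.array(xyz), np.array(radius), np.array(ttag),
                          species=species, individual=individual)
    report = validate_tree(cell)
    if not report.ok:
        code, node, msg = report.issues[0]
        raise SWCError(f"invalid SWC structure ({code} at node {node}): {msg}")
    return cell


def write_swc(cell: CellMorphology, path: str | Path) -> Path:
    """Write a cell as standard 7-column SWC (root parent written as -1)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {cell.cell_id}\n")
        if cell.species:
            fh.write(f"# species: {cell.species}  individual: {cell.individual}\n")
        for i in range(cell.n_nodes):
            fh.write(
                f"{cell.ids[i]} {cell.type_tag[i]} "
                f"{float(cell.xyz[i, 0])!r} {float(cell.xyz[i, 1])!r} "
                f"{float(cell.xyz[i, 2])!r} "
                f"{float(cell.radius[i])!r} {cell.parents[i]}\n"
            )
    return path


def validate_tree(cell: CellMorphology) -> ValidationReport:
    """Enumerate every structural-invariant violation of a cell tree.

    Checked: unique node ids; exactly one root; parents defined before their
    children; no self-reference cycles; strictly positive radii.
    """
    issues: list[tuple[str, int, str]] = []
    seen: set[int] = set()
    for i, nid in enumerate(cell.ids):
        nid = int(nid)
        if nid in seen:
            issues.append(("duplicate-id", nid, "node id occurs more than once"))
        seen.add(nid)

    roots = [int(i) for i, p in zip(cell.ids, cell.parents) if p == ROOT_PARENT]
    if len(roots) == 0:
        issues.append(("no-root", -1, "no node with parent -1"))
    elif len(roots) > 1:
        for r in roots[1:]:
            issues.append(("multi-root", r, "more than one node with parent -1"))

    defined: set[int] = set()
    for nid, par in zip(cell.ids, cell.parents):
        nid, par = int(nid), int(par)
        if par == nid:
            issues.append(("cycle", nid, "node is its own parent"))
        elif par != ROOT_PARENT:
            if par not in seen:
                issues.append(("orphan-parent", nid, f"parent id {par} not in file"))
            elif par not in defined:
                issues.append(("parent-after-child", nid,
                               f"parent id {par} defined after this node"))
        defined.add(nid)

    for nid, r in zip(cell.ids, cell.radius):
        if not r > 0:
            issues.append(("nonpositive-radius", int(nid), f"radius {r} <= 0"))

    return ValidationReport(ok=not issues, issues=issues)


def correct_z_shrinkage(cell: CellMorphology, factor: float = 1.75) -> CellMorphology:
    """Restore section thickness lost to histological processing.

    Shrinkage is confined to the sectioning axis, so every z coordinate is
    multiplied by ``factor`` (default 1.75) while x, y and radii are untouched.
    """
    if not factor > 0:
        raise ValueError(f"shrinkage factor must be > 0, got {factor}")
    xyz = cell.xyz.copy()
    xyz[:, 2] = xyz[:, 2] * factor
    return replace(cell, xyz=xyz)


def _as_polygon(contour: np.ndarray | Polygon) -> Polygon:
    if isinstance(contour, Polygon):
        poly = contour
    else:
        arr = np.asarray(contour, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
            raise ValueError("contour must be an (n>=3, 2) polygon")
        poly = Polygon(arr)
    if not poly.is_valid:
        raise ValueError("contour polygon is self-intersecting or invalid")
    if poly.area <= 0:
        raise ValueError("contour polygon has zero area")
    return poly


# Lattice inclusion is half-open: a point on the "low" boundary belongs to the
# contour, a point on the "high" boundary does not.  Realised by testing the
# point nudged by +eps in x and y, which prevents double selection of lattice
# points shared by adjacent tiles.
_HALF_OPEN_EPS = 1e-9


def place_probe_grid(contour: np.ndarray | Polygon, probe_side: float = 50.0,
                     spacing: float = 900.0,
                     origin_offset: tuple[float, float] = (0.0, 0.0)) -> ProbeGrid:
    """Place square probes on the lattice ``origin_offset + spacing*(i, j)``.

    Only lattice points inside the contour (half-open convention) receive a
    probe.  ``origin_offset`` is typically a seeded uniform draw from
    ``[0, spacing)^2`` so the design is systematic-random.
    """
    if spacing < probe_side:
        raise ValueError("spacing must be >= probe_side")
    poly = _as_polygon(contour)
    minx, miny, maxx, maxy = poly.bounds
    ox, oy = float(origin_offset[0]), float(origin_offset[1])

    i_lo = int(np.floor((minx - ox) / spacing)) - 1
    i_hi = int(np.ceil((maxx - ox) / spacing)) + 1
    j_lo = int(np.floor((miny - oy) / spacing)) - 1
    j_hi = int(np.ceil((maxy - oy) / spacing)) + 1

    centres = []
    for i in range(i_lo, i_hi + 1):
        for j in range(j_lo, j_hi + 1):
            cx, cy = ox + spacing * i, oy + spacing * j
            probe_pt = Point(cx + _HALF_OPEN_EPS, cy + _HALF_OPEN_EPS)
            if poly.covers(probe_pt):
                centres.append((cx, cy))
    centres_arr = (np.asarray(centres, dtype=float) if centres
                   else np.empty((0, 2)))

    if isinstance(contour, Polygon):
        ring = np.asarray(contour.exterior.coords)
    else:
        ring = np.asarray(contour, dtype=float)
    return ProbeGrid(probe_side=float(probe_side), spacing=float(spacing),
                     origin_offset=(ox, oy), probes=centres_arr, contour=ring)


def _dist_to_box(x: np.ndarray, y: np.ndarray, cx: float, cy: float,
                 half: float) -> np.ndarray:
    dx = np.maximum(np.abs(x - cx) - half, 0.0)
    dy = np.maximum(np.abs(y - cy) - half, 0.0)
    return np.hypot(dx, dy)


def select_cells(somata: pd.DataFrame, grid: ProbeGrid) -> list:
    """Stereological cell selection against a probe grid.

    Every soma inside a probe box (half-open ``[c-side/2, c+side/2)`` square)
    is selected.  A probe containing no soma falls back to the single nearest
    soma outside it (distance to the box; ties broken by lowest cell_id).
    Each soma is selected at most once.  With no somata at all the selection is
    empty and a warning is issued.
    """
    import warnings

    if somata.empty:
        warnings.warn("no somata supplied; empty selection", stacklevel=2)
        return []
    df = somata.sort_values("cell_id").reset_index(drop=True)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    half = grid.probe_side / 2.0

    selected: list = []
    chosen = np.zeros(len(df), dtype=bool)
    empty_probes = []
    for cx, cy in grid.probes:
        inside = ((x >= cx - half) & (x < cx + half)
                  & (y >= cy - half) & (y < cy + half))
        if inside.any():
            for k in np.flatnonzero(inside & ~chosen):
                chosen[k] = True
                selected.append(df.at[k, "cell_id"])
        else:
            empty_probes.append((cx, cy))

    for cx, cy in empty_probes:
        if chosen.all():
            break
        d = _dist_to_box(x, y, cx, cy, half)
        d[chosen] = np.inf
        k = int(np.argmin(d))     # df sorted by cell_id -> ties pick lowest id
        chosen[k] = True
        selected.append(df.at[k, "cell_id"])
    return selected
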
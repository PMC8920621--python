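"""Marching-cubes case tables.

The cube corner numbering is fixed once here and shared by sampling, case
indexing and triangulation.  Corner ``k`` sits at the index offset
``CORNER_OFFSETS[k]`` relative to the cell's base grid vertex:

    D0=(0,1,0)  D1=(0,0,0)  D2=(1,0,0)  D3=(1,1,0)      (z = 0 layer)
    D4=(0,1,1)  D5=(0,0,1)  D6=(1,0,1)  D7=(1,1,1)      (z = 1 layer)

i.e. the bottom face is the cycle D1-D2-D3-D0 and the top face is the same
cycle shifted one slice up.  This is the numbering implied by the trilinear
corner weights used throughout the package.

The 256-entry triangle table is *generated* at import time rather than
transcribed from a published listing: for every corner sign pattern the
crossed edges are chained into closed polygons by walking the six cube
faces, then each polygon is fan-triangulated.  On a face where the inside
corners sit on a diagonal (the classic ambiguous configuration) the fixed
rule is to cut the inside corners off, i.e. each inside corner is clipped
by a segment joining its two crossed edges.  Because the rule depends only
on the face's own sign pattern, the two cells sharing a face always make
the same choice, so meshes are crack-free; on every non-ambiguous pattern
the resulting triangle set is the one of the standard published table
(same crossed-edge vertices, ``k - 2`` triangles per ``k``-gon).

Triangles are wound counter-clockwise as seen from the outside (the side
toward which the field decreases), so geometric normals point away from
the inside (``>= isovalue``) region.
"""

from __future__ import annotations

import itertools

import numpy as np

#: index offset of each corner D0..D7 within its cell
CORNER_OFFSETS: tuple[tuple[int, int, int], ...] = (
    (0, 1, 0),
    (0, 0, 0),
    (1, 0, 0),
    (1, 1, 0),
    (0, 1, 1),
    (0, 0, 1),
    (1, 0, 1),
    (1, 1, 1),
)


def _build_edges() -> tuple[tuple[tuple[int, int], ...], dict[tuple[int, int], int]]:
    edges = []
    for i, j in itertools.combinations(range(8), 2):
        a, b = CORNER_OFFSETS[i], CORNER_OFFSETS[j]
        if sum(x != y for x, y in zip(a, b)) == 1:
            edges.append((i, j))
    index = {pair: k for k, pair in enumerate(edges)}
    return tuple(edges), index


#: the 12 cube edges as sorted corner-index pairs, in a fixed order
EDGE_CORNERS, _EDGE_INDEX = _build_edges()

#: axis (0=x, 1=y, 2=z) along which each edge runs
EDGE_AXES: tuple[int, ...] = tuple(
    next(
        ax
        for ax in range(3)
        if CORNER_OFFSETS[i][ax] != CORNER_OFFSETS[j][ax]
    )
    for i, j in EDGE_CORNERS
)


def _build_faces() -> tuple[tuple[int, ...], ...]:
    """The 6 faces, each as 4 corner indices in cyclic order."""
    faces = []
    for axis in range(3):
        for side in (0, 1):
            members = [k for k in range(8) if CORNER_OFFSETS[k][axis] == side]
            other = [a for a in range(3) if a != axis]
            # order cyclically in the face plane
            ring = [(0, 0), (1, 0), (1, 1), (0, 1)]
            ordered = []
            for uv in ring:
                for k in members:
                    off = CORNER_OFFSETS[k]
                    if (off[other[0]], off[other[1]]) == uv:
                        ordered.append(k)
            faces.append(tuple(ordered))
    return tuple(faces)


FACES = _build_faces()


def _face_segments(face: tuple[int, ...], inside: tuple[bool, ...]):
    """Pairs of crossed edges connected across one face.

    Ambiguous diagonal pattern: each inside corner is cut off by the
    segment joining its two adjacent crossed edges (symmetric rule).
    """
    crossed = []
    for k in range(4):
        a, b = face[k], face[(k + 1) % 4]
        if inside[a] != inside[b]:
            crossed.append((k, _EDGE_INDEX[(min(a, b), max(a, b))]))
    if len(crossed) == 2:
        return [(crossed[0][1], crossed[1][1])]
    if len(crossed) == 4:
        segments = []
        for k in range(4):
            if inside[face[k]]:
                prev_e = _EDGE_INDEX[tuple(sorted((face[k - 1], face[k])))]
                next_e = _EDGE_INDEX[tuple(sorted((face[k], face[(k + 1) % 4])))]
                segments.append((prev_e, next_e))
        return segments
    return []


def _polygon_cycles(inside: tuple[bool, ...]) -> list[list[int]]:
    """Closed polygons of crossed-edge indices for one sign pattern."""
    adjacency: dict[int, list[int]] = {}
    for face in FACES:
        for a, b in _face_segments(face, inside):
            adjacency.setdefault(a, []).append(b)
            adjacency.setdefault(b, []).append(a)
    # every crossed edge lies on exactly two faces, each contributing one
    # segment through it, so every node has degree exactly 2 and the graph
    # decomposes into disjoint simple cycles
    cycles = []
    seen: set[int] = set()
    for start in adjacency:
        if start in seen:
            continue
        cycle = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            a, b = adjacency[cur]
            nxt = a if a != prev else b
            if nxt == start:
                break
            cycle.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        cycles.append(cycle)
    return cycles


def _edge_midpoint(edge: int) -> np.ndarray:
    i, j = EDGE_CORNERS[edge]
    return (np.asarray(CORNER_OFFSETS[i], float) + np.asarray(CORNER_OFFSETS[j], float)) / 2.0


def _orient(cycle: list[int], inside: tuple[bool, ...]) -> list[int]:
    pts = [_edge_midpoint(e) for e in cycle]
    normal = np.zeros(3)
    for k in range(len(pts)):  # Newell's method
        p, q = pts[k], pts[(k + 1) % len(pts)]
        normal += np.cross(p, q)
    outward = np.zeros(3)
    for e in cycle:
        i, j = EDGE_CORNERS[e]
        if inside[i]:  # points from the inside endpoint to the outside one
            outward += np.asarray(CORNER_OFFSETS[j], float) - np.asarray(CORNER_OFFSETS[i], float)
        else:
            outward += np.asarray(CORNER_OFFSETS[i], float) - np.asarray(CORNER_OFFSETS[j], float)
    if float(normal @ outward) < 0.0:
        cycle = cycle[::-1]
    return cycle


def _build_triangle_table() -> tuple[tuple[tuple[int, int, int], ...], ...]:
    table = []
    for case in range(256):
        inside = tuple(bool(case >> k & 1) for k in range(8))
        triangles: list[tuple[int, int, int]] = []
        for cycle in _polygon_cycles(inside):
            cycle = _orient(cycle, inside)
            for k in range(1, len(cycle) - 1):
                triangles.append((cycle[0], cycle[k], cycle[k + 1]))
        table.append(tuple(triangles))
    return tuple(table)


#: per case index (bit k set = corner k inside), the triangles as edge triples
TRI_TABLE = _build_triangle_table()

#: per case index, bitmask over the 12 edges that carry a surface vertex
EDGE_TABLE: tuple[int, ...] = tuple(
    int(sum(1 << e for e in {e for tri in tris for e in tri}))
    for tris in TRI_TABLE
)


def _ambiguous_cases() -> frozenset[int]:
    out = set()
    for case in range(256):
        inside = tuple(bool(case >> k & 1) for k in range(8))
        for face in FACES:
            states = [inside[c] for c in face]
            if states == [True, False, True, False] or states == [False, True, False, True]:
                out.add(case)
                break
    return frozenset(out)


#: cases containing at least one diagonally-ambiguous face; on these the
#: classic published table and this generated table may triangulate
#: differently (both are valid isosurface topologies of the sign pattern)
AMBIGUOUS_CASES = _ambiguous_cases()
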
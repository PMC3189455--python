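"""Delaunay tessellation of C-alpha traces.

The Delaunay tessellation of the C-alpha point set partitions the convex
hull of a chain into irregular, space-filling tetrahedra ("simplices").
The four vertices of each simplex are mutual nearest neighbors, and the
multiset of their amino-acid types — the quadruplet composition — is the
unit over which the four-body statistical potential is defined.

Computation is delegated to Qhull via :class:`scipy.spatial.Delaunay`;
this module canonicalizes the output (sorted vertex tuples, lexicographic
simplex order) so tessellations are byte-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial import QhullError
from scipy.spatial.distance import pdist

from .structures import CAlphaTrace

__all__ = [
    "Simplex",
    "Tessellation",
    "DegenerateGeometryError",
    "tessellate",
    "neighbors",
    "quadruplet_composition",
]


class DegenerateGeometryError(ValueError):
    """Raised when the point set is too degenerate to tessellate."""


@dataclass(frozen=True)
class Simplex:
    """One Delaunay tetrahedron: four distinct 1-based vertex indices
    (sorted ascending) and the length of its longest edge in Angstrom."""

    vertices: tuple[int, int, int, int]
    max_edge: float

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != 4:
            raise ValueError("simplex needs 4 distinct vertices")
        if tuple(sorted(self.vertices)) != tuple(self.vertices):
            raise ValueError("vertices must be stored sorted ascending")


@dataclass
class Tessellation:
    """A canonicalized Delaunay tessellation of ``n_points`` points."""

    simplices: list[Simplex]
    n_points: int
    cutoff: float | None = None
    _incidence: dict[int, list[Simplex]] | None = field(
        default=None, repr=False, compare=False
    )

    def incidence(self) -> dict[int, list[Simplex]]:
        """Map each vertex index to the simplices it participates in."""
        if self._incidence is None:
            inc: dict[int, list[Simplex]] = {}
            for s in self.simplices:
                for v in s.vertices:
                    inc.setdefault(v, []).append(s)
            self._incidence = inc
        return self._incidence

    def to_text(self) -> str:
        """Serialize as one line per simplex: ``v1 v2 v3 v4 max_edge``."""
        head = f"# n_points {self.n_points}\n# cutoff {self.cutoff}\n"
        body = "".join(
            f"{s.vertices[0]} {s.vertices[1]} {s.vertices[2]} {s.vertices[3]} "
            f"{s.max_edge:.6f}\n"
            for s in self.simplices
        )
        return head + body

    @classmethod
    def from_text(cls, text: str) -> "Tessellation":
        n_points = 0
        cutoff: float | None = None
        simplices = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                _, key, val = line.split(None, 2)
                if key == "n_points":
                    n_points = int(val)
                elif key == "cutoff":
                    cutoff = None if val == "None" else float(val)
                continue
            a, b, c, d, edge = line.split()
            simplices.append(
                Simplex((int(a), int(b), int(c), int(d)), float(edge))
            )
        return cls(simplices=simplices, n_points=n_points, cutoff=cutoff)


def _build(points: np.ndarray, cutoff: float | None) -> list[Simplex]:
    tri = Delaunay(points)
    seen: set[tuple[int, ...]] = set()
    simplices: list[Simplex] = []
    for row in tri.simplices:
        verts = tuple(sorted(int(v) + 1 for v in row))
        if verts in seen:
            continue
        seen.add(verts)
        edge = float(pdist(points[[v - 1 for v in verts]]).max())
        if cutoff is not None and edge > cutoff:
            continue
        simplices.append(Simplex(verts, edge))
    simplices.sort(key=lambda s: s.vertices)
    return simplices


def tessellate(
    trace: CAlphaTrace | np.ndarray,
    cutoff: float | None = None,
    jitter_seed: int = 0,
) -> Tessellation:
    """Compute the Delaunay tessellation of a trace (or raw point array).

    Parameters
    ----------
    trace
        A :class:`CAlphaTrace` or an ``(N, 3)`` coordinate array, N >= 4.
    cutoff
        Optional maximum edge length in Angstrom; simplices whose longest
        edge exceeds it are discarded.  Default keeps every simplex.
    jitter_seed
        Seed for the fallback jitter applied when Qhull reports a
        cospherical/coplanar degeneracy: a uniform perturbation of magnitude
        1e-6 Angstrom is added and the tessellation retried once.  Real CA
        coordinates are essentially never degenerate; synthetic fixtures
        can be.

    Raises
    ------
    DegenerateGeometryError
        If the points are collinear/coplanar (jitter cannot fix a rank
        deficiency at this magnitude) or the jittered retry also fails.
    """
    points = trace.coords() if isinstance(trace, CAlphaTrace) else np.asarray(trace, float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 4:
        raise ValueError("need an (N, 3) point set with N >= 4")
    centered = points - points.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9)
    if rank < 3:
        raise DegenerateGeometryError(
            "points are collinear/coplanar; Delaunay tessellation in 3D is "
            "undefined — perturb the input (enable jitter) or fix the geometry"
        )
    try:
        simplices = _build(points, cutoff)
    except QhullError:
        rng = np.random.default_rng(jitter_seed)
        jittered = points + rng.uniform(-1e-6, 1e-6, size=points.shape)
        try:
            simplices = _build(jittered, cutoff)
        except QhullError as exc:
            raise DegenerateGeometryError(
                f"Qhull failed even after 1e-6 jitter: {exc}"
            ) from exc
    return Tessellation(simplices=simplices, n_points=len(points), cutoff=cutoff)


def neighbors(tess: Tessellation, position: int) -> set[int]:
    """Tessellation nearest neighbors of ``position`` (1-based).

    The union of all vertices co-occurring with ``position`` in any simplex,
    excluding the position itself; empty if the position occurs in no
    simplex (e.g. removed by the edge-length cutoff).
    """
    if not 1 <= position <= tess.n_points:
        raise IndexError(f"position {position} out of range 1..{tess.n_points}")
    out: set[int] = set()
    for s in tess.incidence().get(position, []):
        out.update(s.vertices)
    out.discard(position)
    return out


def quadruplet_composition(
    tess: Tessellation, trace: CAlphaTrace, simplex: Simplex
) -> tuple[str, str, str, str]:
    """The amino-acid composition of a simplex, canonicalized by sorting.

    Order within a quadruplet carries no information, so the key is the
    sorted multiset of the four residues' one-letter codes.
    """
    aas = sorted(trace.residues[v - 1].aa for v in simplex.vertices)
    return (aas[0], aas[1], aas[2], aas[3])
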
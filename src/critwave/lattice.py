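"""Checkerboard excitatory/inhibitory lattice and its antisymmetric coupling matrix.

The model places one unit on every site of an ``N x N`` square lattice.
Units on "white" squares of the checkerboard are excitatory, units on
"black" squares inhibitory, and every connection has the same magnitude
``g``.  Each unit couples to its 4 nearest neighbours, with the sign of
the connection set by the parity of the *presynaptic* site: an inhibitory
unit inhibits all of its neighbours.  Because nearest neighbours always
have opposite parity, the resulting coupling matrix ``A`` is exactly
antisymmetric and hence has a purely imaginary spectrum -- the lattice is
poised at a high-dimensional Hopf bifurcation ("critical balance" of
excitation and inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LatticeSpec",
    "DistanceShells",
    "parity",
    "build_coupling",
    "distance_shells",
    "save_coupling_triplets",
]


class LatticeError(ValueError):
    """Invalid lattice specification or geometry query."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and coupling strength of the E/I lattice.

    Parameters
    ----------
    n : int
        Edge length in sites.  Must be even (so the checkerboard parity
        tiles the torus consistently) and at least 4.
    g : float
        Synaptic strength, units 1/time.  Strictly positive; all
        connections share this single magnitude.
    bc : {"periodic", "open"}
        Boundary condition.  Periodic is the default: the translation-
        invariant dispersion analysis presupposes it, and it avoids edge
        reflections contaminating attenuation fits.
    """

    n: int
    g: float = 1.0
    bc: str = "periodic"

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)):
            raise LatticeError(f"n must be an integer, got {self.n!r}")
        if self.n < 4:
            raise LatticeError(f"n must be >= 4, got n={self.n}")
        if self.n % 2 != 0:
            raise LatticeError(f"n must be even (checkerboard parity), got n={self.n}")
        if not (self.g > 0):
            raise LatticeError(f"g must be > 0, got g={self.g}")
        if self.bc not in ("periodic", "open"):
            raise LatticeError(f"bc must be 'periodic' or 'open', got {self.bc!r}")

    @property
    def n_sites(self) -> int:
        return self.n * self.n

    def site_index(self, col: int, row: int) -> int:
        """0-based row-major index of the site at (col, row)."""
        n = self.n
        if self.bc == "periodic":
            col %= n
            row %= n
        if not (0 <= col < n and 0 <= row < n):
            raise LatticeError(f"site ({col}, {row}) outside open lattice of edge {n}")
        return col + n * row

    def site_coords(self, index: int) -> tuple[int, int]:
        """(col, row) of a site index."""
        if not (0 <= index < self.n_sites):
            raise LatticeError(f"site index {index} out of range [0, {self.n_sites})")
        return index % self.n, index // self.n

    @property
    def center(self) -> tuple[int, int]:
        return self.n // 2, self.n // 2


def parity(spec: LatticeSpec) -> np.ndarray:
    """Per-site parity sigma = (-1)^(col+row): +1 excitatory, -1 inhibitory."""
    cols, rows = np.meshgrid(np.arange(spec.n), np.arange(spec.n), indexing="xy")
    # row-major flattening matches site_index = col + n*row
    return np.where((cols + rows) % 2 == 0, 1, -1).ravel().astype(np.int8)


_NEIGHBOR_STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def neighbor_indices(spec: LatticeSpec, index: int) -> list[int]:
    """Nearest-neighbour site indices under the spec's boundary condition."""
    col, row = spec.site_coords(index)
    out = []
    for dc, dr in _NEIGHBOR_STEPS:
        c, r = col + dc, row + dr
        if spec.bc == "periodic":
            out.append(spec.site_index(c, r))
        elif 0 <= c < spec.n and 0 <= r < spec.n:
            out.append(spec.site_index(c, r))
    return out


def build_coupling(spec: LatticeSpec) -> sp.csr_matrix:
    """Antisymmetric nearest-neighbour coupling matrix A (n^2 x n^2, sparse).

    ``A[i, j] = g * sigma(j)`` when j is a nearest neighbour of i, else 0.
    Antisymmetry is exact (not merely to round-off): neighbours have
    opposite parity, so ``A[j, i] = g*sigma(i) = -g*sigma(j) = -A[i, j]``,
    with identical floating-point magnitudes on both sides.
    """
    sig = parity(spec)
    rows, cols, vals = [], [], []
    for i in range(spec.n_sites):
        for j in neighbor_indices(spec, i):
            rows.append(i)
            cols.append(j)
            vals.append(spec.g * sig[j])
    A = sp.csr_matrix(
        (np.asarray(vals, dtype=float), (rows, cols)),
        shape=(spec.n_sites, spec.n_sites),
    )
    return A


@dataclass(frozen=True)
class DistanceShells:
    """Partition of lattice sites into integer-radius shells around a center.

    ``shells[b]`` lists the site indices whose (minimum-image, if periodic)
    Euclidean distance to the center rounds to ``b``.  Shell 0 is exactly
    the center site; the shells partition the lattice.
    """

    center: int
    radii: np.ndarray  # sorted occupied shell radii
    shells: dict[int, np.ndarray] = field(repr=False)
    bin_of_site: np.ndarray = field(repr=False)

    def sites(self, radius: int) -> np.ndarray:
        return self.shells[int(radius)]


def distance_shells(
    spec: LatticeSpec,
    center: int | tuple[int, int] | None = None,
    metric: str = "euclidean",
) -> DistanceShells:
    """Bin sites by rounded Euclidean distance from ``center``.

    Under periodic boundaries distances use the minimum image on the
    torus, so the largest attainable radius is round(sqrt(2)*n/2).
    """
    if metric != "euclidean":
        raise LatticeError(f"unsupported metric {metric!r}")
    if center is None:
        center = spec.center
    if isinstance(center, tuple):
        c_idx = spec.site_index(*center)
    else:
        c_idx = int(center)
        if not (0 <= c_idx < spec.n_sites):
            raise LatticeError(f"center index {c_idx} out of range")
    c_col, c_row = spec.site_coords(c_idx)

    cols, rows = np.meshgrid(np.arange(spec.n), np.arange(spec.n), indexing="xy")
    dx = np.abs(cols.ravel() - c_col)
    dy = np.abs(rows.ravel() - c_row)
    if spec.bc == "periodic":
        dx = np.minimum(dx, spec.n - dx)
        dy = np.minimum(dy, spec.n - dy)
    dist = np.hypot(dx, dy)
    bins = np.rint(dist).astype(int)
    shells = {int(b): np.flatnonzero(bins == b) for b in np.unique(bins)}
    radii = np.array(sorted(shells), dtype=int)
    return DistanceShells(center=c_idx, radii=radii, shells=shells, bin_of_site=bins)


def save_coupling_triplets(A: sp.spmatrix, path) -> None:
    """Write the coupling matrix as sparse coordinate triplets (i, j, value)."""
    coo = sp.coo_matrix(A)
    with open(path, "w") as fh:
        fh.write("# i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{float(v)!r}\n")
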
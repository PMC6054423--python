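"""Rectangular lattices of probe ("dummy") atoms that fill cavities.

A probe is a massless, hydrogen-sized pseudo-atom used purely as the
geometric origin of a binding-site pattern.  Grids are cell-centered by
default: an axis of length L sampled at n points puts nodes at
center − L/2 + L·(k + 0.5)/n, which yields exactly nx·ny·nz probes
strictly inside the box.  Probe ids are 1-based and ascend along the
box's long axis first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .structure_io import AtomRecord, Structure

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class ProbeGrid:
    center: np.ndarray
    dims: tuple[float, float, float]
    counts: tuple[int, int, int]
    probes: list[tuple[int, np.ndarray]]
    axis_order: tuple[int, int, int]  # long axis first

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[int]:
        return [pid for pid, _ in self.probes]

    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.probes], dtype=float)

    @property
    def long_axis(self) -> str:
        return "xyz"[self.axis_order[0]]

    def transformed(self, transform) -> "ProbeGrid":
        probes = [(pid, transform.apply(p)) for pid, p in self.probes]
        return ProbeGrid(transform.apply(self.center), self.dims, self.counts,
                         probes, self.axis_order)

    def to_structure(self) -> Structure:
        """Probes as HETATM records: residue 'DUM', element H, one
        residue per probe, the probe id in the residue number."""
        atoms = [
            AtomRecord(name="DUM", element="H", pos=pos, is_hetero=True,
                       chain="P", resnum=pid, resname="DUM")
            for pid, pos in self.probes
        ]
        return Structure(atoms=atoms, title="probe grid")


def _axis_coords(center: float, length: float, n: int,
                 convention: str) -> np.ndarray:
    if convention == "cell-centered":
        k = np.arange(n)
        return center - length / 2 + length * (k + 0.5) / n
    if convention == "corner-inclusive":
        if n == 1:
            return np.array([center])
        return np.linspace(center - length / 2, center + length / 2, n)
    raise ValueError(f"unknown lattice convention {convention!r}")


def make_grid(center, dims, counts,
              convention: Literal["cell-centered", "corner-inclusive"] = "cell-centered",
              ) -> ProbeGrid:
    """Uniform lattice of nx·ny·nz probes spanning a rectangular box."""
    center = np.asarray(center, dtype=float).reshape(3)
    dims = tuple(float(d) for d in dims)
    counts = tuple(int(n) for n in counts)
    if any(n < 1 for n in counts):
        raise ValueError(f"counts must be >= 1, got {counts}")
    if any(d <= 0 for d in dims):
        raise ValueError(f"dims must be positive, got {dims}")

    axes = [_axis_coords(center[i], dims[i], counts[i], convention)
            for i in range(3)]
    long_axis = int(np.argmax(dims))
    rest = sorted((i for i in range(3) if i != long_axis), reverse=True)
    axis_order = (long_axis, *rest)

    # id order: ascending along the long axis, then the remaining axes
    nodes = [np.array([axes[0][i], axes[1][j], axes[2][k]])
             for i in range(counts[0])
             for j in range(counts[1])
             for k in range(counts[2])]
    nodes.sort(key=lambda p: tuple(p[a] for a in axis_order))
    probes = [(pid, pos) for pid, pos in enumerate(nodes, start=1)]
    return ProbeGrid(center=center, dims=dims, counts=counts,
                     probes=probes, axis_order=axis_order)


def prune_grid(grid: ProbeGrid, structure: Structure,
               min_clash: float = 2.0, max_shell: float = 8.0) -> ProbeGrid:
    """Drop probes that clash with the protein or sit outside it.

    A probe survives when its nearest protein heavy atom is at least
    `min_clash` away (not inside an atom) and at most `max_shell` away
    (not in bulk solvent).  Surviving probes keep their ids, so pruning
    is idempotent and ids remain comparable across prune settings.
    """
    if min_clash >= max_shell:
        raise ValueError("min_clash must be < max_shell")
    coords = np.array([a.pos for a in structure.heavy_atoms()], dtype=float)
    kept = []
    for pid, pos in grid.probes:
        if len(coords):
            d = np.min(np.linalg.norm(coords - pos, axis=1))
        else:
            d = np.inf  # no protein: outside any finite shell
        if min_clash <= d <= max_shell:
            kept.append((pid, pos))
    return replace(grid, probes=kept)


def sort_probes_by_axis(grid: ProbeGrid, axis: str | None = None) -> list[int]:
    """Probe ids in stable ascending order of one coordinate (default:
    the long lattice axis); ties keep ascending probe-id order."""
    ax = AXIS_INDEX[axis] if axis is not None else grid.axis_order[0]
    order = sorted(grid.probes, key=lambda item: (item[1][ax], item[0]))
    return [pid for pid, _ in order]
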
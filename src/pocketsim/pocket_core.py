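"""Binding-site extraction, binned distance sets, and the PMScore.

The similarity statistic works on a *pattern*: the set of residues with
at least one heavy atom within a cutoff radius of a probe point (or of
any ligand atom).  For every unordered pair of distinct residues in a
pattern, three inter-residue distances are measured — Cα–Cα, Cβ–Cβ and
centroid–centroid — and stored, ascending-sorted, in bins keyed by the
point kind and the unordered pair of chemical tags.  With 3 point kinds
and C(5,2)+5 = 15 tag pairs there are 45 possible bins.

Two patterns are compared bin-by-bin with a greedy two-pointer sweep
that counts distance pairs agreeing within a tolerance (default 0.5 Å).
The PMScore is the total match count divided by the larger pattern's
total distance count, so it lies in [0, 1] and equals 1 only for
patterns with identical distance multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping

import numpy as np

from .structure_io import (
    LigandAtoms,
    ResiduePoints,
    Structure,
    build_residue_points,
)

PointKind = Literal["CA", "CB", "CM"]
POINT_KINDS: tuple[PointKind, ...] = ("CA", "CB", "CM")
BinKey = tuple[PointKind, tuple[int, int]]

#: all 45 possible bin keys: 3 point kinds × 15 unordered tag pairs
ALL_BIN_KEYS: tuple[BinKey, ...] = tuple(
    (kind, (i, j))
    for kind in POINT_KINDS
    for i in range(1, 6)
    for j in range(i, 6)
)


@dataclass
class PocketSite:
    """Residues surrounding a probe point or a ligand at a cutoff radius."""

    origin: np.ndarray | None
    radius: float
    residues: list[ResiduePoints]

    def __post_init__(self) -> None:
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DistanceSet:
    """Binned ascending-sorted inter-residue point distances of one site."""

    bins: dict[BinKey, np.ndarray]
    n_total: int

    @property
    def is_empty(self) -> bool:
        return self.n_total == 0


@dataclass
class PMResult:
    """Outcome of one PMScore comparison.

    ``score = matches / max(n_a, n_b)``; when both sites are empty the
    score is defined as 0 and ``empty`` is set.
    """

    matches: int
    n_a: int
    n_b: int
    score: float
    empty: bool = False

    def to_dict(self) -> dict:
        return {"matches": self.matches, "n_a": self.n_a, "n_b": self.n_b,
                "score": self.score, "empty": self.empty}


def _site_from_mask(points: list[ResiduePoints], mask: np.ndarray,
                    origin, radius: float) -> PocketSite:
    residues = [rp for rp, keep in zip(points, mask) if keep]
    residues.sort(key=lambda rp: rp.residue_id)
    return PocketSite(origin=origin, radius=radius, residues=residues)


def residue_atom_coords(structure: Structure,
                        points: list[ResiduePoints]) -> list[np.ndarray]:
    """Heavy-atom coordinate arrays per reduced residue, aligned with
    `points` (used to test the ≤-radius membership rule atom-wise)."""
    groups = structure.residues(hetero=False)
    return [
        np.array([a.pos for a in groups[rp.residue_id] if not a.is_hydrogen])
        for rp in points
    ]


def extract_site(structure: Structure, probe, radius: float,
                 _cache: "SiteExtractor | None" = None) -> PocketSite:
    """Residues with ≥1 heavy atom within `radius` of the probe point.

    An empty site is a valid result (probing bulk solvent).  Order is
    deterministic: ascending (chain, resnum, insertion code).
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    ex = _cache if _cache is not None else SiteExtractor(structure)
    return ex.site(probe, radius)


def extract_ligand_site(structure: Structure, ligand: LigandAtoms,
                        cutoff: float) -> PocketSite:
    """Residues with ≥1 heavy atom within `cutoff` of ANY ligand heavy atom."""
    if not ligand.atoms:
        raise ValueError("ligand has no atoms")
    ex = SiteExtractor(structure)
    dmin = ex.min_distances_to(ligand.coords())
    mask = dmin <= cutoff
    return _site_from_mask(ex.points, mask, ligand.centroid(), cutoff)


class SiteExtractor:
    """Precomputed per-structure geometry for repeated site extraction.

    Profiling sweeps extract thousands of sites from the same structure;
    this caches the residue reductions and per-residue heavy-atom
    coordinates once so each extraction is a vectorised distance test.
    """

    def __init__(self, structure: Structure,
                 tag_table: Mapping[str, int] | None = None):
        from .structure_io import residue_points

        self.structure = structure
        self.points = residue_points(structure, tag_table)
        self._atom_groups = residue_atom_coords(structure, self.points)
        if self._atom_groups:
            self._flat = np.concatenate(self._atom_groups)
            lengths = [len(g) for g in self._atom_groups]
            self._owner = np.repeat(np.arange(len(lengths)), lengths)
        else:
            self._flat = np.empty((0, 3))
            self._owner = np.empty(0, dtype=int)

    def min_distances_to(self, targets: np.ndarray) -> np.ndarray:
        """Per-residue minimum heavy-atom distance to any target point."""
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        n = len(self.points)
        if n == 0 or len(targets) == 0:
            return np.full(n, np.inf)
        d = np.linalg.norm(self._flat[:, None, :] - targets[None, :, :],
                           axis=2).min(axis=1)
        out = np.full(n, np.inf)
        np.minimum.at(out, self._owner, d)
        return out

    def site(self, probe, radius: float) -> PocketSite:
        probe = np.asarray(probe, dtype=float).reshape(3)
        dmin = self.min_distances_to(probe[None, :])
        return _site_from_mask(self.points, dmin <= radius, probe, radius)


def distance_sets(site: PocketSite) -> DistanceSet:
    """Build the binned sorted distance sets of a site.

    For each unordered pair of distinct residues, stores |Cα−Cα′|,
    |Cβ−Cβ′| and |centroid−centroid′| under the bin keyed by the point
    kind and the unordered tag pair.  n_total = 3·C(n, 2).
    """
    raw: dict[BinKey, list[float]] = {}
    res = site.residues
    for a, b in combinations(res, 2):
        ti, tj = sorted((a.tag.value, b.tag.value))
        pa, pb = a.points(), b.points()
        for kind in POINT_KINDS:
            d = float(np.linalg.norm(pa[kind] - pb[kind]))
            raw.setdefault((kind, (ti, tj)), []).append(d)
    bins = {k: np.sort(np.asarray(v)) for k, v in raw.items()}
    n_total = sum(len(v) for v in bins.values())
    return DistanceSet(bins=bins, n_total=n_total)


def align_bin(list_a, list_b, tol: float = 0.5) -> int:
    """Greedy two-pointer alignment of two ascending-sorted distance lists.

    Values within `tol` of each other match and both pointers advance;
    otherwise the pointer at the smaller value advances.  For sorted
    lists this greedy sweep attains the maximum monotone (non-crossing)
    matching.  Equal values are a match (|Δ| = 0 ≤ tol).
    """
    a = np.asarray(list_a, dtype=float)
    b = np.asarray(list_b, dtype=float)
    i = j = matches = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            matches += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matches


def pm_score(ds_a: DistanceSet | PocketSite, ds_b: DistanceSet | PocketSite,
             tol: float = 0.5,
             denominator: Literal["max", "min"] = "max") -> PMResult:
    """PMScore between two distance sets (or sites, reduced on the fly).

    matches = Σ over shared bin keys of the greedy per-bin alignment;
    score = matches / max(n_a, n_b) by default (``denominator="min"``
    offers the permissive variant).  Two empty sites score 0, flagged.
    """
    if isinstance(ds_a, PocketSite):
        ds_a = distance_sets(ds_a)
    if isinstance(ds_b, PocketSite):
        ds_b = distance_sets(ds_b)
    matches = 0
    for key, la in ds_a.bins.items():
        lb = ds_b.bins.get(key)
        if lb is not None and len(lb):
            matches += align_bin(la, lb, tol)
    n_a, n_b = ds_a.n_total, ds_b.n_total
    denom = max(n_a, n_b) if denominator == "max" else min(n_a, n_b)
    if denom == 0:
        return PMResult(matches=0, n_a=n_a, n_b=n_b, score=0.0, empty=True)
    return PMResult(matches=matches, n_a=n_a, n_b=n_b,
                    score=matches / denom)
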
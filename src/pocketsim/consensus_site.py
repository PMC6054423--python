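"""Pseudocenter site alignment and consensus binding-site construction.

Each pocket residue is summarised by one or two typed pseudocenters —
hydrogen-bond donor, acceptor, mixed donor/acceptor, aliphatic, or
aromatic — placed on the functional group that carries the property
(hydroxyl oxygen, carboxylate midpoint, ring centroid, ...).  Two sites
are aligned by enumerating type-compatible pseudocenter triplets with
compatible internal distances, solving the least-squares rigid
superposition for each seed, greedily extending to all type-matched
pairs within a radius epsilon, and keeping the alignment with the most
matches (ties: lower RMSD).  Matched residues of the same
physicochemical group then merge into one consensus residue at the
midpoint; everything unmatched is preserved with its provenance.

The triplet-seeded search is a deliberate, exhaustively-verifiable
simplification of geometric-hashing site alignment: correct for
desk-scale sites of up to a few dozen residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Literal, Mapping, Sequence

import numpy as np

from .geometry import RigidTransform, kabsch, rmsd
from .pocket_core import PocketSite
from .structure_io import AtomRecord, ResiduePoints, Structure

PCType = Literal["donor", "acceptor", "donor/acceptor", "aliphatic", "aromatic"]
PC_TYPES: tuple[PCType, ...] = (
    "donor", "acceptor", "donor/acceptor", "aliphatic", "aromatic",
)

#: residue physicochemical groups for the merge rule, from the chemical tag
TAG_GROUP = {1: "non-polar", 2: "non-polar", 3: "polar",
             4: "positive", 5: "negative"}


class DegenerateSiteError(ValueError):
    """Fewer than 3 pseudocenters on a side: no non-trivial alignment."""


@dataclass
class Pseudocenter:
    pos: np.ndarray
    ptype: PCType
    source: tuple[str, int, str, str]  # chain, resnum, icode, resname

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        if self.ptype not in PC_TYPES:
            raise ValueError(f"unknown pseudocenter type {self.ptype!r}")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return self.source[:3]


# Placement rules: resname -> list of (ptype, kind, atom names).
# kind "atom": the named atom; "midpoint": mean of the named atoms;
# "ring": centroid of the ring atoms; "centroid": the side-chain
# centroid of the three-point reduction.  Missing atoms fall back to
# the side-chain centroid.  The table is a documented stand-in for the
# established pseudocenter conventions and is config-overridable.
PCRule = tuple[PCType, str, tuple[str, ...]]
DEFAULT_PSEUDOCENTER_RULES: dict[str, list[PCRule]] = {
    **{r: [("aliphatic", "centroid", ())]
       for r in ("ALA", "VAL", "LEU", "ILE", "MET", "PRO", "CYS", "GLY")},
    "SER": [("donor/acceptor", "atom", ("OG",))],
    "THR": [("donor/acceptor", "atom", ("OG1",))],
    "TYR": [("donor/acceptor", "atom", ("OH",)),
            ("aromatic", "ring", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "PHE": [("aromatic", "ring", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TRP": [("donor", "atom", ("NE1",)),
            ("aromatic", "ring",
             ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"))],
    "HIS": [("donor", "atom", ("NE2",)),
            ("aromatic", "ring", ("CG", "ND1", "CD2", "CE1", "NE2"))],
    "ASN": [("donor/acceptor", "midpoint", ("OD1", "ND2"))],
    "GLN": [("donor/acceptor", "midpoint", ("OE1", "NE2"))],
    "ASP": [("acceptor", "midpoint", ("OD1", "OD2"))],
    "GLU": [("acceptor", "midpoint", ("OE1", "OE2"))],
    "LYS": [("donor", "atom", ("NZ",))],
    "ARG": [("donor", "midpoint", ("NH1", "NH2"))],
}


@dataclass
class SiteAlignment:
    transform: RigidTransform
    correspondences: list[tuple[int, int]]
    pcs_a: list[Pseudocenter]
    pcs_b: list[Pseudocenter]
    rmsd: float

    @property
    def match_count(self) -> int:
        return len(self.correspondences)

    @property
    def rotation(self) -> np.ndarray:
        return self.transform.rotation

    @property
    def translation(self) -> np.ndarray:
        return self.transform.translation

    def matched_pairs(self) -> list[tuple[Pseudocenter, Pseudocenter]]:
        return [(self.pcs_a[i], self.pcs_b[j])
                for i, j in self.correspondences]


@dataclass
class ConsensusResidue:
    position: np.ndarray
    group: str
    resname_a: str
    resname_b: str
    source_a: tuple[str, int, str]
    source_b: tuple[str, int, str]


@dataclass
class ConsensusSite:
    """Merged + preserved residues of two aligned sites (in B's frame)."""

    merged: list[ConsensusResidue]
    preserved: list[tuple[str, ResiduePoints]]  # ("A"|"B", residue)
    transform: RigidTransform

    def to_structure(self) -> Structure:
        """One Cα pseudo-atom per residue: chain A/B = preserved with
        provenance, chain C = merged consensus residues."""
        atoms = []
        for k, cr in enumerate(self.merged, start=1):
            atoms.append(AtomRecord(name="CA", element="C", pos=cr.position,
                                    is_hetero=False, chain="C", resnum=k,
                                    resname=cr.resname_a))
        for label, rp in self.preserved:
            pos = self.transform.apply(rp.p_ca) if label == "A" else rp.p_ca
            atoms.append(AtomRecord(name="CA", element="C", pos=pos,
                                    is_hetero=False, chain=label,
                                    resnum=rp.resnum, resname=rp.resname))
        return Structure(atoms=atoms, title="consensus binding site")


def _residue_atoms_by_name(structure: Structure | None,
                           rp: ResiduePoints) -> dict[str, np.ndarray]:
    if structure is None:
        return {}
    groups = structure.residues(hetero=False)
    atoms = groups.get(rp.residue_id, [])
    return {a.name: a.pos for a in atoms if not a.is_hydrogen}


def assign_pseudocenters(site: PocketSite,
                         rule_table: Mapping[str, list[PCRule]] | None = None,
                         structure: Structure | None = None,
                         ) -> list[Pseudocenter]:
    """Typed pseudocenters for every residue of a site.

    With the parent `structure` available, centers are placed on the
    named functional-group atoms; otherwise (or when atoms are missing)
    they fall back to the residue's side-chain centroid.  Residues
    absent from the rule table are skipped.
    """
    table = DEFAULT_PSEUDOCENTER_RULES if rule_table is None else rule_table
    out: list[Pseudocenter] = []
    for rp in site.residues:
        rules = table.get(rp.resname)
        if rules is None:
            continue
        by_name = _residue_atoms_by_name(structure, rp)
        for ptype, kind, names in rules:
            pos = None
            if kind == "centroid":
                pos = rp.p_cm
            elif names and all(n in by_name for n in names):
                pos = np.mean([by_name[n] for n in names], axis=0)
            if pos is None:
                pos = rp.p_cm
            out.append(Pseudocenter(
                pos=pos, ptype=ptype,
                source=(rp.chain, rp.resnum, rp.icode, rp.resname),
            ))
    return out


def _fit_ok(A: np.ndarray, B: np.ndarray, pairs: list[tuple[int, int]],
            epsilon: float) -> tuple[RigidTransform, float] | None:
    """Least-squares fit of a correspondence set; None unless every
    pair lands within epsilon under its own fit."""
    ia = [i for i, _ in pairs]
    ib = [j for _, j in pairs]
    tf = kabsch(A[ia], B[ib])
    d = np.linalg.norm(tf.apply(A[ia]) - B[ib], axis=1)
    if np.any(d > epsilon):
        return None
    return tf, float(np.sqrt(np.mean(d ** 2)))


def _grow(A: np.ndarray, B: np.ndarray,
          types_a: list[str], types_b: list[str],
          seed_pairs: list[tuple[int, int]], epsilon: float,
          ) -> tuple[list[tuple[int, int]], RigidTransform, float] | None:
    """Verified greedy growth of a seed correspondence.

    Repeatedly tries to add the unused type-matched pair with the
    smallest residual under the current fit; an addition is kept only
    when the refit on the enlarged set still places every matched pair
    within epsilon.  Returns None when the seed itself does not verify.
    """
    fit = _fit_ok(A, B, list(seed_pairs), epsilon)
    if fit is None:
        return None
    pairs = list(seed_pairs)
    tf, r = fit
    while True:
        used_a = {i for i, _ in pairs}
        used_b = {j for _, j in pairs}
        TA = tf.apply(A)
        cands = sorted(
            (float(np.linalg.norm(TA[i] - B[j])), i, j)
            for i in range(len(A)) if i not in used_a
            for j in range(len(B))
            if j not in used_b and types_a[i] == types_b[j]
        )
        added = False
        for d, i, j in cands:
            if d > 2.0 * epsilon:
                break  # beyond any refit's reach
            fit = _fit_ok(A, B, pairs + [(i, j)], epsilon)
            if fit is not None:
                pairs.append((i, j))
                tf, r = fit
                added = True
                break
        if not added:
            return sorted(pairs), tf, r


def align_sites(pcs_a: Sequence[Pseudocenter], pcs_b: Sequence[Pseudocenter],
                epsilon: float = 1.5) -> SiteAlignment:
    """Rigid superposition maximising type-matched pseudocenters.

    Seeds: every type-compatible triplet correspondence whose three
    internal distances agree within 2·epsilon (the widest discrepancy a
    per-point epsilon match permits).  Each verifying seed is grown by
    verified greedy addition — one pair at a time, refitting the
    least-squares transform and requiring all matched pairs within
    epsilon.  Best alignment by (match count, lower RMSD) wins.
    """
    pcs_a = list(pcs_a)
    pcs_b = list(pcs_b)
    if len(pcs_a) < 3 or len(pcs_b) < 3:
        raise DegenerateSiteError(
            f"need >= 3 pseudocenters per side, got {len(pcs_a)} and {len(pcs_b)}"
        )
    A = np.array([p.pos for p in pcs_a])
    B = np.array([p.pos for p in pcs_b])
    ta = [p.ptype for p in pcs_a]
    tb = [p.ptype for p in pcs_b]

    by_type_b: dict[str, list[int]] = {}
    for j, t in enumerate(tb):
        by_type_b.setdefault(t, []).append(j)

    best: SiteAlignment | None = None
    window = 2.0 * epsilon
    for tri_a in combinations(range(len(pcs_a)), 3):
        i1, i2, i3 = tri_a
        da = (np.linalg.norm(A[i1] - A[i2]),
              np.linalg.norm(A[i1] - A[i3]),
              np.linalg.norm(A[i2] - A[i3]))
        pool = [by_type_b.get(ta[i], []) for i in tri_a]
        for j1 in pool[0]:
            for j2 in pool[1]:
                if j2 == j1 or abs(da[0] - np.linalg.norm(B[j1] - B[j2])) > window:
                    continue
                for j3 in pool[2]:
                    if j3 in (j1, j2):
                        continue
                    if (abs(da[1] - np.linalg.norm(B[j1] - B[j3])) > window
                            or abs(da[2] - np.linalg.norm(B[j2] - B[j3])) > window):
                        continue
                    grown = _grow(A, B, ta, tb,
                                  [(i1, j1), (i2, j2), (i3, j3)], epsilon)
                    if grown is None:
                        continue
                    pairs, tf, r = grown
                    cand = SiteAlignment(transform=tf, correspondences=pairs,
                                         pcs_a=pcs_a, pcs_b=pcs_b, rmsd=r)
                    if best is None or (cand.match_count, -cand.rmsd) > (
                            best.match_count, -best.rmsd):
                        best = cand
    if best is None:
        return SiteAlignment(transform=RigidTransform.identity(),
                             correspondences=[], pcs_a=pcs_a, pcs_b=pcs_b,
                             rmsd=0.0)
    return best


def merge_consensus(site_a: PocketSite, site_b: PocketSite,
                    alignment: SiteAlignment,
                    merge_eps: float = 1.5) -> ConsensusSite:
    """Collapse aligned equivalent residues; preserve the rest.

    Two residues merge when (i) at least one pseudocenter pair of
    theirs is matched by the alignment, (ii) they belong to the same
    physicochemical group (polar / non-polar / positive / negative,
    derived from the chemical tag), and (iii) their Cα's lie within
    `merge_eps` after superposition.  Each source residue appears in
    exactly one merged entry or one preserved entry.
    """
    res_a = {rp.residue_id: rp for rp in site_a.residues}
    res_b = {rp.residue_id: rp for rp in site_b.residues}

    # candidate residue pairs from matched pseudocenters
    pair_votes: dict[tuple, int] = {}
    for pa, pb in alignment.matched_pairs():
        key = (pa.residue_id, pb.residue_id)
        pair_votes[key] = pair_votes.get(key, 0) + 1

    tf = alignment.transform
    candidates = []
    for (rid_a, rid_b), votes in pair_votes.items():
        rp_a = res_a.get(rid_a)
        rp_b = res_b.get(rid_b)
        if rp_a is None or rp_b is None:
            continue
        if TAG_GROUP[rp_a.tag.value] != TAG_GROUP[rp_b.tag.value]:
            continue
        d_ca = float(np.linalg.norm(tf.apply(rp_a.p_ca) - rp_b.p_ca))
        if d_ca > merge_eps:
            continue
        candidates.append((-votes, d_ca, rid_a, rid_b))
    candidates.sort()

    used_a: set = set()
    used_b: set = set()
    merged: list[ConsensusResidue] = []
    for _, _, rid_a, rid_b in candidates:
        if rid_a in used_a or rid_b in used_b:
            continue
        rp_a, rp_b = res_a[rid_a], res_b[rid_b]
        merged.append(ConsensusResidue(
            position=(tf.apply(rp_a.p_ca) + rp_b.p_ca) / 2.0,
            group=TAG_GROUP[rp_a.tag.value],
            resname_a=rp_a.resname, resname_b=rp_b.resname,
            source_a=rid_a, source_b=rid_b,
        ))
        used_a.add(rid_a)
        used_b.add(rid_b)

    preserved = (
        [("A", rp) for rid, rp in sorted(res_a.items()) if rid not in used_a]
        + [("B", rp) for rid, rp in sorted(res_b.items()) if rid not in used_b]
    )
    return ConsensusSite(merged=merged, preserved=preserved, transform=tf)
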
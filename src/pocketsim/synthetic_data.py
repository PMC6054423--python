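"""Synthetic toy pockets with controlled geometry, tags, and noise.

Generates small protein-like pockets (5–40 residues) with realistic
local geometry — Cβ at 1.53 Å from Cα, side-chain centroids 1.5–4 Å out
— but no fold, no physics and no solvent.  Every generator is
deterministic under an explicit seed (numpy's default PCG64 generator);
nothing is ever wall-clock seeded.  The module exists so that every
other component is testable without external coordinates: planted
shared sub-pockets give ground truth for similarity recovery, Gaussian
coordinate noise probes score degradation, and retagging probes the
chemistry-sensitivity of the distance bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import RigidTransform
from .structure_io import AtomRecord, LigandAtoms, Structure, DEFAULT_TAG_TABLE

#: side-chain heavy atoms (beyond Cα) of each standard residue
SIDECHAIN_TEMPLATES: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "CYS": ("CB", "SG"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
}

TAG_GROUPS: dict[int, tuple[str, ...]] = {
    tag: tuple(sorted(r for r, t in DEFAULT_TAG_TABLE.items() if t == tag))
    for tag in range(1, 6)
}

CA_CB_BOND = 1.53  # Å
MIN_CA_SEPARATION = 3.5  # Å


class PackingError(RuntimeError):
    """Could not place the requested residues in the shell."""


@dataclass(frozen=True)
class PocketSpec:
    """Recipe for one toy pocket.

    tag_mix is the probability of each chemical tag 1..5; residues are
    placed uniformly in a spherical shell [radius_range] around the
    origin with Cα's at least 3.5 Å apart.
    """

    n_residues: int
    tag_mix: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    radius_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        mix = np.asarray(self.tag_mix, dtype=float)
        if len(mix) != 5 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("tag_mix must be 5 non-negative values summing to 1")


def _element_of(name: str) -> str:
    return name[0] if name[0] in "NOS" else "C"


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _residue_atoms(rng: np.random.Generator, resname: str, ca: np.ndarray,
                   chain: str, resnum: int) -> list[AtomRecord]:
    """Backbone + templated side chain around a Cα position.

    Side-chain atoms beyond Cβ are scattered in a 1.2 Å ball around a
    point 2–2.8 Å out along the Cβ direction, which keeps the centroid
    1.5–4 Å from the Cα for every template.
    """
    u_n = _random_unit(rng)
    u_c = _random_unit(rng)
    atoms = [
        AtomRecord(name="N", element="N", pos=ca + 1.46 * u_n,
                   chain=chain, resnum=resnum, resname=resname),
        AtomRecord(name="CA", element="C", pos=ca,
                   chain=chain, resnum=resnum, resname=resname),
        AtomRecord(name="C", element="C", pos=ca + 1.52 * u_c,
                   chain=chain, resnum=resnum, resname=resname),
        AtomRecord(name="O", element="O", pos=ca + 1.52 * u_c + 1.23 * _random_unit(rng),
                   chain=chain, resnum=resnum, resname=resname),
    ]
    side = SIDECHAIN_TEMPLATES[resname]
    if side:
        d = _random_unit(rng)
        cb = ca + CA_CB_BOND * d
        atoms.append(AtomRecord(name=side[0], element="C", pos=cb,
                                chain=chain, resnum=resnum, resname=resname))
        if len(side) > 1:
            cluster = ca + rng.uniform(2.0, 2.8) * d
            for name in side[1:]:
                pos = cluster + rng.uniform(-1.0, 1.0, size=3) * 1.2 / np.sqrt(3)
                atoms.append(AtomRecord(name=name, element=_element_of(name),
                                        pos=pos, chain=chain, resnum=resnum,
                                        resname=resname))
    return atoms


def _place_ca(rng: np.random.Generator, placed: list[np.ndarray],
              radius_range: tuple[float, float], center: np.ndarray,
              max_tries: int = 2000) -> np.ndarray:
    rmin, rmax = radius_range
    for _ in range(max_tries):
        r = (rmin ** 3 + (rmax ** 3 - rmin ** 3) * rng.uniform()) ** (1 / 3)
        ca = center + r * _random_unit(rng)
        if all(np.linalg.norm(ca - p) >= MIN_CA_SEPARATION for p in placed):
            return ca
    raise PackingError(
        f"could not place residue {len(placed) + 1} in shell {radius_range}"
    )


def make_toy_pocket(spec: PocketSpec, chain: str = "S",
                    center=(0.0, 0.0, 0.0)) -> Structure:
    """Deterministic toy pocket: `n_residues` residues in a shell.

    Residue names are drawn group-first from `tag_mix`, then uniformly
    within the chosen chemical group.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(center, dtype=float)
    atoms: list[AtomRecord] = []
    placed: list[np.ndarray] = []
    for i in range(spec.n_residues):
        tag = int(rng.choice(5, p=np.asarray(spec.tag_mix))) + 1
        resname = str(rng.choice(TAG_GROUPS[tag]))
        ca = _place_ca(rng, placed, spec.radius_range, center)
        placed.append(ca)
        atoms.extend(_residue_atoms(rng, resname, ca, chain, i + 1))
    return Structure(atoms=atoms, title=f"toy pocket seed={spec.seed}")


def perturb(structure: Structure, sigma: float, seed: int) -> Structure:
    """Independent zero-mean Gaussian noise (std `sigma` per coordinate)
    on every atom; sigma = 0 reproduces the input exactly."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Structure(atoms=[replace(a) for a in structure.atoms],
                         model_id=structure.model_id, title=structure.title)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(structure.atoms), 3))
    atoms = [replace(a, pos=a.pos + n)
             for a, n in zip(structure.atoms, noise)]
    return Structure(atoms=atoms, model_id=structure.model_id,
                     title=structure.title)


def retag(structure: Structure, fraction: float, seed: int,
          target_group: int) -> Structure:
    """Rename round(fraction·n) polymer residues into `target_group`.

    The Cα/Cβ positions are kept; side-chain atoms beyond Cβ are
    re-templated for the new name (the geometry change is incidental,
    the tag change is the point).  Hetero residues are untouched.
    """
    if target_group not in TAG_GROUPS:
        raise ValueError("target_group must be 1..5")
    rng = np.random.default_rng(seed)
    residues = structure.residues(hetero=False)
    rids = sorted(residues)
    k = int(round(fraction * len(rids)))
    idx = rng.choice(len(rids), size=k, replace=False) if k else []
    chosen = {rids[i] for i in idx}

    atoms: list[AtomRecord] = []
    for rid in rids:
        group = residues[rid]
        if rid not in chosen:
            atoms.extend(replace(a) for a in group)
            continue
        new_name = str(rng.choice(TAG_GROUPS[target_group]))
        by_name = {a.name: a for a in group}
        ca = by_name["CA"].pos
        keep = [replace(a, resname=new_name) for a in group
                if a.name in ("N", "CA", "C", "O")]
        side = SIDECHAIN_TEMPLATES[new_name]
        if side:
            old_cb = by_name.get("CB")
            d = ((old_cb.pos - ca) / np.linalg.norm(old_cb.pos - ca)
                 if old_cb is not None else _random_unit(rng))
            cb = ca + CA_CB_BOND * d
            keep.append(AtomRecord(name=side[0], element="C", pos=cb,
                                   chain=rid[0], resnum=rid[1], icode=rid[2],
                                   resname=new_name))
            if len(side) > 1:
                cluster = ca + rng.uniform(2.0, 2.8) * d
                for name in side[1:]:
                    pos = cluster + rng.uniform(-1.0, 1.0, size=3) * 1.2 / np.sqrt(3)
                    keep.append(AtomRecord(name=name, element=_element_of(name),
                                           pos=pos, chain=rid[0], resnum=rid[1],
                                           icode=rid[2], resname=new_name))
        atoms.extend(keep)
    hetero = [replace(a) for a in structure.atoms if a.is_hetero]
    return Structure(atoms=atoms + hetero, model_id=structure.model_id,
                     title=structure.title)


def make_planted_pair(shared_spec: PocketSpec,
                      decoy_spec_a: PocketSpec | None,
                      decoy_spec_b: PocketSpec | None,
                      rigid_motion: RigidTransform | None = None,
                      decoy_offset: float = 35.0,
                      ) -> tuple[Structure, Structure, list[tuple[str, int, str]]]:
    """Two structures sharing an identical (rigidly moved) sub-pocket.

    Structure A = shared pocket (chain S, at the origin) + decoy pocket
    A (chain D, centered +`decoy_offset` Å along x).  Structure B = the
    same shared pocket + decoy pocket B (chain D, −`decoy_offset` Å
    along x), with `rigid_motion` applied to all of B.  Returns the
    ground-truth shared residue ids (valid in both structures).
    """
    if decoy_offset < 20.0:
        raise ValueError("decoy shells must sit >= 20 Å from the shared pocket")
    if rigid_motion is None:
        rigid_motion = RigidTransform.identity()

    shared = make_toy_pocket(shared_spec, chain="S")
    shared_ids = sorted(shared.residues(hetero=False))

    atoms_a = [replace(a) for a in shared.atoms]
    if decoy_spec_a is not None:
        decoy_a = make_toy_pocket(decoy_spec_a, chain="D",
                                  center=(decoy_offset, 0.0, 0.0))
        atoms_a.extend(decoy_a.atoms)

    atoms_b = [replace(a) for a in shared.atoms]
    if decoy_spec_b is not None:
        decoy_b = make_toy_pocket(decoy_spec_b, chain="D",
                                  center=(-decoy_offset, 0.0, 0.0))
        atoms_b.extend(decoy_b.atoms)

    struct_a = Structure(atoms=atoms_a, title="planted pair A")
    struct_b = Structure(atoms=atoms_b, title="planted pair B").transformed(rigid_motion)
    return struct_a, struct_b, shared_ids


def make_toy_complex(spec: PocketSpec, ligand_resname: str = "LIG",
                     n_ligand_atoms: int = 5,
                     ) -> tuple[Structure, LigandAtoms]:
    """A toy pocket with a small hetero ligand at its center."""
    rng = np.random.default_rng(spec.seed + 1)
    structure = make_toy_pocket(spec)
    lig_atoms = [
        AtomRecord(name=f"C{i+1}", element="C",
                   pos=rng.uniform(-1.5, 1.5, size=3),
                   is_hetero=True, chain="L", resnum=900,
                   resname=ligand_resname)
        for i in range(n_ligand_atoms)
    ]
    structure.atoms.extend(lig_atoms)
    ligand = LigandAtoms(resname=ligand_resname, chain="L", atoms=lig_atoms)
    return structure, ligand


def make_ensemble(reference: tuple[Structure, LigandAtoms], n_frames: int,
                  mixing: Sequence[float] | None, seed: int,
                  sigma_scale: float = 2.0, target_group: int = 5,
                  ) -> list[tuple[Structure, LigandAtoms]]:
    """Frames interpolating from the reference to a scrambled pocket.

    Frame k is the reference perturbed with sigma = sigma_scale ·
    mixing[k] and retagged with fraction mixing[k] into `target_group`;
    mixing[k] = 0 reproduces the reference exactly.  The ligand is left
    untouched so the site anchor stays fixed.  Default mixing: linear
    0 → 1 over the frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if mixing is None:
        mixing = np.linspace(0.0, 1.0, n_frames)
    mixing = np.asarray(mixing, dtype=float)
    if len(mixing) != n_frames or np.any((mixing < 0) | (mixing > 1)):
        raise ValueError("mixing must be n_frames values in [0, 1]")

    ref_struct, ref_ligand = reference
    lig_names = {a.name for a in ref_ligand.atoms}
    frames = []
    for k, m in enumerate(mixing):
        frame = ref_struct
        if m > 0:
            frame = perturb(ref_struct, sigma_scale * float(m), seed + 7 * k)
            # restore the ligand atoms exactly
            lig_pos = {a.name: a.pos for a in ref_ligand.atoms}
            for a in frame.atoms:
                if a.is_hetero and a.resname == ref_ligand.resname and a.name in lig_names:
                    a.pos = lig_pos[a.name].copy()
            frame = retag(frame, float(m), seed + 7 * k + 3, target_group)
        else:
            frame = perturb(ref_struct, 0.0, seed)
        lig = LigandAtoms(
            resname=ref_ligand.resname, chain=ref_ligand.chain,
            atoms=[a for a in frame.atoms
                   if a.is_hetero and a.resname == ref_ligand.resname],
        )
        frames.append((frame, lig))
    return frames
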
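"""Structure reading/writing and the three-point tagged residue reduction.

PDB parsing and serialisation are delegated to :mod:`gemmi`; this module
adds the representation the similarity statistic operates on: each
standard residue reduced to three labelled points — the Cα, the Cβ, and
the unweighted centroid of its side-chain heavy atoms — together with a
chemical tag in 1..5 classifying the residue as aliphatic-hydrophobic,
aromatic, polar-uncharged, positively or negatively charged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class PDBFormatError(ValueError):
    """Input text contains no parsable coordinate records."""


class ModelNotFoundError(LookupError):
    """Requested MODEL number absent from the file."""


class LigandNotFoundError(LookupError):
    """No hetero residue with the requested name."""


class AmbiguousLigandError(ValueError):
    """Several ligand copies match and no chain was given."""


class UnknownResidueError(KeyError):
    """Residue name missing from the active tag table (strict mode)."""


# Default five-group chemical tag table.  The partition follows the
# common hydrophobic / aromatic / polar / positive / negative split of
# the 20 standard residues, with histidine counted as positive.  It is
# an overridable input, not a fixed truth.
DEFAULT_TAG_TABLE: dict[str, int] = {
    **{r: 1 for r in ("ALA", "VAL", "LEU", "ILE", "MET", "CYS", "PRO", "GLY")},
    **{r: 2 for r in ("PHE", "TRP", "TYR")},
    **{r: 3 for r in ("SER", "THR", "ASN", "GLN")},
    **{r: 4 for r in ("LYS", "ARG", "HIS")},
    **{r: 5 for r in ("ASP", "GLU")},
}

TAG_LABELS: dict[int, str] = {
    1: "aliphatic-hydrophobic",
    2: "aromatic",
    3: "polar-uncharged",
    4: "positive",
    5: "negative",
}


@dataclass(frozen=True)
class ChemTag:
    """One of the five residue chemistry classes used to key distance bins."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in TAG_LABELS:
            raise ValueError(f"chemical tag must be 1..5, got {self.value}")

    @property
    def label(self) -> str:
        return TAG_LABELS[self.value]


@dataclass
class AtomRecord:
    """One PDB coordinate record (ATOM or HETATM)."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    chain: str = "A"
    resnum: int = 1
    icode: str = ""
    resname: str = "UNK"

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, resnum, insertion code) — the residue identity key."""
        return (self.chain, self.resnum, self.icode)


@dataclass
class Structure:
    """A flat list of atom records for one model."""

    atoms: list[AtomRecord] = field(default_factory=list)
    model_id: int = 1
    title: str = ""

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def residues(self, hetero: bool | None = None) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Group atoms by residue identity, preserving file order.

        ``hetero=False`` keeps polymer (ATOM) residues only, ``True``
        keeps HETATM residues only, ``None`` keeps everything.
        """
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for atom in self.atoms:
            if hetero is not None and atom.is_hetero != hetero:
                continue
            out.setdefault(atom.residue_id, []).append(atom)
        return out

    def transformed(self, transform) -> "Structure":
        """Copy with a rigid transform applied to every atom position."""
        atoms = [replace(a, pos=transform.apply(a.pos)) for a in self.atoms]
        return Structure(atoms=atoms, model_id=self.model_id, title=self.title)


@dataclass
class ResiduePoints:
    """The three-point, tagged reduction of one residue.

    ``p_cb`` falls back to ``p_ca`` when no Cβ exists (glycine, chain
    breaks); ``p_cm`` is the unweighted mean of the side-chain heavy
    atoms (everything beyond Cα excluding backbone N, C, O, OXT), again
    falling back to ``p_ca`` when the side chain is absent.
    """

    chain: str
    resnum: int
    icode: str
    resname: str
    tag: ChemTag
    p_ca: np.ndarray
    p_cb: np.ndarray
    p_cm: np.ndarray

    def __post_init__(self) -> None:
        self.p_ca = np.asarray(self.p_ca, dtype=float).reshape(3)
        self.p_cb = np.asarray(self.p_cb, dtype=float).reshape(3)
        self.p_cm = np.asarray(self.p_cm, dtype=float).reshape(3)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)

    def points(self) -> dict[str, np.ndarray]:
        return {"CA": self.p_ca, "CB": self.p_cb, "CM": self.p_cm}


@dataclass
class LigandAtoms:
    """Heavy atoms of one bound hetero residue (the site-defining ligand)."""

    resname: str
    chain: str
    atoms: list[AtomRecord]

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per (residue, atom name): highest occupancy,
    ties broken by alphabetically first altloc."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (*atom.residue_id, atom.resname, atom.name)
        prev = best.get(key)
        if prev is None:
            best[key] = atom
            order.append(key)
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy, _altloc_rank(prev.altloc)
        ):
            best[key] = atom
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # higher rank wins; blank altloc outranks everything, then A > B > ...
    if not altloc or altloc == "\x00":
        return 0.0
    return -ord(altloc)


def parse_structure(text: str, model: int | None = None) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Returns the atoms of the requested model (default: the first one)
    with alternate locations resolved to the highest-occupancy conformer.
    Hydrogens are retained in the record; downstream geometry ignores
    them via :meth:`Structure.heavy_atoms`.
    """
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBFormatError("no coordinate records found")

    chosen = None
    if model is None:
        chosen = st[0]
    else:
        for m in st:
            if int(m.num) == model:
                chosen = m
                break
        if chosen is None:
            raise ModelNotFoundError(
                f"model {model} not in file (has {[int(m.num) for m in st]})"
            )

    atoms: list[AtomRecord] = []
    for ch in chosen:
        for res in ch:
            het = res.het_flag == "H"
            for a in res:
                altloc = a.altloc if a.altloc not in ("\x00",) else ""
                atoms.append(
                    AtomRecord(
                        name=a.name,
                        element=a.element.name,
                        pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=round(float(a.occ), 2),
                        altloc=altloc,
                        is_hetero=het,
                        chain=ch.name,
                        resnum=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        resname=res.name,
                    )
                )
    if not atoms:
        raise PDBFormatError("no parsable ATOM/HETATM record in requested model")
    model_id = int(chosen.num)
    return Structure(atoms=_resolve_altlocs(atoms), model_id=model_id,
                     title=st.name or "")


def read_structure(path: str | Path, model: int | None = None) -> Structure:
    return parse_structure(Path(path).read_text(), model=model)


def parse_models(text: str) -> list[Structure]:
    """All models of a multi-model PDB, in file order."""
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBFormatError("no coordinate records found")
    return [parse_structure(text, model=int(m.num)) for m in st]


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    # group atoms into (chain -> ordered residues) first; gemmi's
    # add_residue/add_chain copy their argument, so objects must be
    # complete before insertion
    chain_order: list[str] = []
    grouped: dict[str, list[tuple[tuple, list[AtomRecord]]]] = {}
    for atom in structure.atoms:
        if atom.chain not in grouped:
            grouped[atom.chain] = []
            chain_order.append(atom.chain)
        seq = grouped[atom.chain]
        rkey = (atom.resnum, atom.icode, atom.resname)
        if not seq or seq[-1][0] != rkey:
            seq.append((rkey, []))
        seq[-1][1].append(atom)

    st = gemmi.Structure()
    st.name = structure.title
    model = gemmi.Model(structure.model_id)
    for chain_name in chain_order:
        ch = gemmi.Chain(chain_name)
        for (resnum, icode, resname), atoms in grouped[chain_name]:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            res.het_flag = "H" if atoms[0].is_hetero else "A"
            for atom in atoms:
                g = gemmi.Atom()
                g.name = atom.name
                g.element = gemmi.Element(atom.element)
                g.pos = gemmi.Position(*atom.pos)
                g.occ = atom.occupancy
                if atom.altloc:
                    g.altloc = atom.altloc
                res.add_atom(g)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    return st


def structure_to_pdb(structure: Structure) -> str:
    """Serialise to PDB text (coordinates at the 3-decimal convention)."""
    return _to_gemmi(structure).make_pdb_string()


def write_structure(structure: Structure, path: str | Path) -> None:
    Path(path).write_text(structure_to_pdb(structure))


def assign_tag(resname: str,
               tag_table: Mapping[str, int] | None = None,
               strict: bool = False) -> ChemTag | None:
    """Look up the chemical tag for a residue name.

    Unknown names return ``None`` with a warning by default; with
    ``strict=True`` they raise :class:`UnknownResidueError`.
    """
    table = DEFAULT_TAG_TABLE if tag_table is None else tag_table
    if resname not in table:
        if strict:
            raise UnknownResidueError(resname)
        logger.warning("unknown residue name %r: skipped (no tag)", resname)
        return None
    return ChemTag(table[resname])


def build_residue_points(residue_atoms: Sequence[AtomRecord],
                         tag_table: Mapping[str, int] | None = None,
                         strict: bool = False) -> ResiduePoints | None:
    """Reduce one residue's atoms to the three-point representation.

    Returns ``None`` (with a logged warning) when the residue lacks a
    Cα heavy atom or its name has no tag.
    """
    heavy = [a for a in residue_atoms if not a.is_hydrogen]
    if not heavy:
        return None
    first = heavy[0]
    by_name = {a.name: a for a in heavy}
    ca = by_name.get("CA")
    if ca is None:
        logger.warning("residue %s %s%s has no Cα: skipped",
                       first.resname, first.chain, first.resnum)
        return None
    tag = assign_tag(first.resname, tag_table, strict=strict)
    if tag is None:
        return None
    p_ca = ca.pos
    cb = by_name.get("CB")
    p_cb = cb.pos if cb is not None else p_ca
    side = [a.pos for a in heavy if a.name not in BACKBONE_ATOMS]
    p_cm = np.mean(side, axis=0) if side else p_ca
    return ResiduePoints(
        chain=first.chain, resnum=first.resnum, icode=first.icode,
        resname=first.resname, tag=tag, p_ca=p_ca, p_cb=p_cb, p_cm=p_cm,
    )


def residue_points(structure: Structure,
                   tag_table: Mapping[str, int] | None = None,
                   strict: bool = False) -> list[ResiduePoints]:
    """Three-point reductions for every polymer residue of a structure,
    ordered by (chain, resnum, icode)."""
    out = []
    for _, atoms in sorted(structure.residues(hetero=False).items()):
        rp = build_residue_points(atoms, tag_table, strict=strict)
        if rp is not None:
            out.append(rp)
    return out


def select_ligand(structure: Structure, resname: str,
                  chain: str | None = None) -> LigandAtoms:
    """Pick the heavy atoms of a bound hetero residue by name.

    With several copies present, `chain` disambiguates; omitting it
    raises :class:`AmbiguousLigandError` listing the candidates.
    """
    candidates = [
        (rid, atoms)
        for rid, atoms in structure.residues(hetero=True).items()
        if atoms[0].resname == resname and (chain is None or rid[0] == chain)
    ]
    if not candidates:
        raise LigandNotFoundError(
            f"no hetero residue {resname!r}"
            + (f" in chain {chain!r}" if chain else "")
        )
    if len(candidates) > 1:
        where = ", ".join(f"{rid[0]}/{rid[1]}{rid[2]}" for rid, _ in candidates)
        raise AmbiguousLigandError(
            f"{len(candidates)} copies of {resname!r} ({where}); pass chain="
        )
    rid, atoms = candidates[0]
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        raise LigandNotFoundError(f"ligand {resname!r} has no heavy atoms")
    return LigandAtoms(resname=resname, chain=rid[0], atoms=heavy)
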
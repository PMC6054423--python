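from itertools import combinations, permutations

import numpy as np
import pytest

import pocketsim as ps
from pocketsim import synthetic_data as sd
from pocketsim.consensus_site import (
    PC_TYPES,
    DegenerateSiteError,
    Pseudocenter,
    align_sites,
    assign_pseudocenters,
    merge_consensus,
)
from pocketsim.geometry import kabsch, random_rigid_transform
from pocketsim.pocket_core import PocketSite, extract_site
from pocketsim.structure_io import AtomRecord, ChemTag, ResiduePoints


def brute_force_max_matches(pcs_a, pcs_b, eps):
    """Independent oracle: largest type-consistent correspondence set
    (size >= 3) whose own least-squares fit puts every pair within eps,
    found by exhausting all injective mappings."""
    A = np.array([p.pos for p in pcs_a])
    B = np.array([p.pos for p in pcs_b])
    ta = [p.ptype for p in pcs_a]
    tb = [p.ptype for p in pcs_b]
    best = 0
    for k in range(min(len(A), len(B)), 2, -1):
        if k <= best:
            break
        found = False
        for sub_a in combinations(range(len(A)), k):
            for sub_b in permutations(range(len(B)), k):
                if any(ta[i] != tb[j] for i, j in zip(sub_a, sub_b)):
                    continue
                tf = kabsch(A[list(sub_a)], B[list(sub_b)])
                d = np.linalg.norm(tf.apply(A[list(sub_a)]) - B[list(sub_b)],
                                   axis=1)
                if np.all(d <= eps):
                    best, found = k, True
                    break
            if found:
                break
    return best


def random_pcs(rng, n, label, types=PC_TYPES[:3]):
    return [Pseudocenter(rng.uniform(-6, 6, 3), rng.choice(types),
                         (label, i, "", "SER")) for i in range(n)]


class TestAssignPseudocenters:
    def _site_of(self, structure):
        return extract_site(structure, (0, 0, 0), 50.0)

    def test_serine_gets_mixed_donor_acceptor(self):
        atoms = [
            AtomRecord("CA", "C", (0, 0, 0), resname="SER", resnum=1),
            AtomRecord("CB", "C", (0, 0, 1.5), resname="SER", resnum=1),
            AtomRecord("OG", "O", (0, 1.2, 2.0), resname="SER", resnum=1),
        ]
        st = ps.Structure(atoms=atoms)
        pcs = assign_pseudocenters(self._site_of(st), structure=st)
        assert len(pcs) == 1
        assert pcs[0].ptype == "donor/acceptor"
        np.testing.assert_allclose(pcs[0].pos, [0, 1.2, 2.0])

    def test_phenylalanine_aromatic_at_ring_centroid(self):
        ring = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        rng = np.random.default_rng(1)
        ring_pos = rng.normal(size=(6, 3)) + [5, 5, 5]
        atoms = [AtomRecord("CA", "C", (0, 0, 0), resname="PHE", resnum=1),
                 AtomRecord("CB", "C", (1, 0, 0), resname="PHE", resnum=1)]
        atoms += [AtomRecord(n, "C", p, resname="PHE", resnum=1)
                  for n, p in zip(ring, ring_pos)]
        st = ps.Structure(atoms=atoms)
        pcs = assign_pseudocenters(self._site_of(st), structure=st)
        assert [p.ptype for p in pcs] == ["aromatic"]
        np.testing.assert_allclose(pcs[0].pos, ring_pos.mean(axis=0))

    def test_carboxylate_acceptor_at_midpoint(self):
        atoms = [
            AtomRecord("CA", "C", (0, 0, 0), resname="ASP", resnum=1),
            AtomRecord("CB", "C", (1.5, 0, 0), resname="ASP", resnum=1),
            AtomRecord("CG", "C", (2.5, 0, 0), resname="ASP", resnum=1),
            AtomRecord("OD1", "O", (3.0, 1.0, 0), resname="ASP", resnum=1),
            AtomRecord("OD2", "O", (3.0, -1.0, 0), resname="ASP", resnum=1),
        ]
        st = ps.Structure(atoms=atoms)
        pcs = assign_pseudocenters(self._site_of(st), structure=st)
        assert [p.ptype for p in pcs] == ["acceptor"]
        np.testing.assert_allclose(pcs[0].pos, [3.0, 0.0, 0.0])

    def test_empty_site_empty_list(self):
        assert assign_pseudocenters(PocketSite(None, 0, [])) == []

    def test_every_standard_residue_covered(self):
        st = sd.make_toy_pocket(sd.PocketSpec(n_residues=30, seed=17))
        site = extract_site(st, (0, 0, 0), 50.0)
        pcs = assign_pseudocenters(site, structure=st)
        covered = {p.residue_id for p in pcs}
        assert covered == {rp.residue_id for rp in site.residues}


class TestAlignSites:
    def test_rigid_copy_fully_recovered(self):
        st = sd.make_toy_pocket(sd.PocketSpec(n_residues=10, seed=7))
        site = extract_site(st, (0, 0, 0), 15.0)
        pcs = assign_pseudocenters(site, structure=st)
        tf = random_rigid_transform(np.random.default_rng(3))
        moved = st.transformed(tf)
        pcs_m = assign_pseudocenters(
            extract_site(moved, tf.apply(np.zeros(3)), 15.0), structure=moved)
        al = align_sites(pcs, pcs_m, epsilon=1.0)
        assert al.match_count == len(pcs)
        assert al.rmsd < 1e-6
        assert np.isclose(np.linalg.det(al.rotation), 1.0)

    def test_self_alignment_recovers_identity(self):
        st = sd.make_toy_pocket(sd.PocketSpec(n_residues=8, seed=13))
        site = extract_site(st, (0, 0, 0), 15.0)
        pcs = assign_pseudocenters(site, structure=st)
        al = align_sites(pcs, pcs, epsilon=1.0)
        assert al.rmsd < 1e-6
        np.testing.assert_allclose(al.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(al.translation, 0.0, atol=1e-6)

    def test_disjoint_types_no_matches(self):
        rng = np.random.default_rng(0)
        pcs_a = random_pcs(rng, 4, "A", types=["donor"])
        pcs_b = random_pcs(rng, 4, "B", types=["acceptor"])
        al = align_sites(pcs_a, pcs_b, epsilon=1.5)
        assert al.match_count == 0

    def test_degenerate_input_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DegenerateSiteError):
            align_sites(random_pcs(rng, 2, "A"), random_pcs(rng, 5, "B"))

    def test_matches_exhaustive_oracle_on_random_sites(self):
        """Triplet seeding + verified greedy growth must find the same
        maximum correspondence size as exhaustive search (50 seeds,
        6 centers per side)."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pcs_a = random_pcs(rng, 6, "A")
            pcs_b = random_pcs(rng, 6, "B")
            al = align_sites(pcs_a, pcs_b, epsilon=1.5)
            got = al.match_count if al.match_count >= 3 else 0
            assert got == brute_force_max_matches(pcs_a, pcs_b, 1.5)

    def test_match_count_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(42)
        pcs_a = random_pcs(rng, 6, "A")
        pcs_b = random_pcs(rng, 6, "B")
        base = align_sites(pcs_a, pcs_b, epsilon=1.5).match_count
        tf = random_rigid_transform(np.random.default_rng(5))
        moved_b = [Pseudocenter(tf.apply(p.pos), p.ptype, p.source)
                   for p in pcs_b]
        assert align_sites(pcs_a, moved_b, epsilon=1.5).match_count == base


class TestMergeConsensus:
    def _aligned_pair(self, seed=7, n=10):
        st = sd.make_toy_pocket(sd.PocketSpec(n_residues=n, seed=seed))
        site = extract_site(st, (0, 0, 0), 15.0)
        tf = random_rigid_transform(np.random.default_rng(seed))
        moved = st.transformed(tf)
        site_m = extract_site(moved, tf.apply(np.zeros(3)), 15.0)
        al = align_sites(assign_pseudocenters(site, structure=st),
                         assign_pseudocenters(site_m, structure=moved),
                         epsilon=1.0)
        return site, site_m, al

    def test_identical_sites_fully_merged(self):
        site, site_m, al = self._aligned_pair()
        cons = merge_consensus(site, site_m, al)
        assert len(cons.merged) == len(site)
        assert cons.preserved == []

    def test_zero_match_alignment_preserves_everything(self):
        from pocketsim.consensus_site import SiteAlignment
        from pocketsim.geometry import RigidTransform

        site, site_m, al = self._aligned_pair(seed=3, n=6)
        empty = SiteAlignment(RigidTransform.identity(), [], al.pcs_a,
                              al.pcs_b, 0.0)
        cons = merge_consensus(site, site_m, empty)
        assert cons.merged == []
        assert len(cons.preserved) == len(site) + len(site_m)

    def test_coverage_counts_every_residue_once(self):
        for seed in range(5):
            site, site_m, al = self._aligned_pair(seed=seed, n=8)
            cons = merge_consensus(site, site_m, al)
            assert 2 * len(cons.merged) + len(cons.preserved) == (
                len(site) + len(site_m))
            merged_a = {cr.source_a for cr in cons.merged}
            merged_b = {cr.source_b for cr in cons.merged}
            preserved_a = {rp.residue_id for lab, rp in cons.preserved
                           if lab == "A"}
            preserved_b = {rp.residue_id for lab, rp in cons.preserved
                           if lab == "B"}
            assert merged_a | preserved_a == {rp.residue_id
                                              for rp in site.residues}
            assert merged_b | preserved_b == {rp.residue_id
                                              for rp in site_m.residues}
            assert not merged_a & preserved_a
            assert not merged_b & preserved_b

    def test_group_mismatch_blocks_merge(self):
        """An aspartate matched onto a lysine pseudocenter must not
        merge: negative vs positive groups differ."""
        def rp_of(resname, tag, pos):
            pos = np.asarray(pos, float)
            return ResiduePoints("A", 1, "", resname, ChemTag(tag),
                                 pos, pos, pos)

        from pocketsim.consensus_site import SiteAlignment
        from pocketsim.geometry import RigidTransform

        site_a = PocketSite(None, 0, [rp_of("ASP", 5, (0, 0, 0))])
        site_b = PocketSite(None, 0, [rp_of("LYS", 4, (0, 0, 0))])
        pc_a = Pseudocenter((0, 0, 0), "acceptor", ("A", 1, "", "ASP"))
        pc_b = Pseudocenter((0, 0, 0), "acceptor", ("A", 1, "", "LYS"))
        al = SiteAlignment(RigidTransform.identity(), [(0, 0)], [pc_a],
                           [pc_b], 0.0)
        cons = merge_consensus(site_a, site_b, al)
        assert cons.merged == []
        assert len(cons.preserved) == 2

    def test_matched_same_group_pair_merges(self):
        def rp_of(resnum, resname, tag, pos):
            pos = np.asarray(pos, float)
            return ResiduePoints("A", resnum, "", resname, ChemTag(tag),
                                 pos, pos, pos)

        from pocketsim.consensus_site import SiteAlignment
        from pocketsim.geometry import RigidTransform

        site_a = PocketSite(None, 0, [rp_of(1, "ASP", 5, (0, 0, 0)),
                                      rp_of(2, "ALA", 1, (8, 0, 0))])
        site_b = PocketSite(None, 0, [rp_of(1, "GLU", 5, (0.2, 0, 0)),
                                      rp_of(2, "SER", 3, (12, 0, 0))])
        pc_a = Pseudocenter((0, 0, 0), "acceptor", ("A", 1, "", "ASP"))
        pc_b = Pseudocenter((0.2, 0, 0), "acceptor", ("A", 1, "", "GLU"))
        al = SiteAlignment(RigidTransform.identity(), [(0, 0)], [pc_a],
                           [pc_b], 0.1)
        cons = merge_consensus(site_a, site_b, al)
        assert len(cons.merged) == 1
        assert cons.merged[0].group == "negative"
        assert len(cons.preserved) == 2

    def test_consensus_writable_as_pdb(self, tmp_path):
        site, site_m, al = self._aligned_pair(seed=2, n=6)
        cons = merge_consensus(site, site_m, al)
        out = tmp_path / "consensus.pdb"
        ps.write_structure(cons.to_structure(), out)
        back = ps.read_structure(out)
        assert len(back.atoms) == len(cons.merged) + len(cons.preserved)
        assert {a.chain for a in back.atoms} <= {"A", "B", "C"}
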
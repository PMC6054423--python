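# pocketsim

Binding-site similarity profiling with dummy probe atoms.

Proteins with unrelated sequences and folds can still present locally
similar binding pockets — the reason a promiscuous ligand binds both a
transporter and an enzyme.  Sequence alignment cannot see this:
pocket-forming residues are scattered along the chain.  `pocketsim`
compares pockets as three-dimensional objects, and — crucially — does
not require knowing where the pocket is: lattices of massless,
hydrogen-sized probe ("dummy") atoms fill a cavity, and every probe
defines a candidate site.  Sweeping all probe pairs of two structures
over a schedule of shell radii produces a similarity profile of the two
cavities, from which similar zones are read off.  It is aimed at
structural bioinformaticians studying binding-site convergence,
polypharmacology, or off-target effects.

## The statistic

A site (pattern) around a probe point *p* at radius *r* is the set of
residues with at least one heavy atom within *r* of *p* (or, for
ligand-defined sites, within a cutoff of any ligand atom).  Each residue
is reduced to three points — Cα, Cβ, and the unweighted side-chain
heavy-atom centroid — and one chemical tag *t* ∈ {1..5}
(aliphatic-hydrophobic, aromatic, polar-uncharged, positive, negative).

For every unordered pair of distinct residues, the three same-kind
inter-residue distances (Cα–Cα, Cβ–Cβ, centroid–centroid) are stored,
ascending-sorted, in bins keyed by point kind and unordered tag pair —
3 × 15 = 45 possible bins; a site of *n* residues stores
3·C(*n*, 2) distances.  Matching bins of two sites are aligned with a
greedy two-pointer sweep that counts pairs of distances agreeing within
a tolerance τ = 0.5 Å (provably the maximum monotone matching).  The
similarity is

    PMScore = matches / max(N_A, N_B)  ∈ [0, 1]

where N_A, N_B are the total distance counts of the two sites; a score
of at least 0.5 is read as "similar".  Sweeping all probe pairs of two
grids over radii r = 3, 3.5, …, 10 Å and averaging per pair gives the
similarity profile matrix; a finer sweep (3 → 10 Å in 0.1 Å steps, 70
shells) scores conformational ensembles frame-by-frame against a
reference ligand site.

Two similar sites can also be merged into a **consensus binding site**:
residues are summarised by typed pseudocenters (H-bond donor, acceptor,
mixed donor/acceptor, aliphatic, aromatic), the rigid superposition
maximising type-matched centers within ε is found by exhaustive triplet
seeding plus verified greedy growth, and matched residues of the same
physicochemical group collapse to their midpoint while all others are
preserved.

## Worked example

```python
import numpy as np
import pocketsim as ps
from pocketsim import synthetic_data as sd

# a 20-residue synthetic pocket, and a 0.5 Å noise-perturbed copy
spec = sd.PocketSpec(n_residues=20, radius_range=(2.0, 6.0), seed=42)
pocket = sd.make_toy_pocket(spec)
noisy = sd.perturb(pocket, sigma=0.5, seed=7)

site = ps.extract_site(pocket, probe=(0.0, 0.0, 0.0), radius=8.0)
print("residues in 8 A pattern:", len(site))
ds = ps.distance_sets(site)
print("stored distances:", ds.n_total, "bins used:", len(ds.bins))

result = ps.pm_score(site, ps.extract_site(noisy, (0.0, 0.0, 0.0), 8.0))
print(f"PMScore vs 0.5 A-perturbed copy: {result.score:.3f} "
      f"({result.matches}/{max(result.n_a, result.n_b)})")

grid = ps.make_grid(center=(0, 0, 0), dims=(1.5, 1.5, 1.5), counts=(2, 2, 2))
sched = ps.radius_schedule(3, 10, 0.5, "inclusive")
prof = ps.profile(pocket, grid, noisy, grid, sched)
zones = ps.classify(prof, threshold=0.5)
print("similar probe pairs at 0.5:", len(zones.similar_pairs), "of", 64)
```

prints

```
residues in 8 A pattern: 20
stored distances: 570 bins used: 42
PMScore vs 0.5 A-perturbed copy: 0.826 (471/570)
similar probe pairs at 0.5: 64 of 64
```

The pattern's 570 distances (3·C(20,2)) land in 42 of the 45 bins; half
an ångström of coordinate noise still matches 471 of them within the
0.5 Å tolerance (score 0.83), and every one of the 8 × 8 probe pairs of
the two grids stays above the 0.5 similarity threshold — the perturbed
pocket is recognised as the same cavity.

The same operations are available from a shell, e.g.

```sh
pocketsim grid --center 0,0,0 --dims 15,15,60 --counts 4,4,12 --out-json grid.json
pocketsim profile --pdb-a a.pdb --grid-a grid.json --pdb-b b.pdb --grid-b grid.json \
    --radii 3:10:0.5:inclusive --out profile.tsv
pocketsim consensus --pdb-a a.pdb --pdb-b b.pdb --ligand MTA --cutoff 4 --out consensus.pdb
```

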
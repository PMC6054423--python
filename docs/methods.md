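# Methods

## Site representation

A binding-site pattern is defined purely geometrically: the residues
with at least one heavy atom within a cutoff radius of an origin — a
probe point on a lattice, or any atom of a bound ligand.  Hydrogens are
parsed but never enter geometry; alternate locations are resolved to
the highest-occupancy conformer (ties: alphabetically first altloc);
HETATM residues are never pattern members — they act only as ligands or
probes.

Each residue contributes three labelled points:

* **Cα** — the backbone anchor;
* **Cβ** — side-chain direction; when absent (glycine, truncated side
  chains) the Cα position is substituted rather than a virtual Cβ
  constructed, keeping every distance well defined at the price of a
  degenerate Cα/Cβ pair for those residues;
* **centroid** — the unweighted mean of all side-chain heavy atoms
  (everything beyond Cα except backbone N, C, O, OXT), again falling
  back to Cα for glycine.  Unweighted, because crystal structures
  typically lack hydrogens and occupancy weighting would couple the
  geometry to refinement artefacts.

Each residue also carries a chemical tag 1–5.  The default partition of
the 20 standard residues is

| tag | class | residues |
|---|---|---|
| 1 | aliphatic-hydrophobic | ALA VAL LEU ILE MET CYS PRO GLY |
| 2 | aromatic | PHE TRP TYR |
| 3 | polar-uncharged | SER THR ASN GLN |
| 4 | positive | LYS ARG HIS |
| 5 | negative | ASP GLU |

The literature does not fix a single canonical 5-group partition
(histidine in particular is assignable to 2, 3 or 4); this table places
it with the positives and is overridable through the config file
(`tag_table:`), so users can reproduce alternative groupings.  Unknown
residue names are skipped with a warning by default; a strict mode
raises instead.

## The PMScore

For every unordered pair of *distinct* residues in a pattern, three
same-kind distances (Cα–Cα, Cβ–Cβ, centroid–centroid) are binned by
point kind × unordered tag pair (45 possible bins) and sorted
ascending; a pattern of n residues stores exactly 3·C(n, 2) distances.
Cross-kind pairs (e.g. Cα–Cβ) are not stored, and intra-residue
distances do not exist under same-kind pairing — both deliberate
readings of an ambiguous convention, kept fixed for reproducibility.

Corresponding bins of two patterns are aligned by a greedy two-pointer
sweep: distances within τ (default 0.5 Å, motivated by the natural
thermal motion of protein structures) match and both pointers advance;
otherwise the pointer at the smaller value advances; equal values are a
match.  For ascending-sorted lists this greedy rule attains the maximum
monotone matching — the test suite verifies it against an exhaustive
oracle on random instances rather than trusting the exchange argument.

    PMScore = Σ_bins matches / max(N_A, N_B)

The max denominator penalises size mismatch (a sub-pocket of a much
larger pocket is *not* the same site); `denominator="min"` is available
where containment is the question.  When both patterns are empty the
score is defined as 0 and flagged — profiling sweeps legitimately probe
bulk solvent and must not raise.

Consequences worth knowing:

* self-comparison of any non-empty pattern scores exactly 1.0;
* the score is symmetric and invariant under rigid motion of either
  structure (numerically: < 1e−9 drift);
* in a radius sweep, radii at which a pattern is empty contribute 0 to
  the per-pair mean rather than being dropped — dropping them would
  inflate means at small radii.  A "unit self-similarity diagonal"
  therefore holds exactly when every shell of the schedule is
  populated, which the tests assert explicitly as a precondition.

## Probe grids

Probes fill a rectangular box as a cell-centered lattice: along an axis
of length L with n points, coordinates are center − L/2 + L·(k+0.5)/n.
Cell-centering yields exactly nx·ny·nz probes strictly inside the box
for any counts (a corner-inclusive option exists).  The reference
configuration is a 15 × 15 × 60 Å box at (4, 4, 12) — 192 probes — for
transporter-scale cavities; enzyme-scale boxes are 15 × 15 × 30 Å.
Probe ids are 1-based, ascending along the box's long axis (then y,
then x), so id order matches the axis-sorted order used to lay out
profile matrices.

`prune_grid` keeps a probe only if its nearest protein heavy atom lies
in [min_clash, max_shell] (defaults 2.0 and 8.0 Å): closer means inside
an atom, farther means bulk solvent.  Cavity-confined probe sets (such
as a 118-probe enzyme cavity) are in general *not* lattice products;
they arise from pruning and their exact count depends on the structure,
so no attempt is made to reproduce any particular pruned count.
Pruning preserves probe ids and is idempotent.

## Radius schedules and profiles

Two sweep conventions exist because both endpoints-included and
endpoint-excluded counts are in active use:

* coarse: 3 → 10 Å, step 0.5, **inclusive** → 15 radii;
* fine: 3 → 10 Å, step 0.1, **half-open** (stop excluded) → 70 radii.

A profile evaluates PMScore for every (probe_a, probe_b, radius) triple
— |A|·|B|·|radii| evaluations, e.g. 192·192·15 = 552,960, or
118·192·15 = 339,840 for an enzyme-vs-transporter run; the planner
(`count_comparisons`) reports the number without evaluating.  Per-pair
means over the schedule form the profile matrix, rows/columns sorted
along each grid's long axis (configurable).  Probe-pair computations
are independent; results are bit-identical regardless of evaluation
order.  Pairs with mean ≥ threshold (default 0.5, boundary included)
are the similar zones; a probe is "similar" if it appears in at least
one such pair (an `aggregate="mean"` option instead requires the
probe's mean over all partners to reach the threshold — the pair-based
reading is the default because zone maps are sparse and a probe's mean
over mostly-unrelated partners is almost never informative).

## Ensemble scoring

A conformational ensemble (multi-model PDB) is scored frame-by-frame
against a reference ligand-bound site.  The ligand cutoff (4 Å by
convention for defining sites; some analyses use 6 Å — it is an
explicit argument, never silently defaulted differently) fixes the
candidate residues of each site; each radius of the fine schedule then
keeps the candidates with an atom within that distance of the *ligand
centroid*, mirroring the growing shells of the dummy-atom sweep; the
frame's score is the mean over shells.  Shells empty on **both** sides
carry no information and are excluded from this mean — without this, a
frame identical to the reference would score below 1 purely because
small shells around the ligand centroid are empty, which would make the
per-frame score depend on where the schedule starts rather than on
conformation.  Frames missing the ligand are flagged and scored NaN;
the run continues.  No frame subsampling is performed: frames are
scored as given.

## Consensus binding sites

Residues are summarised by typed pseudocenters: hydroxyl oxygens as
mixed donor/acceptor (SER, THR, TYR), carboxylate midpoints as acceptor
(ASP, GLU), amide midpoints as donor/acceptor (ASN, GLN), LYS NZ and
the ARG NH midpoint as donor, ring centroids as aromatic (PHE, TYR,
TRP, HIS, plus TRP NE1 / HIS NE2 as donor), and the side-chain centroid
as aliphatic for the hydrophobics.  The placement table is a documented
stand-in for conventions that vary between tools; it is overridable,
and atoms missing from a residue fall back to the side-chain centroid.

Alignment maximises type-matched pseudocenters under a rigid motion:

1. enumerate all type-compatible triplet correspondences whose three
   internal distances agree within **2ε** — the widest discrepancy
   consistent with every point matching within ε after some rigid
   motion (filtering at ε, though intuitive, discards valid seeds);
2. solve the least-squares (Kabsch/SVD, reflection-corrected)
   superposition of each seed and keep it only if all three pairs land
   within ε;
3. grow greedily with verification: repeatedly add the unmatched
   type-compatible pair with the smallest residual, refit on the
   enlarged set, and keep the addition only if *every* matched pair
   still lies within ε under the refit;
4. return the alignment with the most matches, ties broken by lower
   RMSD.

This exhaustive seeding replaces geometric-hashing indexing: at
desk-scale sites (≤ ~40 residues, ≤ ~60 pseudocenters) the O(n³m³)
seed enumeration is tractable and the whole procedure can be verified
against brute-force search over all correspondence subsets — which the
test suite does on 6-center sites.  Hash-based indexing would only
change speed, not results.

Merging: residues merge into one consensus residue (at the Cα midpoint
after superposition) when they have a matched pseudocenter pair, belong
to the same physicochemical group — non-polar (tags 1, 2), polar (3),
positive (4), negative (5) — and their Cα's lie within `merge_eps`
(default 1.5 Å) after the transform; the Cα gate replaces the manual
curation step such workflows traditionally need with a deterministic
rule.  Everything unmatched is preserved with provenance; each input
residue ends up in exactly one merged or preserved entry.  The output
PDB uses chain C for merged residues and chains A/B for preserved ones.

## Synthetic data

The generator produces pockets, not proteins: 5–40 residues placed
uniformly in a spherical shell (default 4–12 Å; denser fixtures use
2–6 Å) with Cα separations ≥ 3.5 Å by rejection sampling, residue names
drawn group-first from a 5-vector of tag probabilities, Cβ at 1.53 Å in
a random direction, and remaining side-chain atoms scattered around a
point 2–2.8 Å out along the Cβ direction — keeping side-chain centroids
1.5–4 Å from the Cα, the range observed across real rotamers.  All
randomness flows through numpy's seeded PCG64 generator; identical
seeds give identical structures on any platform.

Controlled corruptions: `perturb` adds i.i.d. Gaussian noise per
coordinate (σ = 0 is the exact identity); `retag` renames an exact
round(fraction·n) of residues into a target group without moving
Cα/Cβ; `make_planted_pair` embeds one shared pocket (rigidly moved)
in two structures plus tag-disjoint decoy pockets ≥ 20 Å away;
`make_ensemble` interpolates from the reference (mixing 0) to a
perturbed-and-retagged pocket (mixing 1, noise scale 2 Å — enough to
destroy most distance matches) with the ligand held fixed.

What passing on synthetic data does **not** show: the generator has no
backbone connectivity, no rotamer correlations, no secondary structure,
no solvent, and its decoys are chemically disjoint by construction —
so recovery rates here bound the method's behaviour under its own
assumptions, not its discrimination on real, chemically homogeneous
binding sites.  Conformational ensembles are noise interpolations, not
dynamics.

## Numerical choices and problem sizes

* Distance-bin alignment tolerance τ = 0.5 Å; similarity threshold 0.5
  (boundary inclusive); alignment ε = 1.5 Å; merge_eps = 1.5 Å.
* Schedule lattices are built with a 1e−9 slack so that binary floating
  point cannot drop an endpoint (3 → 10 by 0.5 has exactly 15 radii).
* Kabsch uses SVD with explicit reflection correction (det = +1
  always); degenerate (collinear) triplets still yield a valid
  least-squares transform.
* Grid/probe ties in axis sorting break by probe id, making matrix
  layouts fully deterministic.
* Test and acceptance runs use reduced problem sizes — pockets of 8–25
  residues, grids of 1–8 probes — chosen so the full suite exercises
  every code path in seconds while the planner checks full-scale sweep
  sizes (552,960 / 339,840) by exact integer arithmetic.

## Known limitations

* Residue-level comparison only; two sites differing by atom-level
  rearrangements within the same residues score 1.
* The PMScore has no null model here; a score's statistical
  significance is out of scope.
* Only pairwise consensus construction is implemented; multi-site
  consensus reduces to iterated pairwise merges and is not provided.
* mmCIF, assemblies/symmetry expansion and hydrogen placement are not
  supported; input is PDB-format text.
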
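# msper

Mutation site prediction for enhancing the regioselectivity of enzyme
substrate reaction sites.

Enzymes with low regioselectivity — cytochrome P450s are the canonical
case — convert one substrate into several products because the substrate
can dock in the active site in several orientations, each presenting a
different reaction-site atom to the catalytic center. `msper` takes
conformational ensembles of an enzyme–substrate complex (from enhanced
MD sampling, plain MD, docking, or a set of crystal/NMR poses) and
produces a ranked list of candidate substitution residues expected to
destabilize the docking poses that lead to byproducts while leaving the
target-product poses intact. It is a purely geometric, conformational
analysis: no force field, no quantum chemistry, no choice of which amino
acid to substitute in — only *where* to mutate.

## Method

Each frame of the ensemble is assigned to exactly one **docking-pose
group** or none: the distance from the enzyme's active-site atom (e.g.
the heme-bound oxygen of a P450) to each declared substrate reaction-site
hydrogen is computed, and the frame belongs to the nearest hydrogen's
group when that distance is strictly below

    r_active_site + r_H + tolerance   (1.48 + 1.00 + 1.00 = 3.48 Å by default)

Docked frames are split into the **target-product group** (poses at the
hydrogens of the desired reaction site) and the **byproduct group** (all
other docked poses). For every enzyme heavy atom, the weighted contact
rate within a group is

    C = Σᵢ cᵢ wᵢ / Σᵢ wᵢ

where cᵢ = 1 when the atom lies within vdW-sum + tolerance of the
nearest substrate heavy atom in frame i, and wᵢ is the frame weight
(reweighting factor of an enhanced-sampling run; 1 otherwise). The
per-atom difference map

    D = C_bp − C_tp

highlights atoms that touch the substrate specifically in byproduct
poses, and the substitution candidate score of a residue is

    S_scr = Σ_{atoms in residue} D_atom

Residues are ranked by descending S_scr per replicate (active-site
residues removed first), and the **ranking average** across independent
replicate simulations orders the final candidate list. A convergence
report (top-k overlap and Spearman rank correlation between replicates)
indicates whether sampling sufficed — the recommended check is whether
the top-ranked residues match between replicates, not whether the scores
do.

## Worked example

The package ships a generator for fully synthetic test systems: a toy
pocket of pseudo-residues around an active-site oxygen, with a limonene
or p-cymene substrate and *planted* contact asymmetries whose correct
ranking is known by construction. Residues A2/A7/A8/A12 contact the
substrate only in byproduct poses (they should rank top), A4/A5/A9 only
in target poses (they should rank bottom):

```sh
msper simulate-fixture --out demo --seed 42 --frames-per-group 100 --noise 0.2
msper run --config demo/config.toml --out demo_out
```

prints

```
replicate 1: 300 frames, docked weight 300 of 300, groups {'H2': 100, 'H5a': 5, 'H5b': 11, 'H6b': 100, 'H9b': 84}
replicate 2: 300 frames, docked weight 300 of 300, groups {'H2': 100, 'H5a': 7, 'H5b': 4, 'H6b': 100, 'H9b': 89}
convergence: top-k overlap {3: 1.0, 5: 1.0}, spearman 1.0000
```

(H6b is the target site here; a few H9b poses jitter into the
neighbouring H5a/H5b groups at 0.2 Å noise, which is exactly the kind of
variation the replicate comparison is meant to absorb.) The aggregated
ranking `demo_out/aggregated.tsv` begins

```
chain  resnum  icode  residue_name  rank_rep1  rank_rep2  ranking_average
A      7              PKT           1          1          1
A      12             PKT           2          2          2
A      2              PKT           3          3          3
A      8              PKT           4          4          4
```

— the four planted byproduct-contact residues, ordered by their heavy-atom
counts (their zero-noise scores are S_scr = 5, 4, 3, 2), with the three
target-contact residues at the bottom with negative scores. Per-replicate
tables, per-atom contact maps (`contacts_rep*.tsv`), a difference-map PDB
with D in the B-factor column for visualization (`diffmap_rep*.pdb`), the
convergence report and a run manifest land in the same directory.

Real systems use the same interface: a multi-model PDB (or a directory of
per-frame PDBs) per replicate, an optional one-weight-per-frame text
file, and a TOML config naming the substrate residue, the active-site
atom, the reaction-site hydrogens and the target subset.

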
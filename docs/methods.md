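# Methods

## Model and assumptions

`msper` treats a conformational ensemble as an exchangeable weighted set
of frames: no kinetics, no time ordering, no persistence of contacts
across frames. All statements are geometric. The assumptions inherited
from the underlying method are:

* the enzyme's catalytic center can be represented by a single atom
  (for P450s, the oxygen bound to the heme iron), not a centroid;
* a frame is a productive docking pose for a reaction site exactly when
  that site's hydrogen is the nearest declared hydrogen to the
  active-site atom *and* lies within the radius-sum-plus-tolerance
  threshold (strict inequality — the boundary is out, following the
  "less than" rule used throughout);
* residues whose heavy atoms contact the substrate preferentially in
  byproduct poses stabilize those poses, so substituting them should
  suppress byproduct formation while sparing the target pose.

Frame weights are consumed as opaque non-negative reals (reweighting
factors of an enhanced-sampling run, or all ones). They are never
normalised at I/O time; the contact rate C is a ratio, so every derived
quantity is invariant under a global rescaling of the weights.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `active_site_radius` | 1.48 | Å | vdW radius of the active-site oxygen in the pose threshold |
| `reactive_hydrogen_radius` | 1.00 | Å | vdW radius of a reaction-site hydrogen |
| `pose_tolerance` | 1.00 | Å | slack added to the radius sum for pose assignment (default threshold 3.48 Å) |
| `contact_tolerance` | 1.00 | Å | slack added to the heavy-atom vdW sum for the contact indicator |
| heavy-atom vdW radii | Bondi set | Å | C 1.70, N 1.55, O 1.52, S 1.80, ... |
| `include_cofactor` | false | — | whether cofactor (heme) heavy atoms are scored |
| `top_k` | 5, 10 | — | list depths for the replicate-overlap diagnostic |

The heavy-atom radii are the Bondi (1964) values, with transition metals
(absent from Bondi) taken from Batsanov (2001); any entry can be
overridden by a two-column text file, including the two pose-threshold
radii via the `ACTIVE_SITE` / `REACTIVE_HYDROGEN` keys. The pose radii
are kept separate from the element table because the pose definition
pins them independently of whichever set is used for heavy atoms.

## Design choices

* **Scored atom universe.** Contact rates are computed for enzyme-role
  heavy atoms only. Cofactor atoms are excluded by default — the method
  ranks mutable protein residues, and heme atoms cannot be substituted —
  but can be included for map inspection via `include_cofactor`.
* **Contact geometry.** Both sides of the contact test are heavy atoms;
  substrate hydrogens enter only the pose assignment. The threshold for
  an enzyme atom is built from the radius of its *nearest* substrate
  heavy atom, mirroring the pose rule's nearest-site convention.
* **Exclusive pose groups.** Each frame carries exactly one label. Ties
  between hydrogens at identical distances break toward the smaller atom
  index; with real-valued coordinates this is a measure-zero event, and
  the rule exists only to make the pipeline deterministic.
* **Ordinal ranks.** Ranks are consecutive integers (ordinal, not
  fractional/competition), with exact score ties broken by residue
  number ascending, then chain id. Replicate aggregation is the
  arithmetic mean of ordinal ranks; equal averages again order by
  residue number. All enzyme residues are ranked — residues with no
  scored contacts share the zero-score tail — so candidate reduction is
  relative to the full sequence, not to a contact-bearing subset.
* **Active-site exclusion before ranking.** Excluded residues (e.g. the
  cysteine anchoring the heme) are removed before ranks are assigned, so
  ranks 1..n always run over eligible residues. Exclusions come from an
  explicit config list and/or an `active_site_anchor` declaration.
* **Degenerate partitions are errors.** An empty target or byproduct
  group makes D undefined; the pipeline aborts with a
  replicate-attributed error rather than emitting half a result.
* **CLI precedence.** Command-line `--replicate`/`--weights` flags
  override the config's input section when given; this is the
  conventional precedence and avoids a config-wins inversion flag.

## Numerical notes

* Contact indicators are computed vectorised over frame chunks sized to
  ~5·10⁶ distance pairs; the test suite proves them bit-exact against a
  naive all-pairs oracle, so no approximation is introduced by the
  chunking.
* The weighted rate Σcᵢwᵢ/Σwᵢ is clamped to [0,1]: summation-order
  roundoff can otherwise overshoot 1 by one ulp.
* Distances use double precision throughout; PDB round-trips are exact
  to the format's 10⁻³ Å coordinate precision.
* The difference-map PDB export writes D into the B-factor column
  (`%6.2f`, clipped to [−9.99, 99.99]); unscored atoms get 0.00.

## What the synthetic generator emulates — and what it does not

The planted-signal generator builds a toy pocket: 8–20 pseudo-residues
of 1–5 carbon atoms on a 12 Å ring around an active-site oxygen, plus an
idealized limonene or p-cymene topology (10 C + 16 H and 10 C + 14 H
respectively, hydrogens labelled per carbon: H6b, H3a, H9b, ...). Per
frame the substrate is rigidly oriented so the chosen group's C–H bond
points at the oxygen at 2.4 Å, with a random azimuthal spin and optional
isotropic Gaussian noise on every atom; "planted" residues are placed in
substrate contact (3.4 Å from an anchor carbon, 1 Å inside the contact
threshold) only in byproduct frames, "anti" residues only in target
frames. At zero noise this makes the expected scores exact integers
(±heavy-atom count) and the full expected ranking known in closed form.
Generation-time checks verify the intended hydrogen really is the strict
nearest reaction site at the canonical placement and refuse inconsistent
requests.

The generator reproduces the *logical* structure of the problem —
pose-dependent contacts, replicate variability, weight handling — but
none of its physics: there is no excluded volume, no induced fit, no
correlation between frames, and contact asymmetries are binary rather
than graded. Passing the recovery tests therefore demonstrates that the
scoring and ranking machinery is correct, not that the method's
biological premise holds for any particular enzyme.

Default fixture conditions: 200 frames per pose group, 0.2 Å noise, one
target group (H6b) and two byproduct groups (H9b, H2), four planted and
three anti residues — small enough that every contact computation can be
cross-checked by the brute-force oracle in well under a second. Replicas
of one experiment share the residue layout (drawn from a separate layout
seed) while frames derive from the per-replicate seed.

## Limitations

* Pose assignment depends on declared reaction-site hydrogens only; a
  substrate whose reactive positions are not hydrogens would need a
  generalized site declaration.
* Binary-format trajectories (DCD/XTC) are not read; convert to
  multi-model PDB or per-frame PDB directories first.
* The score is sensitive to sampling quality by design; with poorly
  converged ensembles the replicate convergence report is the only
  guard, and it requires at least two independent replicates.
* Insertion codes are carried through residue identity but fixture
  systems never exercise them with non-empty values.
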
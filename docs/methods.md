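# Methods

This note documents the models and procedures implemented in
`senescreen`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical conventions.

## Candidate triage

**Membership frequency.** Identifiers are canonicalized by stripping
whitespace and uppercasing; they are otherwise opaque symbols — no
alias or ortholog mapping is attempted, since that would silently pull
in an external database. A Co-IP hit list of size *n* is crossed with
*m* named annotation sets; a protein's frequency is the number of sets
containing it, and the frequency filter keeps proteins with frequency
≥ *k* (default *k* = 3, configurable). The comparison is inclusive
("three or more"); a strict "more than *k*" policy is obtained by
passing *k* + 1.

**Expression filter.** A protein responds in a stimulus when
logRatio > `lr_min` (default 0) and qValue ≤ `q_max` (default 0.05).
The default mode requires a response in *every* stimulus present in the
table ("all"), reflecting the use case of candidates up-regulated under
each of several independent senescence-inducing stimuli; an "any" mode
is provided. Proteins absent from the table fail the filter with a
logged warning rather than erroring, since hit lists routinely outrun
expression coverage.

**Enrichment.** Per term, the one-sided Fisher exact p-value toward
over-representation is computed as the hypergeometric upper tail
P[X ≥ a] with population = background, successes = background∩term,
draws = list. Multiple testing uses Benjamini–Hochberg step-up FDR over
all tested terms; results are ordered by FDR and truncated to the top
15 by default. Terms with no background overlap are skipped and logged;
an empty off-diagonal yields an infinite odds ratio, reported as `inf`
rather than masked. Ties in all output orderings are broken
lexicographically so output files are byte-reproducible.

**Focal-term subnetwork.** The neighbourhood of a focal term in a term
association network is the set of nodes within graph distance ≤ depth
(default 1) plus induced edges, computed with `networkx.ego_graph`.

## Pose-ensemble post-processing

**RMSD convention.** For rigid docking ensembles the informative
quantity is the ligand displacement after removing the receptor's
frame: pose *j* is superposed onto pose *i* over receptor-chain CA
atoms (Kabsch least squares, proper rotation enforced via the SVD sign
correction), and RMSD is measured over ligand-chain CA atoms. Both
selections are configurable (e.g. whole-complex CA). The first chain in
the file is taken as the receptor by convention.

**Clustering.** The default is single-linkage clustering cut at the
RMSD cutoff — equivalently, connected components of the graph joining
pose pairs with RMSD ≤ cutoff (default 5 Å). It is parameter-free,
deterministic, and gives clean "most populated cluster" semantics. A
quality-threshold variant (`method="qt"`) repeatedly extracts the pose
with the most cutoff-neighbours; it is stricter on elongated clusters.
Cluster ids are renumbered by population (descending), ties by smallest
member index.

**Centroid.** The representative model is the medoid of the most
populated cluster: the member minimizing mean RMSD to its co-members.
(A coordinate-average "centroid" would not be a real pose.) A
population tie between clusters is broken toward the cluster holding
the best (lowest) interface score I_sc, then the smallest member index;
the medoid tie rule is the same.

**Ramachandran screen.** φ/ψ are the standard backbone dihedrals
(C(i−1)–N–CA–C and N–CA–C–N(i+1)); chain termini and residues with
missing backbone atoms are classed `undefined` and excluded from the
summary fractions. Classification uses coarse rectangular regions —
favored: φ∈[−180°,−30°], ψ∈[−75°,−5°] (helical) or φ∈[−180°,−45°],
ψ∈[90°,180°] (sheet); allowed: a 20° margin around each favored
rectangle (ψ wraps across ±180°); otherwise outlier, except that
glycine and proline are floored at `allowed` since their basins are not
modelled. The region table is an argument, so a stricter reference map
can be dropped in.

**PDB dialect.** Fixed-width PDB v3.3; only ATOM/HETATM, MODEL/ENDMDL,
TER and END records are interpreted. Altlocs other than blank/'A' are
dropped with a warning; insertion codes are rejected with a clear
error; a model whose atom records deviate from model 1 raises a format
error naming that model. Coordinates round-trip at the format's
10⁻³ Å precision.

## Interface dynamics

**Contacts.** Two residues on opposite chains are in contact in a frame
when the minimum distance between their scoped atoms is ≤ the cutoff
(default 5 Å). The default scope is heavy atoms (hydrogens excluded),
the common convention for "non-bonded interaction" cutoffs; `all` and
`ca` scopes are available. Detection queries a k-d tree at the cutoff
scale, so cost tracks the number of nearby pairs; the test suite checks
exact set equality against an O(n²) all-pairs loop on every frame it
touches. Distances are computed without periodic-boundary imaging:
inputs are assumed to be whole, imaged solute complexes.

**Frequencies and consensus.** A pair's frequency is
frames-in-contact / total frames, exactly; the reported mean minimum
distance averages over in-contact frames only (frames out of contact
have no bounded minimum under the tree query, and averaging them in
would mix regimes). A residue is a consensus interface residue when it
participates in ≥ 1 inter-chain pair with frequency ≥ `freq_min` in
*every* replica; `freq_min` defaults to 0.5 ("present in the majority
of frames in every replica") and is configurable, since no universal
threshold exists. Consensus is monotone in `freq_min` by construction.

**Classification.** Salt bridge: side-chain charged-group nitrogen
(LYS NZ; ARG NH1/NH2/NE; HIS ND1/NE2 behind the `his_charged` flag,
default off since histidine protonation is unknowable from coordinates)
within 4.0 Å of a carboxylate oxygen (ASP OD1/OD2, GLU OE1/OE2).
Hydrogen bond: any N/O–N/O pair within 3.5 Å; when the structure
carries hydrogens a D–H···A angle ≥ 120° is additionally required,
otherwise the criterion degrades gracefully to distance-only (the
common hydrogen-free PDB case) so behaviour is deterministic across
input dialects. The pair label is the criterion with the higher
occupancy, salt bridge taking precedence at a tie; pairs meeting
neither are `other`.

## Imaging quantification

Pearson r is the plain correlation over masked pixels (whole field, a
binary mask, or any labelled cell map; a per-cell variant returns one r
per label — both field-wise and per-cell conventions exist in the
literature, so both are provided). A constant channel raises an error
instead of returning 0. Focus segmentation is a global threshold (fixed
or Otsu) followed by 8-connected component labelling (matching common
ImageJ defaults) and area gating, with intensity-weighted centroids.
Foci are assigned to the cell label at their centroid pixel — a focus
straddling two cells goes entirely to the centroid's cell; background
foci are dropped and logged. The positive-cell percentage thresholds
any per-cell metric at a user cutoff; the underlying stain chemistry
(e.g. SA-βGal) is deliberately not modelled.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *shape* of the study inputs with planted,
independently recountable truth:

* **Triage** — a 305-symbol universe crossed with 6 sets, constructed
  so exactly `n_planted` identifiers (default 22) sit in ≥ k sets and
  all others in fewer; the composite scenario additionally plants 10
  responders whose expression rows pass any filter with q_max < 0.2
  while all other rows are guaranteed to fail it. Set membership is
  random, so the generator does not emulate the correlation structure
  of real annotation databases.
* **Poses** — a rigid ideal-geometry poly-alanine receptor plus a
  ligand chain displaced to lattice-separated cluster centers
  (pairwise ≥ `inter_sep`, default 15 Å) with isotropic Gaussian noise
  (default σ = 0.5 Å); the first pose of each cluster is the exact
  zero-noise center. The generator verifies max-intra < min-inter
  ligand RMSD and regenerates on violation. Default sizes (3 clusters,
  100 poses, 20 residues/chain) keep all-pairs superposition fast while
  exercising every code path.
* **Trajectories** — planted residue pairs toggle between a bound
  geometry (minimum heavy-atom distance 4.0 Å) and an unbound one
  (8.5 Å) on an exact schedule hitting each target frequency to within
  1/n_frames; positional noise is Gaussian truncated at 3σ so no frame
  can cross the 5 Å cutoff for σ ≤ 0.2, keeping frequency recovery
  exact rather than statistical. No force field, solvent, or real
  conformational dynamics is modelled — these trajectories validate
  bookkeeping, not physics.
* **Images** — non-overlapping labelled nuclear disks; foci as Gaussian
  spots (σ = 2 px, amplitude 1000) planted ≥ 12 px apart (comfortably
  above the 4σ separation needed for exact recovery), with each spot's
  half-maximum pixel area recorded at render time; channel B =
  coloc·A + (1−coloc)·(independent blob field), so r = 1 exactly at
  coloc = 1 with zero noise and the channels are independent at
  coloc = 0. No microscope PSF, shot noise model, or background
  gradient is included.

Consequently, green tests demonstrate that every analysis recovers
planted truth under its own assumptions — they do not certify
performance on real annotation databases, force-field trajectories, or
microscope images.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng(seed)`; fixed
seeds give bit-identical outputs, and the end-to-end pipeline writes
byte-identical files across repeated runs. The test suite and the
acceptance script run the scenarios at the sizes quoted above (500-atom
/ 100–200-frame trajectories, 100-pose ensembles, 512×512 images),
which complete in seconds on a single CPU while exercising the same
code paths as larger inputs.

## Known limitations

* No mmCIF, DCD/XTC or compressed-format support; multi-model PDB and
  TIFF/PNG only.
* Insertion codes and altloc variants beyond 'A' are rejected/dropped.
* The Ramachandran regions are deliberately coarse rectangles, not a
  reference density map.
* Hydrogen-bond detection without hydrogens is distance-only and will
  overcount donor–donor N/O pairs.
* Pearson colocalization only; Manders coefficients and Costes
  randomization are out of scope.
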
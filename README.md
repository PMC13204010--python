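# senescreen

Tools for annotating senescence-associated protein–protein interactions
(PPIs), built around the kind of integrative workflow used to go from a
co-immunoprecipitation (Co-IP) hit list to a structurally and
microscopically characterized interaction — e.g. a transmembrane
protease engaging an HSP70-family chaperone at its nucleotide-binding
domain.

The package covers four analysis stages, plus a synthetic-data generator
that produces every input with planted ground truth so the whole
pipeline is testable without any external downloads:

1. **Candidate triage** (`senescreen.triage`) — cross-reference a Co-IP
   hit list with several senescence/ageing annotation gene sets, keep
   proteins present in ≥ *k* sets, then keep those up-regulated
   (logRatio > 0, q ≤ 0.05 by default) under every senescence stimulus
   in an expression table. Term over-representation uses the one-sided
   Fisher exact test — per term, the hypergeometric tail
   P[X ≥ a] for the 2×2 table (list∩term, list∖term, background∩term,
   rest) — with Benjamini–Hochberg FDR control, reported as
   −log₁₀(FDR); a focal-term neighbourhood can be cut out of a term
   association network.
2. **Docked-pose post-processing** (`senescreen.pose_ensemble`) —
   pairwise ligand RMSD after Kabsch superposition on the receptor
   chain, single-linkage cutoff clustering (default 5 Å), medoid
   ("centroid") selection in the most populated cluster with
   interface-score (I_sc) tie-breaks, and a coarse Ramachandran screen.
3. **Interface dynamics** (`senescreen.interface_dynamics`) — backbone
   RMSD series, inter-chain residue contacts at a 5 Å heavy-atom
   cutoff, per-replica contact frequencies, consensus interface
   residues across replicas, residue-pair distance series, residue
   center-of-mass contact maps, and geometric hydrogen-bond /
   salt-bridge classification.
4. **Imaging quantification** (`senescreen.imaging_quant`) — Pearson
   colocalization of two channels (whole-field or per cell), puncta
   segmentation (threshold + 8-connected components + area gates),
   per-cell focus counts and PLA-style signal areas, and the percentage
   of positive cells above a per-cell cutoff (the SA-βGal-style
   readout).

All exchange formats are plain text: identifier lists (TXT), gene sets
(GMT), expression tables (CSV), pose ensembles and trajectories
(multi-model PDB), images and label masks (16-bit TIFF).

## Worked example

Generate the standard synthetic triage scenario (a 305-protein hit
list, six annotation sets, 22 planted multi-set candidates of which 10
respond under three stimuli) and run the triage on it:

```sh
$ senescreen simulate triage --seed 1 --out demo
wrote triage inputs for 305 identifiers to demo
$ senescreen triage --coip demo/coip.txt --sets demo/sets.gmt --k 3 \
      --expr demo/expression.csv --out demo_triage
{"n_input": 305, "n_sets": 6, "k": 3, "n_pass_frequency": 22, "n_pass_expression": 10}
```

The JSON line is the stage summary: of 305 input identifiers, exactly
the 22 planted candidates appear in ≥ 3 of the 6 sets, and exactly the
10 planted responders additionally pass the expression filter —
matching the generator's ground truth (`demo/truth.json`).

The docking stage works the same way:

```sh
$ senescreen simulate poses --seed 1 --out demo_poses   # 50/30/20 planted clusters
wrote 100 poses to demo_poses
$ senescreen poses --pdb demo_poses/poses.pdb --scores demo_poses/scores.csv \
      --cutoff 5.0 --out demo_poses_out
centroid pose 31 of 100; 3 clusters
```

Clustering the 100-pose ensemble at the 5 Å cutoff recovers the three
planted clusters, and the selected representative (pose 31 under this
seed) is the planted zero-noise cluster center of the most populated
cluster. `demo_poses_out/` holds the RMSD matrix, cluster assignments,
the centroid PDB and its Ramachandran report.

Library use mirrors the CLI; see the module docstrings:

```python
from senescreen import synthetic_data as synth
from senescreen import contact_frequency, consensus_residues

truths = synth.gen_replica_trajectories(
    100, shared_pairs=[(32, 401, 0.8)], private_pairs=[[], [], []], seed=1)
tables = [contact_frequency(t.trajectory, "A", "B") for t in truths]
print(consensus_residues(tables, freq_min=0.5).pairs)
```

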
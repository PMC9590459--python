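# enzdesign

A tested, reusable pipeline for data-driven enzyme redesign. Starting from a
multiple sequence alignment of the protein family and a structure model with
bound ligands, it:

1. weights sequences and builds a log-odds conservation profile (PSSM),
   listing non-native residues with positive support at each target position
   (`enzdesign.conservation`);
2. fits a Potts model by regularized pseudolikelihood and scores co-evolving
   position pairs with gauge-fixed Frobenius norms plus the average product
   correction, proposing substitutions favored by the strongest couplings
   (`enzdesign.coevolution`);
3. computes Shrake–Rupley solvent accessibility and classifies residues as
   surface / semi-exposed / buried and active-pocket / distal
   (`enzdesign.structure`);
4. enumerates candidate variants from both evidence streams, clusters them
   with PAM30-derived distances (deterministic average linkage), and selects
   the lowest-scored representative per cluster; variant names are
   hyphenated substitution strings with composing aliases, e.g.
   `L48F-S49A-I61F-L120T-T352K-L356P` then `V1-K352I`
   (`enzdesign.variants`);
5. implements HPLC–MS quantification arithmetic: exact adduct m/z from
   molecular formulas, extracted-ion chromatograms at ppm tolerance,
   trapezoidal peak areas, standard curves, and normalization of product
   yields to percentages (`enzdesign.msquant`).

A synthetic-data module (`enzdesign.synthetic`) generates every input the
pipeline consumes — Gibbs-sampled MSAs with planted couplings and conserved
columns, toy helical structures with a placed ligand atom, and Gaussian-peak
chromatograms — so the whole pipeline is testable offline.

## CLI

```sh
# full design run from a YAML config
enzdesign design run --config config.yaml --out results/

# individual stages
enzdesign coevo fit --alignment family.fasta --out couplings.tsv
enzdesign struct classify --structure model.pdb --ligand LIG --out env.tsv
enzdesign quant run --config quant.yaml
enzdesign synth make --kind msa --seed 1 --out msa.fasta
```

A design config is a flat YAML file:

```yaml
alignment: family.fasta      # FASTA / A3M / Stockholm
structure: model.pdb         # optional; enables burial/pocket annotation
ligand_names: [HEM]
cluster_k: 8
identity_threshold: 0.8
alpha: 1.0                   # PSSM pseudocount weight
surface_min: 0.25
buried_max: 0.05
pocket_cutoff: 6.0
output_dir: out
```

Outputs: `pssm.tsv`, `couplings.tsv`, `environment.tsv`, `candidates.tsv`
(per-variant provenance, burial class, score, cluster, representative flag),
and `report.json` with parameters, neff, convergence diagnostics, and input
content hashes.

A quantification config maps compounds to formulas/adducts and standard-curve
points, with an optional `shared_curve_map` to quantify a product against a
structurally similar standard; it emits a yields-and-percentages table.

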
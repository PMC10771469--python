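# bindsurf

Cluster the known protein–protein interfaces of one protein into its
distinct binding surfaces, and derive products useful for integrative
modelling.

Interfaces (named residue-number sets on a common numbering scheme) are
projected onto a single-chain Cα structure.  A Gaussian kernel over
pairwise Cα distances (width σ = 1.9 Å) turns each interface into a
vector in an inner-product space; the similarity between two interfaces
is the sine of the angle between their vectors (0 = same patch,
1 = non-overlapping patches).  Average-linkage hierarchical clustering
of the sin θ matrix, cut at 0.866 (= sin 60°, inclusive), yields the
binding surfaces.  Downstream products:

- per-residue surface probabilities `P(i, K)` (fraction of cluster
  members containing residue *i*) and PDB files with
  `B = 50·(1 + P)` encoded in the B-factor column;
- recognition entropy `S = ln(N_rec × N_lig)` and a rank-weighted
  docking-quality score over the top-[1, 5, 10, 50, 100] array;
- spatial clustering of flat residue lists by Cα–Cα distance
  (average linkage, 15 Å cutoff);
- ambiguous interaction restraints (HADDOCK-style `.tbl`) for every
  combination of receptor × ligand binding surfaces, keeping residues
  with `P ≥ 0.3`;
- per-surface aggregation of partner annotations from an offline
  partner → term table;
- a deterministic generator of synthetic helical structures with
  planted binding surfaces, so the whole pipeline is testable offline.

No network access anywhere: all inputs are local files.

## CLI

One entry point with subcommands:

```sh
# generate a synthetic fixture: structure + interface file + truth labels
bindsurf fixtures --k 3 --patch-size 8 --replicates 5 --seed 7 --out-dir fixture

# full clustering workflow
bindsurf cluster --pdb fixture/fixture.pdb --interface-file fixture/interfaces.json \
    --out-dir run --sigma 1.9 --linkage average --threshold 0.866 --int-cov-cutoff 0.7

# spatial clustering of a residue list
bindsurf resclust --pdb fixture/fixture.pdb --residue-list 2,3,4,30,31 --cutoff 15

# restraints for every combination of binding surfaces of two runs
bindsurf restraints --rec-run run_receptor --lig-run run_ligand --p-thr 0.3 --out restraints

# partner-annotation aggregation per surface
bindsurf localise --run run --annotations partners.tsv

# recognition entropy / docking quality / correlation
bindsurf metrics --rec-clusters 13 --lig-clusters 4
bindsurf metrics --quality-table qualities.tsv --counts-table counts.tsv
```

A `cluster` run directory contains `manifest.json` (options round-tripped
exactly as parsed), `similarity.txt` (upper-triangle
`name_i name_j sin_theta`), `clusters.txt`, `clusters.json`,
`cluster_probabilities.tsv` and one `probability_cluster_K.pdb` per
surface.

### File formats

- **PDB**: standard fixed-column `ATOM` records; only Cα atoms of one
  chain are used (first altloc wins, first model only, insertion codes
  rejected).
- **Interface file**: JSON object mapping interface name (convention:
  `partner-structure`, e.g. `P01070-1avx`) to an array of integer
  residue numbers, on the same numbering scheme as the structure.
- **Quality table**: TSV `complex  method  Q_top1 Q_top5 Q_top10 Q_top50 Q_top100`
  with qualities in {0, 1, 2, 3}.
- **Annotation table**: TSV `partner_id  term`, one row per label.

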
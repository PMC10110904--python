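# panchol

Comparative pan-proteome analysis for phenotype-defined groups of bacterial
strains — built around the question *which proteins are exclusive to
cholesterol-assimilating probiotic strains?*

Probiotic *Enterococcus faecium* strains differ sharply in whether they
assimilate cholesterol in vitro. Given per-strain proteomes (protein FASTA +
COG annotations) and genomes, `panchol` reconstructs the comparative workflow
that turns that phenotype contrast into candidate proteins:

1. **Ortholog clustering** — all-vs-all Smith–Waterman alignment (BLOSUM62,
   affine gaps), reciprocal best hits (RBH), connected components, paralog
   attachment: proteins are grouped into orthogroups and a presence/absence
   matrix with per-strain copy numbers.
2. **Pan-proteome partition** — each orthogroup is *core* (present in all *n*
   strains), *unique* (exactly one strain) or *accessory* (otherwise), with
   cluster and protein counts, percentages and per-strain strain-specific
   counts.
3. **COG profiles and contrasts** — per-class abundance
   (100 × class count / annotated proteins in scope) per partition or strain
   group, and fold-abundance ratios between groups.
4. **Group-exclusive discovery** — orthogroups present in *every* strain of
   group A and absent from *every* strain of group B: the candidate marker
   proteins of the A phenotype.
5. **Marker screening** — presence calls for a curated gene panel (e.g. *bsh*,
   *dltA*, enterocins) at identity > 85% and ~100% query coverage.
6. **Genome relatedness** — fragment-based average nucleotide identity (ANI),
   divergence = 100 − ANI, and a neighbor-joining dendrogram in Newick form.
7. **Synthetic pangenomes** — a seeded simulator with known core/accessory/
   unique/marker structure and analytic expectations, used to validate every
   stage against ground truth.

## Worked example

```python
from panchol import (PangenomeConfig, generate_pangenome, infer_orthogroups,
                     classify, summarize, group_exclusive)

config = PangenomeConfig(n_core_families=12, n_accessory_families=8,
                         n_unique_per_strain=2, n_group_marker_families=4,
                         substitution_rate=0.02, seed=11)
proteomes, truth = generate_pangenome(config)
orthogroups, matrix, hits = infer_orthogroups(proteomes)
summary = summarize(matrix, classify(matrix))
contrast = group_exclusive(matrix, ["LR13", "WEFA23"], ["T110", "170M39", "SP15"])
```

Running `python examples/01_simulate_and_partition.py` prints:

```
strains: LR13, WEFA23, T110, 170M39, SP15
proteins clustered: 105
orthogroups: 34
  core         12 clusters (35.3%), 64 proteins
  accessory    12 clusters (35.3%), 31 proteins
  unique       10 clusters (29.4%), 10 proteins
ground truth: {'core': 12, 'accessory': 12, 'unique': 10}
per-strain strain-specific proteins: {'LR13': 2, 'WEFA23': 2, 'T110': 2, '170M39': 2, 'SP15': 2}
```

The clustering recovered the simulated family structure exactly: 12 core
families, 8 accessory + 4 group-marker families (both count as accessory —
present in some but not all strains), and 2 private families per strain.
`contrast.count` is 4: exactly the simulated marker families private to the
cholesterol-assimilating pair. The other examples cover the group contrast at
published scale (21 exclusive proteins among 126 orthogroups), COG
fold-abundance (3% vs 0.7% → 4.29-fold), marker screening (seeded markers
recovered at ~95% identity), and ANI/NJ dendrograms.

## Command line

A thin CLI mirrors the library:

```bash
panchol simulate --seed 11 --out-dir sim/            # FASTA + truth.json
panchol cluster --strain LR13:sim/LR13.faa:sim/LR13.cog.tsv ... --out-dir out/
panchol partition --matrix out/presence_matrix.tsv --out summary.json
panchol contrast --matrix out/presence_matrix.tsv \
    --group-a LR13,WEFA23 --group-b T110,170M39,SP15 --out contrast.json
panchol ani --genome LR13:lr13.fna --genome T110:t110.fna --out-dir ani/
panchol tree --divergence ani/divergence.tsv --out tree.nwk
panchol run-all --config run.yaml --out-dir out/     # everything, one config
```

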
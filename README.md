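# panoric

**Positional pan-genome analysis along the oriC→terC replication axis of
circular bacterial chromosomes.**

Bacterial chromosomes are replicated bidirectionally from a single origin
(*oriC*) to a terminus (*terC*). Gene location relative to this axis matters:
origin-proximal genes enjoy a replication-associated dosage advantage, while
terminus-proximal and island regions tend to accumulate horizontally acquired
DNA. `panoric` asks, for a set of related strains, *where along the
replication axis do conserved genes, prophages and genomic islands live?* It
is aimed at comparative genomicists who already have closed genomes, gene
annotations, an orthology table and (optionally) prophage/island calls.

The package provides:

- **Pan-genome classification** from Proteinortho-dialect orthology tables:
  core / soft-core (families in ≥ ⌈0.95·n⌉ strains) / accessory labels, with
  paralog and algebraic-connectivity (≥ 0.9) filters, and the per-gene
  **ortholog score** s ∈ [0, n−1] — the number of *other* strains carrying an
  ortholog.
- **Origin calling** from sequence signals: the detrended cumulative G−C
  disparity curve, DnaA-box density (9-mers TTATCCACA / TGTTTCACG / TGTGGATAT
  at ≤1–2 mismatches) in intergenic regions, local GC minima, and
  *parA/parB* proximity, combined into a weighted composite with an explicit
  "ambiguous" outcome.
- **Positional statistics**: mean ortholog score in circular sliding windows
  of 20 genes regressed on relative oriC distance d ∈ [0, 1]
  (ȳ_w = α + β·d_w, with permutation-based slope significance), cohort-level
  slope QQ/sign analysis, eight-segment ANOVA + Tukey HSD enrichment, and
  phage/GI counts per chromosome third.
- A **synthetic-cohort generator** that plants all of the above structure
  (occupancy mixtures, a linear conservation gradient of chosen slope β,
  replichore-switching GC skew, DnaA boxes, regions with chosen placement)
  with recorded ground truth, so the whole pipeline is testable end to end.

See `docs/methods.md` for the statistical details and assumptions.

## Worked example

Simulate a 6-strain cohort whose conserved genes cluster toward the origin
(β = −5 ortholog-score units from oriC to terC) and run the full pipeline:

```python
from panoric import RunConfig, SimulationConfig, run_pipeline

cfg = RunConfig(
    outdir="example_out",
    seed=5,
    simulate=SimulationConfig(
        n_strains=6, n_families=700, genes_per_strain=400,
        genome_length=800_000, positional_bias_beta=-5.0,
        phage_placement="near_ter", gi_placement="near_ter", seed=5,
    ),
)
manifest = run_pipeline(cfg)
print(manifest["strains"])
print({k: v for k, v in manifest["slope_summary"].items() if k.startswith("n_")})
```

which prints:

```
{'total': 6, 'oric_called': 6, 'oric_ambiguous': 0, 'ambiguous_strains': []}
{'n_strains': 6, 'n_negative': 6, 'n_positive': 0,
 'n_significant_negative': 6, 'n_significant_positive': 0}
```

All six origins were recovered from the planted skew/DnaA signals, and every
strain shows a significantly negative conservation slope, as planted. The
output directory contains the per-family classification, a pan-genome summary
(total, core and soft-core family counts with and without paralog /
connectivity filters), per-strain origin candidate reports, window-fit and
QQ tables, the eight-segment means with ANOVA/Tukey results, per-third
phage/GI counts, and a one-row cohort summary, e.g.:

```
n_strains_total  oriC_called  oriC_ambiguous  significant_negative_slope ...
6                6            0               6
```

The same pipeline runs from the shell:

```bash
panoric all --config run.yaml --seed 5 --outdir example_out
panoric simulate --seed 1 --outdir fixtures     # just write a fixture set
panoric classify --proteinortho fixtures/families.proteinortho.tsv
panoric oric --fasta fixtures/S000.fasta --gff fixtures/S000.gff3
```

For real data, point the config's `inputs:` block at a FASTA directory, a
GFF3 directory, the Proteinortho table and any BED files of
PHASTER/AlienHunter/IslandViewer calls.

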
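# Methods

`panoric` quantifies how gene conservation, prophages and genomic islands are
distributed along the replication axis of circular bacterial chromosomes. This
note documents the models, the numerical choices, and what the synthetic
validation does and does not establish.

## Coordinates and the replication axis

A circular chromosome of length *L* is replicated bidirectionally from a
single origin (*oriC*) to a terminus (*terC*) half a genome away. Every
position *p* is summarised by its circular distance to the origin,
*d(p) = min((p − o) mod L, L − (p − o) mod L)*, normalised by *L/2* so that 0
is *oriC* and 1 is *terC*. Genes are located by the midpoint of their
coordinates; prophage/genomic-island intervals by their interval midpoint.
The two replichores are labelled by whether the shorter arc to *oriC* runs
clockwise (increasing coordinates, "right") or anticlockwise ("left").

## Ortholog score and pan-genome classification

Ortholog families are consumed in the Proteinortho tab-separated dialect.
For a gene of a focal strain, the **ortholog score** is the number of *other*
strains with at least one member in the gene's family, so the maximum over
*n* strains is *n − 1*. Families are labelled **core** when present in every
strain and **soft-core** when present in at least ⌈*f·n*⌉ strains (default
*f* = 0.95; for 109 strains this gives 104 — the ceiling is the only rounding
consistent with that published convention). Paralogous families (two or more
members in one strain) and families below a Proteinortho algebraic
connectivity of 0.9 are flagged so "core, no paralogs, high connectivity"
counts can be reported. Genes present in the annotation but absent from the
orthology table score 0 and are flagged rather than dropped, which keeps
window indexing aligned with the chromosome.

## Origin calling

The caller formalises a curation procedure built on four signals:

1. **Cumulative G−C disparity.** The running sum of (G − C) along one strand
   has extrema at *oriC* and *terC* because of replication-associated
   mutational asymmetry. The cumulative curve is linearly detrended
   (subtracting *x · total/L*) before taking extrema; this makes the extremum
   location exactly equivariant under rotation of the arbitrary linear
   coordinate origin, which the raw cumulative sum is not whenever the
   genome-wide G−C total is nonzero. The relevant extremum type (min vs max)
   is selected as the one closer to the DnaA-box-richest candidate, because
   assembly orientation is arbitrary. A curve is called **flat** when its
   detrended range does not exceed `flatness_factor` (default 5) times the
   Brownian-bridge scale σ√L expected from an unskewed sequence of the same
   composition; flat curves force an ambiguous call.
2. **DnaA boxes.** All circular positions on both strands within Hamming
   distance ≤ 1 (fallback ≤ 2 when no region reaches the minimum box count,
   mirroring the two-pass search practice) of the 9-mers TTATCCACA, TGTTTCACG
   or TGTGGATAT. `N` bases count as mismatches.
3. **Local GC content.** GC fraction in circular windows (default 1 kb every
   100 bp); origins sit in locally GC-poor intergenic DNA.
4. **parA/parB proximity.** Chromosome-partitioning genes identified by name;
   only *parA* is required (some strains lack an annotated *parB*). When both
   are absent the criterion is dropped and the remaining weights renormalised.

Candidates are the intergenic regions (circular complement of merged gene
intervals) containing at least `min_boxes` (default 3) hits. Each is scored
by a weighted sum of min–max/ratio-normalised criteria with default weights
0.40 (boxes), 0.30 (disparity distance), 0.15 (local GC), 0.15 (parAB);
the source procedure gives criteria but no weights, so these are this
package's choice and all are configurable. The top candidate is **called**
unless the runner-up's composite is within 10% of it, the curve is flat, or
no region reached the box threshold — then every candidate is **ambiguous**
and the strain is excluded from positional statistics (it still counts in the
pan-genome tallies).

## Sliding-window conservation gradient

Per strain, the mean ortholog score is computed in circular sliding windows
of 20 genes advancing by 1 gene, each window located by the normalised
distance of its middle gene. An ordinary least-squares line (and a quadratic,
for comparison by AIC; the quadratic is preferred only when its AIC is lower
by more than 2) is fitted to mean score vs distance. The slope has the units
"ortholog-score change from *oriC* to *terC*".

Because step-1 windows overlap, neighbouring window means are strongly
autocorrelated and the naive OLS p-value for the slope is anti-conservative.
Significance is therefore assessed by a **gene-level permutation test**:
under the null of no positional structure the scores are exchangeable across
gene positions, so permuting scores and recomputing the window-mean slope
(one dot product per permutation; default 999) yields an exact reference
distribution. The OLS p-value is retained in the output as a descriptive
quantity only.

Across a cohort, slopes are summarised by sign counts, significance counts at
α = 0.05 (per-strain, no multiple-testing correction — the per-strain calls
are reported raw), and a QQ comparison against a normal distribution fitted
to the observed slopes (Blom plotting positions; a conservative
Kolmogorov–Smirnov band at the 5% level flags departure from normality).

## Segment and thirds analyses

For chromosome-level contrasts each chromosome is cut into eight equal
segments. Segment 1 is **centred** on *oriC* (boundaries at *o ± L/16*) with
numbering proceeding clockwise; a convention with segment 1 starting exactly
at *oriC* is available behind a flag. Differences between segments are tested
by one-way ANOVA followed by Tukey HSD, with **per-strain segment means as
the replicate unit** — pooling genes across strains would pseudo-replicate.

Prophage and genomic-island calls (BED intervals from PHASTER-, AlienHunter-
or IslandViewer-style tools) are assigned by midpoint to three
normalised-distance bins [0, ⅓], (⅓, ⅔], (⅔, 1]; each "third" is the union of
the two symmetric arcs on both replichores and covers L/3 bp. Counts and DNA
proportions per third are compared by ANOVA + Tukey, separately per source
tool, again over per-strain summaries.

## Synthetic cohorts

The generator produces complete, internally consistent inputs with planted
truth, emulating the study design the analysis assumes:

- **Occupancy mixture.** Each family draws its carrier-strain fraction from a
  configurable mixture (default: 25% core, 5% at 0.95, 20% at 0.5, 20% at
  0.25, 30% at 0.05), and counts are adjusted so the grand total of gene
  slots is exact. Carriers are realised by a Gale–Ryser-style greedy fill so
  **every strain carries exactly `genes_per_strain` genes**, paralog copies
  included (5% of families get a duplicate member in one carrier, planned
  before the fill).
- **Positional bias.** Within each strain, family occupancies are rank-matched
  to noisy linear targets *β·d + σz* over gene positions. The rank transform
  attenuates the realised slope when scores are non-Gaussian, so σ is
  calibrated by per-strain bisection until the gene-level regression slope of
  the placed scores equals β; slopes beyond the comonotone maximum are clamped
  there (the construction's detection floor). This makes β the literal
  regression slope the downstream fit should recover.
- **Sequences.** Bases are drawn with replichore-dependent skew: on the
  clockwise replichore P(G) ∝ (1 + s)·GC/2 and P(C) ∝ (1 − s)·GC/2 (signs
  flipped on the other replichore; A/T get half the skew in the opposite
  orientation), with background GC 0.60. The detrended cumulative G−C then
  attains its minimum at the planted origin. Exact DnaA 9-mers are written
  into the *oriC* intergenic gap, the flanking genes are named *parA*/*parB*,
  and planted phage/GI intervals get a GC-depressed but G/C-balanced
  composition.
- **Regions.** Per-strain phage/GI counts are Poisson around the configured
  means (default 3 phage, 4 GI) — real strains differ in prophage load, and
  fixed totals would make per-third counts artificially dependent. Midpoint
  distances follow the chosen placement law (uniform, or Beta(1.5, 5) /
  Beta(5, 1.5) for near-origin / near-terminus clustering); intervals are
  redrawn if they would wrap the linear coordinate origin (plain BED cannot
  represent a wrapped interval) or cover the origin gap.
- Default cohort sizes used throughout validation are 12–20 strains, 1,000
  genes per strain on 2 Mb chromosomes, which keeps a full sweep of the
  recovery experiments within a few minutes on one core.

What the generator does **not** emulate: realistic protein or codon content,
operon structure, rearrangements/inversions, gene-transfer agents, plasmids
or multi-replicon genomes, annotation errors, or any mechanistic model of how
conservation gradients arise (the linear placement law matches the fitted
model by construction; it is a stand-in, not a mechanism). Passing the
recovery experiments therefore shows the estimators are correct and
calibrated under the assumed statistical structure — not that real genomes
satisfy that structure.

## Numerical and degenerate-input choices

- Distances are integers in bp where possible; ties in extremum location
  resolve to the lowest grid position (grid default 100 bp).
- Permutation p-values use the add-one estimator (1 + #extreme)/(B + 1).
- One-way ANOVA on all-equal data returns p = 1 (no signal) instead of NaN.
- Tukey tables are empty when group variance is exactly zero.
- `reduce_one_per_genus` draws the kept strain per genus from a seeded
  generator over genera in sorted order, so results are reproducible.
- All randomness flows from `numpy` `SeedSequence` spawns of a single seed;
  fixed seeds give byte-identical output files.

## Known limitations

- The composite origin score is one defensible formalisation of a manual
  curation procedure; there is no ground-truth weighting, and the defaults
  were chosen for the planted-signal regime (strong skew, clustered boxes).
- Slope significance is exact only under exchangeability; real chromosomes
  have block structure (operons, islands) that permutation over single genes
  does not preserve.
- The thirds analysis assigns a region wholly to its midpoint's bin; regions
  straddling a bin boundary are not split.
- Multi-replicon genomes (chromids, megaplasmids) are out of scope; one
  FASTA record per strain is assumed.
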
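# thermobin

Taxonomic binning, protein-family clustering, metabolic profiling and
chemolithotrophic energetics for hot-spring metagenomes.

## The problem

Metagenomes from hydrothermal outflow channels sample communities whose
dominant organisms often have no close relative in reference databases.
Homology-based read assignment (BLAST-style searches) is precise where
references exist and useless where they do not; composition-based
assignment (nucleotide word-usage signatures) needs no references but
must be seeded with trustworthy labels. `thermobin` implements the
coordinated strategy that combines the two, plus the downstream
reconstruction steps that turn taxonomic bins into per-organism
metabolic profiles and a ranking of chemolithotrophic energy sources
along a cooling, alkaline outflow gradient. It is aimed at
microbial-ecology researchers who want these classic desk-scale
algorithms as a tested, scriptable library rather than a collection of
one-off services.

## The methods

**Homology consensus binning.** Two tracks are run per sequence: an
inclusive lowest-common-ancestor assignment over protein-level hits
(min bit score 35, top-percent 10, dataset-wide min support 5 with
bottom-up promotion) and a conservative nucleotide best-hit assignment
(bit score strictly above 300). A sequence enters a bin at the deepest
rank where the tracks agree rank-by-rank, or when (1) the LCA track
resolves it at species level, (2) the best hit scores above 1000 bits,
or (3) the shallower track agrees as far as it goes and the deeper
track reaches exactly two ranks further. Every call records the rule
that fired, so assignments are auditable.

**Tetranucleotide recruitment.** Each sequence is summarised by the
frequencies of the 256 overlapping 4-mers (counted on both strands, so
profiles are strand-invariant), profiles are projected onto the first
ten principal components, and Pearson correlations *r* between PC-score
vectors drive recruitment: a sequence longer than 900 nt and unassigned
by homology joins bin *B* iff its mean correlation to *B*'s members
exceeds *B*'s internal mean pairwise correlation and does not exceed
that of any other bin (bins need at least 50 members to recruit).
Unassigned mates of assigned paired reads are then co-assigned.

**Protein families and EC transfer.** Markov clustering (MCL, inflation
1.2) of the all-versus-all similarity graph of environmental plus
EC-labelled reference proteins, after discarding edges with e-value
above 1e-40; an EC number transfers to a cluster's unlabelled members
when it exceeds 1% of the cluster's EC label instances.

**Bin statistics and metabolic profiles.** Per bin: assigned megabases,
percent of site sequence, depth = Mb / estimated genome size, and
Lander–Waterman expected coverage (1 − e^(−depth)) × 100. EC copy
counts are normalised by the duplication factor (EC-labelled proteins ÷
distinct ECs) and called present above 0.25. Biogeochemical gene
tallies (sulfur, nitrogen, carbon-fixation categories) are normalised
to the smallest site dataset.

**OTUs and diversity.** Alignment columns are filtered (entropy ≥ 2
bits, >50% gaps, or invariant), distances are gap-skipped p-distances,
OTUs form by furthest-neighbour clustering at 3% distance, and
communities are summarised by Shannon H′ = −Σ pᵢ ln pᵢ, Simpson
D = Σ pᵢ², and Pielou J = H′/ln S.

**Energetics.** Chemical affinity A_r = 2.303 R T (log₁₀K_r − log₁₀Q_r)
measures energy available from reaction *r*; per mole of electrons it
is well approximated as linear in pH, so reactions are evaluated from
(slope, intercept, electrons) parameter tables across sites, ranked,
and screened for sign crossings along the outflow.

Every stage is exercised end to end on a synthetic hot-spring community
generator (Markov-chain genomes with controllable tetranucleotide
signatures, skewed abundances, error-free ~1 kb paired reads, simulated
hit tables whose identity and bit score decay with taxonomic distance,
planted protein families) with a full truth table for evaluation.

## Worked example

```python
from thermobin import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=0))
rec = result["recruitment"]
print(f"assigned fraction (phylum level): {result['assigned_fraction']:.3f}")
print(f"eligible hit-free reads (>900 nt): {rec['n_eligible_hit_free']}")
print(f"recruited by the tetranucleotide stage: {rec['eligible_recruited_frac']:.3f}")
print(f"phylum accuracy of recruited reads: {rec['recruited_phylum_accuracy']:.3f}")
print(result["evaluation"][["rank", "precision", "recall"]].head(2).to_string(index=False))
```

prints

```
assigned fraction (phylum level): 0.988
eligible hit-free reads (>900 nt): 394
recruited by the tetranucleotide stage: 0.987
phylum accuracy of recruited reads: 0.985
        rank  precision   recall
superkingdom   0.974128 0.962222
      phylum   0.961755 0.950000
```

On the shipped three-phylum scenario (1800 reads, 30% with no database
hits at all), homology consensus seeds the bins, the tetranucleotide
stage recruits 98.7% of the long hit-free reads (98.5% of recruits land
in the right phylum), and 98.8% of all reads end up phylum-assigned —
the reference-free stage rescuing exactly the fraction that homology
cannot see.

The same stages are available from the shell:

```bash
thermobin simulate --seed 0 --outdir sim
thermobin bin-homology sim/protein_hits.tsv sim/nucleotide_hits.tsv sim/taxonomy.tsv --out hom.csv
thermobin bin-tetra sim/reads.fasta hom.csv --out assignments.csv
thermobin evaluate assignments.csv sim/truth.csv sim/taxa.tsv --out eval.csv
thermobin run --seed 0 --outdir results/run
```

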
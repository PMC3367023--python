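# Methods

This note documents the models and procedures implemented in
`thermobin`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic test bed does and
does not demonstrate.

## Homology consensus binning

Two independent assignment tracks are merged per sequence.

*LCA track* (protein-level hits). Hits below `min_score = 35` bits are
dropped; hits within `top_percent = 10`% of the best retained bit score
are kept; the sequence is placed at the lowest common ancestor of the
kept lineages. A subject absent from the taxonomy contributes the root
(uninformative) lineage, which pulls the call to root and leaves the
read unassigned — the conservative reading. After all per-read calls, a
single bottom-up pass enforces `min_support = 5`: any taxon node with
fewer assigned reads promotes them to its parent (counts accumulate
upward); reads reaching the root become unassigned. Promotion rather
than discard was chosen because it preserves reads at the deepest
supportable rank.

*Best-hit track* (nucleotide hits). The single top hit assigns its
lineage when its bit score is strictly above `min_bit = 300` ("above
300" read as strict); ties on the top score resolve to the LCA of the
tied subjects.

*Consensus.* The base rule assigns at the deepest rank where the two
lineages agree rank-by-rank from superkingdom down. Three overrides,
checked in order before the base rule: (1) an LCA call at species level
is accepted outright; (2) a best hit above 1000 bits is accepted
outright; (3) when the shallower track agrees with the deeper one as
far as it is resolved and the deeper call reaches exactly two ranks
further, the deeper call is accepted. Override 3 deliberately requires
the shallower track to be *unresolved* past the agreement depth — it
exists to rescue a shallow-but-consistent second opinion (e.g. both
tracks matching at class while one is below its family-level
threshold), not to overrule an active conflict at family/genus. Every
call records the rule that fired; `audit_consensus` re-derives the
justification, and the test suite audits every consensus call the
pipeline makes.

## Tetranucleotide binning

Profiles are frequencies of the 256 overlapping 4-mers counted on the
sequence and its reverse complement (reads are unoriented, so profiles
must be strand-invariant; this also makes freq(w) = freq(revcomp(w)) an
exact invariant). Windows containing non-ACGT characters are skipped.

PCA is covariance-based (mean-centred, unscaled) on the union of all
sequences at a site — assigned and unassigned alike — and the first ten
component scores are retained (zero-padded when rank-deficient, with
each component's sign fixed by its largest-magnitude loading for
reproducibility). Pearson correlations between 10-dimensional score
vectors drive recruitment:

- bins need ≥ 50 members to recruit (smaller bins rely on homology
  alone);
- a candidate (> 900 nt, not phylum-assigned by homology) joins bin B
  iff its mean correlation to B's members is **greater** than B's
  internal mean pairwise correlation and **not greater** than the
  internal mean of any other bin; matching zero or several bins leaves
  it unassigned (conservative tie-break);
- unassigned mates of assigned paired reads then adopt their mate's
  bin; pairs with conflicting assignments are left untouched and
  flagged.

A statistical note on the recruitment rule: a genuine bin member is
exchangeable with the bin, so its mean correlation to the bin exceeds
the internal mean only about half the time in the idealised clean-bin
limit. The rule's practical power comes from the facts that homology
bins are slightly contaminated (which depresses the internal mean more
than the candidate-to-bin mean) and that candidates pass a length gate
(longer sequences have less profile noise than the average member).
Correlation-only recruitment therefore recovers ~83–90% of eligible
hit-free reads on the shipped scenario; the stage as a whole — rule
plus mate co-assignment — recovers ~98%, at ≥ 98% phylum accuracy.

## Protein families and EC transfer

The similarity graph keeps edges with e-value ≤ 1e-40, weighted by bit
score, plus a self-loop per node equal to its maximum incident weight
(1.0 for isolated nodes) — the standard guard against random-walk
parity artifacts. MCL iterates expansion (matrix squaring) and
inflation (entrywise power 1.2, column renormalised) with entries below
1e-5 pruned, until the matrix changes by less than 1e-8 or 200
iterations (non-convergence returns the current clustering with a
warning). Clusters are read from the attractor structure: attractor
systems sharing a column are merged and each node follows its largest
steady-state entry, ties to the lowest row index. The test suite checks
the pruned implementation against an independent unpruned fixed-point
iteration on all small fixture graphs.

EC transfer: within a cluster, each EC whose count exceeds 1% of all EC
label *instances* (strict inequality) transfers to every unlabelled
member. The alternative reading (1% of distinct ECs) is exposed via the
`min_frac` parameter but instance-fraction is the default.

## Bin statistics and metabolic profiles

Depth = assigned Mb ÷ estimated genome size (user-supplied per bin;
nearest sequenced neighbour in practice, true genome size for synthetic
bins). Coverage uses the Lander–Waterman expectation
(1 − e^(−depth)) × 100, which reproduces the published bin table's
depth→coverage mapping to within printed rounding. Bins under 0.2% of a
site's sequence are reported but flagged out of metabolic profiling.

EC presence: normalised value = raw copy count ÷ duplication factor,
where the duplication factor is total EC-labelled proteins ÷ distinct
ECs in the scope; present iff the normalised value exceeds 0.25.
Presence is monotone non-increasing in both the cutoff and the
duplication factor. Gene-category tallies use the shipped YAML map; the
dual-use sulfur genes (dsr, apr, sat) are counted under sulfate
reduction only, keeping the oxidation and reduction tallies disjoint.
With `normalize`, each site's counts scale by (smallest site total ÷
site total).

## OTUs and diversity

Columns are removed at entropy ≥ 2.0 bits (computed over the observed
residue/gap symbols; the ≥ direction removes maximally random columns,
which is the filter's purpose), > 50% gaps, or 100% identity.
Distances are gap-skipped p-distances; a pair with no comparable
positions is reported at distance 1.0 with a warning. Furthest-neighbour
(complete-linkage) clustering at threshold 0.03 guarantees every
within-OTU pair is within the threshold; end gaps are treated like
internal gaps. Simpson's index is reported as D = Σp² with 1−D and 1/D
conversions exposed, and Pielou's J is omitted (None) for single-
category communities where it is undefined.

## Energetics

`affinity_from_logs` implements A = 2.303 · R · T · (log₁₀K − log₁₀Q)
with R = 1.9872e-3 kcal/(mol·K). The per-reaction evaluation used by
the pipeline takes (slope, intercept) pairs giving affinity per mole of
electrons as a linear function of pH, multiplied by the electron count
for totals; kcal is the working unit with kJ behind a flag. Ranking is
per site, descending, ties broken by reaction id; reactions whose
per-electron affinity changes sign between sites and reactions negative
everywhere are listed separately. The shipped 20-reaction table is a
synthetic fixture (invented parameters spanning the realistic
per-electron range for alkaline springs, with oxygen-oxidant reactions
on top); it stands in for the full published reaction inventory, which
is not bundled.

## The synthetic community generator

The generator emulates a chemotrophic hot-spring streamer community:
three taxa (an Aquificae-like bacterium at abundance 0.5, a
Thermoproteales-like crenarchaeon at 0.3, a Thermus-like deinococcus at
0.2) with genomes drawn from order-3 Markov chains — memory at exactly
the tetranucleotide scale the binner uses — around distinct GC contents
(0.42 / 0.55 / 0.65) with lognormal word-usage perturbations
(`signature_sd = 0.35`, which puts pairwise Jensen–Shannon divergences
between stationary tetranucleotide distributions at 0.05–0.15). Genomes
are 200 kb: abundance structure and signatures, not genome size, carry
the signal, and this keeps the full pipeline in seconds. Reads are
error-free (Sanger-style chemistry; the methods never model sequencing
error), truncated-normal around 1000 ± 150 nt (matching ~0.9–1.1 kb
per-site averages), paired from opposite ends of ~3 kb fragments, 1800
per run.

Simulated homology searches give each taxon one congeneric reference
(identity 100 − 45·d for reference distance d, default d = 0.25 →
~89%) and one confamilial reference 8 points lower; cross-phylum
references sit at 55%. Hit probabilities decay with distance (a
self-reference registers every read); identity noise scales with
divergence (a perfect match has none); the alignable fraction is drawn
once per read and shared across its hits; bit scores are a linear
function of identity and alignment length (separate coefficients for
protein and nucleotide searches) plus Gaussian noise. A shared 30% of
reads receives no hits in either search — the novel-sequence pool the
tetranucleotide stage must rescue. These choices reproduce the regime
that motivates coordinated binning: homology assignment that is mostly
right, occasionally wrong (a few percent of reads whose own-lineage
references go unhit are misled by distant matches), and silent on a
third of the data.

Planted protein families have strong within-family edges (bit ~500,
e-value 1e-60) and sparse spurious cross-family edges (10% of cross
pairs, bit ~50) whose e-values are log-uniform between 1e-50 and 1e-10,
so most are removed by the 1e-40 cutoff — the mechanism that keeps
families separable at inflation 1.2.

What passing tests show — and don't. The generator provides exact truth
for reads, families and ECs, so recovery numbers are real measurements,
not self-fulfilling labels. But its genomes are stationary Markov
chains (no HGT islands, repeats, rRNA operons or local composition
shifts), its communities have three well-separated taxa (no
strain-level mixtures or gradients of relatedness), and its reads are
error- and chimera-free. Recovery rates on real metagenomes will be
lower, and the relative ordering of method performance is the
transferable result, not the absolute percentages.

## Numerical and bookkeeping choices

- Lineages are fixed 7-rank tuples (superkingdom…species); empty ranks
  must form a contiguous suffix. All internal coordinates are 0-based
  half-open; formats keep native conventions at the boundary.
- Mate pairs are encoded by configurable header suffixes (`/1`, `/2`).
- Complete-linkage clustering delegates to `scipy.cluster.hierarchy`;
  cluster labels are renumbered by first appearance for determinism.
- PCA delegates to scikit-learn with a deterministic sign convention;
  Pearson correlations of zero-variance score vectors are defined as 0
  with a warning (conservative for recruitment).
- Every stochastic step derives its stream from the run seed via
  `numpy.random.SeedSequence`; reruns are byte-identical, and warnings
  (undefined correlations, non-convergent MCL, empty EC scopes) are
  collected into the run manifest.
- Problem sizes used throughout the shipped scenario and acceptance
  script: 1800 reads × ~1 kb over three 200 kb genomes, 20 planted
  families of 10 proteins, 20 reactions × 5 sites.

## Known limitations

- The tetranucleotide stage recruits into homology-seeded bins only; a
  taxon with *no* homology seed (the fully novel-phylum case) is not
  discovered de novo — candidates matching no bin stay unassigned.
- MCL cluster extraction resolves overlapping attractor systems by
  merging; soft/overlapping cluster output is not supported.
- The energetics module evaluates supplied slope/intercept tables; it
  does not compute equilibrium constants from speciation chemistry or
  extrapolate them in temperature.
- Estimated genome sizes for bin statistics are inputs, not inferences.
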
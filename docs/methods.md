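# Methods

## Pipeline model and assumptions

The analysis treats each host sample as one viral community profiled by
read mapping against a single co-assembled contig catalog. Three
conventions shape everything downstream:

- **Missing records are zeros.** A (sample, contig) pair absent from the
  coverage table means no reads mapped, not missing data.
- **Filtering is contig-global.** The length and depth filters remove a
  contig from the whole catalog, not per sample, because the catalog is
  co-assembled: the depth criterion uses the *maximum* mean depth across
  samples, so a contig well-covered anywhere is retained everywhere.
  "Coverage" in the depth filter is interpreted as mean per-base fold
  coverage.
- **Boundary semantics are literal.** "Less than 500 bp" and "less than
  5×" are strict-less removals (exactly 500 bp and exactly 5.0× survive);
  the 75% breadth rule is inclusive (breadth ≥ 0.75 is present).

Relative abundance is read density (reads mapped / contig length)
normalised per sample, which corrects for the fact that a long contig
collects proportionally more reads at equal molar abundance.

## Beta diversity and the consensus dendrogram

Counts are rarefied **without replacement** (multivariate hypergeometric) —
the standard semantics of "rarefied to a depth of d counts"; replicate r
uses seed base + r so each replicate is independently reproducible.
Defaults are 10 replicates at depth 16,400. Bray–Curtis is computed on the
rarefied integer counts (with equal column totals this is equivalent to
proportions). The binary Jaccard index is available on any presence matrix;
in the pipeline it uses the 75%-breadth presence calls, which are the
natural presence/absence reading of the data and are rarefaction-free, so
the Jaccard path has a single "replicate". (The library also accepts
presence derived from rarefied counts if a caller wants that variant.)

UPGMA is implemented directly rather than through a generic linkage
routine because the pipeline needs two guarantees: merge height is *half*
the merging clusters' average distance (so cophenetic distance = 2 ×
height of the lowest common ancestor, and tip-to-tip path length equals
cophenetic distance), and exact ties are broken on the lexicographically
smallest pair of sorted cluster-label tuples, which makes the output
invariant to input order on any platform. On tie-free input it agrees with
scipy's average-linkage cophenetics to machine precision (checked in the
test suite); on ultrametric input it recovers the input matrix exactly.

"Averaging" replicate UPGMA trees is realised as the elementwise mean of
the replicate trees' cophenetic matrices followed by one more UPGMA run.
This choice is deterministic, commutes with the single-replicate case, and
always produces a well-formed ultrametric tree. Majority-rule consensus was
rejected because it can return unresolved (non-binary) trees, which would
change the cluster counts entering the congruence metrics.

## Congruence test

Both metrics operate on the nontrivial cluster sets of the rooted trees.
The matching-cluster distance pads the shorter cluster list with empty sets
(so multifurcating inputs, possible after tied merges, are handled
naturally) and solves the assignment exactly — by enumeration for ≤ 4
clusters, otherwise by the Hungarian algorithm.

The null distribution is simulated, not tabulated. Two generators are
provided and always recorded in the result:

- `uniform` (default): sequential random attachment, uniform over all
  (2n−3)!! labeled rooted binary topologies;
- `yule`: repeated splitting of a uniformly chosen leaf with shuffled label
  order, uniform over labeled histories. Per-topology mass then depends on
  tree shape; for five leaves the analytic values are 1/180 (pectinate),
  1/90 (two-cherry shape ((ab)(cd))e) and 1/60 (((ab)c)(de)), which the
  test suite checks against the sampler.

Conventions: p = count/N with the "≤ observed" (conservative) rule; when
the count is zero the p-value is reported as the upper bound 1/N and
flagged — a Monte Carlo p-value is never exactly zero. The normalised
scores divide the observed distance by the maximum distance in the null
sample (0/0 ≡ 0), so they remain meaningful for multifurcating dendrograms
where the closed-form maximum would not apply; p-values are computed on raw
distances and are unaffected by normalisation.

For a perfectly congruent pair of 5-leaf binary trees the p-value has a
closed form — the probability that a random topology equals the host
topology: 1/105 ≈ 0.0095 under `uniform`, and 1/180 ≈ 0.0056 under `yule`
for a pectinate host tree. The acceptance script reports the `yule` value
for the five-taxon pectinate host phylogeny; the generator behind
previously published analyses of this design is unpublished, so the scheme
accompanies every reported p-value.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a few host
lines (default 5), one virome each, ~1,000 contigs (a ~21% core of ~220
contigs implies a catalog of that order), 100 bp reads, and per-sample
depth (default 50,000) comfortably above the 16,400-count rarefaction
depth. Contig lengths are uniform on (500, 40,000) bp — lengths matter only
through the length adjustment and the 500 bp filter, so no attempt is made
to mimic empirical length distributions.

The abundance model is Brownian motion on the host tree in log space: a
contig's root log-abundance is Normal(0, 1); along each branch of length t
it diffuses with variance `signal_sd²·t`; at each tip independent
Normal(0, `noise_sd`) noise is added; read counts are one multinomial draw
per host over softmax-transformed log-abundances. The model is *our*
construction (the emulated study posits no generative model); its virtue is
that `signal_sd/noise_sd` is a single interpretable signal-to-noise ratio,
with `signal_sd = 0` giving exchangeable hosts — the stochastic-assembly
null. Defaults `signal_sd = 1.0`, `noise_sd = 0.5` give an intermediate,
clearly-but-not-perfectly phylosymbiotic regime.

Coverage summaries use the Lander–Waterman approximation: at mean depth d,
expected breadth 1 − exp(−d). This is deterministic given counts and
lengths — adequate for testing threshold logic, and it deliberately skips
per-read placement simulation.

What the generator does **not** emulate: sequence content, assembly
artifacts and chimeras, uneven within-contig coverage (GC or mappability
bias), cross-sample index bleed, or overdispersed (non-multinomial)
count noise. Passing power/calibration tests therefore demonstrate the
statistical machinery under a clean compositional model, not robustness to
those real-data pathologies.

All randomness flows from one master seed through named, fixed spawn-key
substreams (host tree, root abundances, Brownian steps, host noise,
multinomial draws, contig lengths, rarefaction, null topologies), so any
stage can be regenerated independently and every dataset is bit-identical
for a fixed seed.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to make their expected behaviour
sharp: the headline p-value checks use the full N = 100,000 null sample;
the metric oracle covers all 105 × 105 pairs of 5-leaf topologies plus 300
random 6-leaf pairs against a brute-force all-matchings search;
generator uniformity uses 150,000 draws on 4 labels (chi-square) and
50,000 on 5; power and type-I rates use 200 simulated datasets per
condition (2,000 contigs, depth 10,000, rarefied 3× to 5,000, N = 2,000
null topologies per run) on a fixed shallow pectinate 5-host tree with
heights 0.1–0.4. The power condition uses `signal_sd/noise_sd = 5`
(1.0/0.2); stronger absolute signal is *not* better — very large
`signal_sd` saturates Bray–Curtis near 1 for all pairs and destroys the
tree structure, one reason the defaults keep log-abundance dispersion
moderate.

## Known limitations

- Bray–Curtis on deep divergences saturates; the congruence test then loses
  power even when a phylogenetic process generated the data.
- The Monte Carlo null randomises topology only; it does not model the
  shape bias UPGMA imposes on dendrograms estimated from exchangeable data,
  so exact type-I calibration is not guaranteed (the calibration test uses
  a deliberately loose ≤ 20% band at α = 0.05).
- `validate_inputs` checks schema and labeling, not biological plausibility
  (e.g. it does not flag breadth/depth combinations that are jointly
  implausible).
- The consensus is a mean-cophenetic construction; it does not carry
  per-clade support values across replicates.
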
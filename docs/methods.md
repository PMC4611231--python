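# Methods

`ribotide` re-implements, as a tested and seed-deterministic library, the
statistical workflow used in ocean-transect microbial biogeography surveys:
an SSU-amplicon arm (read QC → OTU clustering → rarefaction → community
ordination and group tests) and a metatranscriptome arm (rRNA ribotag
profiling, functional count comparison, viral-signal filtering, and genome
recruitment). Real survey data are not bundled; every pipeline input can be
generated by the `simulate` module with known ground truth, and the test
suite judges the implementation against that truth and against closed-form
or brute-force oracles.

## Amplicon read QC

A read is truncated at the first position whose Phred score falls below the
truncation threshold (default Q20) and retained only if the truncated read
is longer than 75 bp, carries fewer than 3 low-quality bases, and contains
no N. "Low quality" is defined as Q < 20 — the same notion as the truncation
threshold — and is evaluated on the retained portion. One consequence worth
stating: at the default truncation threshold the low-quality census of the
retained prefix is always zero, so the `too_many_lowq` rejection only
becomes live when `qc_trunc_phred` is lowered below 20. The length rule is
strict (`> 75`), and rejection reasons are checked in the order
`too_short`, `too_many_lowq`, `contains_N`. QC is idempotent on kept reads.

## Ribotag extraction

Ribotags are 33-nt fingerprints of the 16S V4 hyper-variable region,
obtained without assembly by locating the conserved flank immediately 5' of
V4 and reporting the bases downstream of it.

The flank is located with a log-odds position-specific scoring matrix
(PSSM). Given N aligned flank sequences, a background distribution `bg`
(default uniform) and pseudocount `c`:

    score_i(b) = log2( ((n_i(b) + c * bg_b) / (N + c)) / bg_b )

The maximum achievable score is the sum of per-column maxima; the scanning
threshold defaults to 80% of that maximum (the published tag extractor's
matrix and threshold are not public, so the package ships a *synthetic*
training alignment built from degenerate variants of the conserved
515F-region motif `GTGYCAGCMGCCGCGGTAA` and exposes both alignment and
threshold as configuration). Both strands of every read are scanned; only
windows with at least 33 bases remaining downstream are eligible; the
highest-scoring window at or above threshold wins, with ties broken to the
leftmost window on the + strand, one tag per read (a read covers one rRNA
locus). At these settings a single flank mismatch keeps a read above
threshold and two mismatches reject it, which puts read-level recall at a 1%
per-base error rate near `1 − P(≥2 errors in 19 nt) ≈ 98%` while random
sequence essentially never scores through.

Tag tables are normalized per sample by the total number of tag-bearing
reads, making unequal-depth samples comparable for Bray-Curtis ordination.
The phrase this rule operationalizes ("normalized by the total reads
covering a tag") is ambiguous between a per-sample and a per-tag reading;
the per-sample reading is used because the frequencies then feed a
between-sample dissimilarity. Samples with zero tag-bearing reads are
flagged and excluded.

## OTU clustering

De-novo OTUs are built by greedy centroid clustering at 97% identity:
sequences are processed in decreasing abundance (ties by id), each joining
the first centroid within the identity threshold or founding a new OTU.
Identity is defined exactly — matches / alignment columns under global
Needleman–Wunsch with match 1 / mismatch 0 / gap −1 — rather than delegated
to a heuristic tool whose formula varies by version; the greedy output is
verified against a brute-force re-implementation on small inputs.

## Community ecology

* **Rarefaction** draws a multivariate hypergeometric subsample (without
  replacement) per sample to a common depth, default 6871 reads — the
  smallest sample of the original survey. Samples below the depth are
  dropped, not padded. Every output row sums to the depth exactly.
* **Bray-Curtis**: `BC(j,k) = Σ_i |y_ij − y_ik| / Σ_i (y_ij + y_ik)`.
* **nMDS** is Kruskal's non-metric scaling (stress-1, monotone regression on
  dissimilarity ranks). The SMACOF/isotonic engine is scikit-learn's
  non-metric `MDS`; the package adds a principal-coordinates start plus
  seeded random restarts and keeps the lowest-stress configuration, making
  the result deterministic for a given seed.
* **ANOSIM** follows Clarke: all off-diagonal dissimilarities are ranked
  (mid-ranks for ties) and `R = (r̄_B − r̄_W)/(M/2)` with `M = n(n−1)/2`.
  The p-value permutes group labels (default 999 permutations) with the +1
  correction, so p is never 0. The statistic is cross-checked against
  scikit-bio and against exhaustive enumeration on 2+2 designs.
* **SIMPER** decomposes the mean between-group Bray-Curtis into per-feature
  contributions `δ_i(j,k) = |y_ij − y_ik| / Σ_m (y_mj + y_mk)` averaged over
  between-group pairs. The contributions sum to the mean between-group
  dissimilarity to 1e-9 by construction; the suite asserts this identity on
  random tables. No extra standardization is applied beyond the rarefied
  counts themselves.
* **Weighted UniFrac** accumulates, per branch, each sample's fraction of
  counts descending through that branch: `raw(j,k) = Σ_b l_b |p_j − p_k|`.
  The normalized variant (default) divides by `Σ_b l_b (p_j + p_k)`,
  bounding values in [0,1] and making them depth-comparable; on a star tree
  with unit branches it coincides with Bray-Curtis on relative abundances,
  which the suite uses as a closed-form cross-check alongside a naive
  per-branch enumeration oracle and scikit-bio.
* **Alpha diversity** is observed richness and Shannon entropy (natural
  log); an all-zero sample reports 0 with an `undefined` flag.

## Metatranscriptome functional analysis

Counts are normalized either to reads-per-million of the sample's total
reads or by median-of-ratios size factors followed by `log2(x+1)` — a
deliberately simple variance-stabilizing stand-in for DESeq's parametric
transform, chosen because the downstream use is qualitative ordination, not
per-gene inference. Pathway summaries are arithmetic means of member-KO
normalized values (a KO in several pathways contributes to each), and are
therefore bounded by the member extremes.

Reads with reference hit lists are placed taxonomically at the lowest
common ancestor of all hits scoring within a top-percent margin (default
10%) of the read's best hit.

Differential abundance between two libraries uses a subsample-resampling
protocol: 1000 rounds, each drawing a multinomial subsample of 10,000 hits
from each library's empirical proportions, recording per-feature count
differences; a matching null distribution draws both subsamples from the
pooled proportions. A feature is significant at the 98% threshold when its
central 98% observed-difference interval is disjoint from the null
interval. The source method's comparison rule is not fully specified in the
literature; interval disjointness is the interpretation used here, with a
`median_outside` alternative behind a switch. Subsampling is with
replacement (multinomial); direction comes from the median observed
difference. This rule is conservative: measured per-feature false-positive
rates on null pairs sit well below the nominal 2%.

The viral quotient of a phage orthologous group is `VQ = v/(v+h)` where `v`
and `h` are per-genome-normalized hit rates to viral and prokaryotic
references (prophage regions excluded from `h`). The ratio form is an
assumption — the source renders it only as a figure — chosen as the only
form bounded in [0,1], consistent with "likelihood of occurring only in
phage", and compatible with a 0.8 cutoff. VQ is invariant under common
scaling of `v` and `h`. The retention filter keeps records with at least
1000 total counts (inclusive) and VQ strictly above 0.8, a literal reading
of "at least" versus "higher than".

## Genome recruitment

Reads are competitively assigned to a reference panel by seed-and-extend:
an exact k-mer index (k = 15) over both strands of all genomes proposes
diagonals; each diagonal is scored by gapless extension over the read
placement with match +1 / mismatch −2, locally trimmed to the
maximum-scoring segment (the gapless Smith–Waterman optimum on that
diagonal, computed by a cumulative-sum argmax). Hits below the identity or
score floors (defaults 0.7 and 40) are discarded, and each read keeps its
single best hit under a total order — score, identity, genome id, strand,
position — so output is deterministic. Alignment is substitution-only: the
synthetic error model plants no indels, and gap-free alignment admits an
exhaustive oracle (local gapless pairwise alignment over the whole panel)
that the suite checks against. Coverage summaries increment each hit's
aligned interval, so summed depth equals summed aligned length exactly;
per-genome proportions, covered fraction, and length-weighted mean identity
follow. Day/night-style condition comparisons report per-genome proportion
shifts sorted by magnitude.

## Synthetic data: what it emulates, and what it does not

* **OTU tables**: Dirichlet-multinomial draws over lognormal (σ = 1.5) base
  abundances, five water-mass groups of five stations, per-sample depths
  uniform in 7000–15000 (comfortably above the 6871 rarefaction depth). The
  default "water-mass" design boosts a dedicated 10% block of features
  8-fold per group — the several-fold dominant-taxon shifts reported
  between oceanic water masses — with overdispersion 0.002 (Dirichlet
  concentration 500, within-group compositional CV of roughly 30%,
  realistic for amplicon replicates). These defaults put strong designs in
  the near-saturated ANOSIM regime (R ≈ 1) and null designs at R ≈ 0; the
  dispersion-0 degenerate case is kept because it admits analytic oracles.
* **Tagged reads**: a conserved flank (IUPAC degeneracies resolved per
  read) followed by a pool tag at a random offset inside a 150-nt read,
  uniform substitution errors, a decoy fraction of pure random sequence,
  and a reverse-complemented fraction. Extraction recall is defined against
  the *realized* (post-error) tag: at 1% error roughly 28% of tags carry an
  error themselves, so recovery of the pre-error pool tag is not what the
  extractor can be graded on.
* **Functional libraries**: two multinomial libraries over lognormal base
  proportions with planted multiplicative fold-changes in condition B.
* **Genome panels**: genomes mutated from a common random ancestor. A
  scalar divergence is the per-genome substitution rate from the ancestor
  (pairwise separation ≈ twice that); a full matrix is treated as target
  pairwise divergences and decomposed into per-genome rates by least
  squares, with infeasible triangles rejected. Achieved pairwise
  divergences are returned alongside the panel.

Not emulated: rRNA secondary structure, chimeras, indels, quality-score
autocorrelation, phylogenetically realistic tag pools, GC/coverage biases,
and real database structure (SILVA/KEGG/POG). Passing tests therefore
demonstrate correctness of the statistics and algorithms under a controlled
substitution-only error model, not end-to-end performance on real survey
reads.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single-CPU desk run: 50,000 reads for ribotag recall, 500 null tables (999
permutations each) for ANOSIM calibration, 200 random trees for the UniFrac
oracle, and 100,000 reads against a 5 × 20 kb panel for recruitment. The
null-calibration sweep of the resampling test runs at 200 subsamples of
2000 hits — the comparison rule is subsample-size-free, so calibration
transfers — while the power check runs the full 1000 × 10000 protocol.
Genome panels are kilobase-scale stand-ins for megabase genomes; per-read
statistics (identity, best-hit competition) are length-invariant, while
absolute coverage depths scale with panel size.

Other numerical commitments: coordinates are 0-based half-open throughout;
FASTQ quality is fixed Phred+33 with scores validated into [0, 60];
distance matrices are validated symmetric with zero diagonal; all
stochastic operations take explicit seeds and derive independent per-stage
RNG streams from them (same seed + same input → identical output); the
ANOSIM permutation comparison uses a 1e-12 slack to make `R_perm ≥ R_obs`
robust to rank arithmetic noise; rarefaction uses the generator's exact
multivariate hypergeometric sampler.

## Known limitations

* The PSSM training alignment is synthetic; absolute recall numbers depend
  on its width and degeneracy, though the mechanism and thresholds are the
  ones exercised.
* Greedy clustering is quadratic in the number of unique sequences and
  intended for desk-scale inputs, not millions of amplicons.
* Recruitment has no gapped mode and no e-value model; identity/score
  floors stand in for significance filtering.
* The size-factor transform is not DESeq's variance-stabilizing transform;
  ordination-level conclusions match, per-feature variances do not.
* `nmds` reports Kruskal stress-1 from the best of a finite set of
  restarts; global optimality is not guaranteed for pathological inputs.
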
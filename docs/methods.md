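# Methods

This note documents the models and procedures metaclone implements, the
defaults that matter, what the synthetic cohort does and does not emulate,
and the judgment calls made where the underlying study design left the
choice open.

## Somatic-mutation consensus

Calls from MuTect, VarScan2 and Strelka2 are consumed as a tidy table (one
row per call per caller per tumor) keyed by `chrom_pos_ref_alt`.  Filtering
follows the printed inequalities literally — "≥" thresholds inclusive,
"<"/"below" exclusive:

| criterion | default |
| --- | --- |
| tumor sequencing depth | ≥ 20× |
| germline sequencing depth | ≥ 10× |
| tumor VAF | ≥ 0.02 |
| germline VAF | < 0.01 |
| reads supporting the variant | ≥ 4 |
| max population frequency (ESP6500/1000G/ExAC) | < 0.01 |
| MuTect LOD | ≥ 10 |
| Strelka quality | ≥ 35 |

A mutation is accepted in a tumor when ≥ 2 callers report it post-filter.
Rejected (single-caller) mutations are rescued when the same mutation
occurs — accepted or rejected — in at least two distinct tumors.  Three
points were genuinely open and are fixed as follows:

- **Self-counting.** The occurrence count includes the rejecting tumor
  itself, so two tumors that each reject the same mutation rescue each
  other.  The brute-force oracle in the test suite implements both readings;
  they diverge exactly on such borderline cases, and include-self is the
  simpler reading of "shared by at least two tumors".
- **Single pass.** Rescue runs once, not to a transitive closure.  Under
  occurrence counting on the pre-rescue union, iterating cannot add
  mutations, so the single pass is already a fixed point (tested).
- **Scope.** Rescue applies only to consensus-stage rejects, not to calls
  that failed evidence filters: a filter failure is evidence against the
  call itself, while single-caller support is a disagreement between
  otherwise-passing observations.

Filter provenance is ignored downstream — only post-filter presence enters
the consensus — and every stage logs record counts so the cascade is
auditable.

## Phylogeny

The binary presence/absence matrix (rows: tumors plus an all-zero
`germline` row modelling the mutation-free ancestor) is scored by Fitch
parsimony, vectorised across characters.  Search modes:

- `exhaustive` enumerates all (2n−5)!! unrooted topologies (capped at 8
  leaves) and returns the global optimum;
- `nni` hill-climbs by nearest-neighbor interchange from a neighbor-joining
  start tree on Hamming distances, with up to 20 sideways (equal-score)
  moves and cycle detection before declaring a local optimum.  On random
  6-leaf instances this attains the exhaustive optimum in 20/20 test seeds.

Ties among co-optimal trees are broken by the lexicographically smallest
canonical newick (subtrees sorted at every node), making results
reproducible without randomness; the `seed` argument is accepted for
interface stability only.  No branch lengths, bootstrap or likelihood
models: the tree is tumor-level, not clone-level.

## TCR repertoire metrics

Computed on productive rearrangements only (in-frame, no stop codon), with
frequencies always recomputed from template counts at load time:

- **density** = productive templates / total nucleated-cell genome
  equivalents, capped at 1 with a warning on pathological inputs;
- **richness** = distinct nucleotide rearrangements (productive-only by
  default, configurable — the underlying definition does not say);
- **clonality** = `1 + Σ pᵢ log₂ pᵢ / log₂ N`, i.e. 1 − Pielou's evenness.
  A single-clone repertoire returns 1 by convention: the evenness
  denominator log₂(1) vanishes there and the limit of one dominant clone is
  maximal monoclonality.  Terms with pᵢ = 0 cannot occur because only
  observed clones are stored.

Overlap analyses default to nucleotide rearrangements (richness, Jaccard,
shared-across-all) but use amino-acid CDR3 sequences for top-clonotype and
exclusion analyses, matching how dominant clonotypes are reported; both
keys are configurable.  A clonotype is "excluded" when undetected in one
anatomical group while detected in at least half of the other group's
samples.

## Neoantigens and methylation

Affinity prediction is consumed from file (mutation id, peptide, HLA
allele, IC50 nM); thresholds are strict: IC50 < 500 nM binder, < 50 nM
strong binder.  A tumor's neoantigen set is keyed by mutation id (not
peptide) so the methylation join is well-defined; peptide-level counts are
reported alongside.

Methylation calls use beta > 0.3 (strict).  Because the array does not
annotate mutations, probes are assigned to a mutation on the same
chromosome within a 2,000 bp window — a promoter-scale neighborhood — and a
mutation is methylated when **any** assigned probe is (window and combiner
configurable; a mean-beta combiner is provided).  The per-tumor statistic
is `methylated covered neoantigen mutations / covered neoantigen
mutations`; mutations without probe coverage are excluded from both sides,
and a zero denominator flags the sample rather than producing a number.

## Association layer

Spearman correlations use mid-ranks and the two-sided t-approximation;
two-group contrasts use the rank-sum test, three or more levels
Kruskal-Wallis with tie correction.  Matrix-vs-matrix associations (TCR JI
vs neoantigen JI) correlate strict upper-triangle vectors in a fixed label
order; these observations are tumor pairs and not independent, so a Mantel
permutation p-value is available (`stats.mantel_p`) while the default
reports the plain correlation.  No multiple-testing correction by default
(p < 0.05 significant); Benjamini-Hochberg via `adjust=True`.

## Synthetic cohort

The generator emulates the study's data structure, not its biology, and its
defaults are the study conditions:

- **Mutations.** 20 tumors (primary `P` plus `M01..M19`); anatomical groups
  (left-thoracic `P, M02, M03, M04`; thoracic; non-thoracic) form clades of
  a balanced random tree, so mutation overlap is higher within groups.
  Exactly 10 truncal mutations sit on the root edge, including a designated
  truncal stop-gain (`17_7578382_G_C`); each internal branch carries
  Poisson(6) clade mutations; private mutations top each tumor up to a
  target drawn uniformly in 57–98, the reported per-tumor range.  Totals
  are therefore dominated by private mutations — the generator calibrates
  the per-tumor range and truncal count, not the cohort-level sharing
  fractions.
- **Caller views.** Each true mutation is seen per caller with sensitivity
  0.9; evidence draws (depth ~ Poisson(120), VAF ~ U(0.15, 0.6), LOD ~
  N(40, 12), quality ~ N(60, 10), 1.5% germline contamination) let ~95–97%
  of true calls clear the filters.  False calls arrive per caller at rate
  0.02 with independently drawn positions, so they are single-caller and
  removed by consensus.  In the noiseless limit (sensitivity 1, false rate
  0, contamination 0, zero score variance) consensus reproduces truth
  exactly — a tested contract.
- **Repertoires.** Clone sizes follow a rank-based power law whose exponent
  (0.6–1.1) increases with a per-sample latent `u`; clone count (250–600
  private clones plus a 100-clone pool present in every sample) and density
  (3–38% of 50,000 nucleated-cell equivalents) also increase with `u`, so
  density, richness and clonality are positively inter-correlated by
  construction.  Every generated clone keeps ≥ 1 template: richness is
  planted as the clone count rather than left to sampling depth, which
  would otherwise anti-correlate richness with clonal skew.  Five prevalent
  clonotypes are planted absent from left-thoracic samples.  At this desk
  scale (richness in the hundreds) clonality lands around 0.05–0.3 rather
  than the 0.02–0.05 seen at richness ~10⁴; the formula is
  scale-invariant, the magnitude is not.
- **Affinities.** IC50 is log-uniform on [1, 50000] nM with a per-mutation
  center (peptides jitter around it), making binder status
  mutation-intrinsic — the property the neoantigen-overlap analysis relies
  on — and yielding ~40 neoantigen-coding mutations per tumor.
- **Methylation coupling.** Latents (u, v) come from a Gaussian copula with
  Pearson parameter 2·sin(π·ρ/6) so the planted Spearman coupling between
  the repertoire latent and the methylated-ratio latent equals `rho_plant`
  (default −0.7).  Per sample, a fraction r_s = 0.15 + 0.7·Φ(v) of covered
  neoantigen mutations draws probes from a high-beta component (Beta(40,3));
  the rest draw Beta(2,40), whose mass above 0.3 is ~1e-5, so the realized
  ratio tracks r_s closely.  CD8 fractions increase with `u`.

Randomness flows from one integer seed through ordered named child streams
(truth, latents, calls, repertoires, affinities, methylation), so cohorts
are bit-reproducible and outputs round-trip through the package's own
readers and writers (tested).

What passing tests therefore show: the pipeline's rules are implemented
correctly (oracle equivalence), planted signals of known strength are
recovered at the study's sample size, and summaries land in the reported
ranges.  What they do not show: performance on real FFPE artifacts, PCR
bias, subclonal copy-number structure, HLA-restricted antigen specificity,
or any biological claim beyond summary-range calibration.

## Numerical choices and degenerate inputs

- Jaccard of two empty sets is defined as 0 with a warning.
- Constant vectors leave Spearman undefined: flagged NaN, not an exception;
  fewer than 3 complete pairs is an error.
- All-identical data gives Kruskal-Wallis H = 0, p = 1.
- Multi-allelic records are split into biallelic mutation ids at load time;
  coordinates are 1-based inclusive.
- Problem sizes in tests and recovery experiments (20-tumor cohorts,
  repertoires of a few hundred clones, 15–50 seeds per experiment) were
  chosen as the smallest sizes at which the planted effects are
  identifiable at the study's n = 20; they are the package's own test
  conditions, not estimates of the study's sequencing scale.

## Known limitations

- No VCF ingestion: the tidy TSV dialect is the interface, reflecting that
  upstream caller outputs are heterogeneous and the study's own tables are
  request-only.  No BAM-level re-checking, copy-number integration, HLA
  typing, V/J-usage analysis, or MHC binding prediction.
- The indel question is left open upstream: the data model permits
  multi-base ref/alt, but defaults treat SNVs.
- The exclusion report is descriptive (presence/absence pattern), not a
  significance test for clonotype–site association.
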
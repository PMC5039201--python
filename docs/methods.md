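# Methods

## The model

A pooled competition starts from strain frequencies f_i(0) and runs for G
generations of exponential growth. With per-strain selection coefficients
s_i in log2 fitness units per generation,

    f_i(G) = f_i(0) · 2^(G·s_i) / Σ_j f_j(0) · 2^(G·s_j).

Measuring strain abundance by sequencing before and after therefore gives a
log2 fold-change of approximately G·s_i, up to the pool-renormalisation
term (small while most of the pool is near-neutral) and the counting noise
model below. The homozygous pool runs 10 generations, the heterozygous
pool 20, in basal medium and under glucose- or sorbitol-induced osmotic
stress, in biological triplicate; time-zero (t0) samples anchor each run.

## Synthetic data generator

The generator emulates the experiment end to end; its defaults are the
study's conditions.

**Library.** `generate_catalog` draws 20-mer up-/down-tags uniformly and
redraws collisions until all 2n tags are pairwise Hamming ≥ 5, which makes
≤ 2-mismatch assignment provably unambiguous. Multiplex 6-mer indices are
pairwise ≥ 3 apart.

**Truth.** Initial frequencies are lognormal(0, σ=1), normalised — wide
enough that a realistic minority of strains falls below the 10%-of-mean
abundance cutoff. Roles are assigned disjointly: ~5% impaired and ~3%
advantaged under stress (spike-and-slab: affected strains draw
s = ∓|N(0.2, 0.1)|, applying to both stresses with probability 0.5,
otherwise one), ~12% suppressor-artifact genes, and two sentinels
modelled on the experiment's quality-control references: a HOG1-like
strain (s_glucose = s_sorbitol = −2, lethal under stress) and a BUL1-like
strain (s ∈ [0.13, 0.16] under both stresses, so 10 generations yield
logFC ≈ 1.3–1.6). Sentinels enter the pool at the pool-mean frequency:
they stand in for reference strains of representative abundance, and their
recovery should reflect the method rather than a lucky or unlucky
abundance draw. Artifact genes model extragenic suppressors acquired
during propagation of the homozygous collection: in the homozygous pool
s_basal = +|N(0.08, 0.03)| (a mild advantage, basal logFC just above 0);
in the heterozygous pool s_basal = −(0.3 + |N(0.05, 0.03)|), so 20
generations push logFC below −3. Calling `generate_truth` with the same
seed and gene list for both collections yields consistent flags because
all draws are gene-level.

**Counts.** `simulate_competition` splits each strain's expected frequency
between its two tags with a per-tag lognormal(0, 0.3) amplification bias
(PCR efficiency), multiplies strain abundances per replicate by an
independent Gamma(1/φ_sim, mean 1) factor with φ_sim = 0.05 by default
(biological replicate noise), and draws one multinomial of the requested
depth per replicate. The resulting counts are negative-binomial-like with
dispersion ≈ φ_sim, which is what makes the common-dispersion inference
well-posed and testable.

**Reads.** `simulate_reads` writes gzipped single-end FASTQ:
6-mer index + common primer (up: `GATGTCCACGAGGTCTCT`, down:
`CGGTGTCGGTCTCGTAG`) + 20-mer tag + random filler to the read length
(default 50 nt), then independent per-base substitutions to a different
base at the configured error rate. Qualities are a constant 'I' line and
are never used by the counter. The true read geometry of the sequencing
run (in-line index vs separate index read) is not fully recoverable, so
counter and simulator share this one declared layout. Not modelled: PCR
chimeras, indels, paired-end reads, quality degradation along the read —
so passing tests demonstrate correctness of the counting and inference
machinery under substitution noise, not robustness to every real-world
artifact.

**Randomness.** Every public function takes one integer seed and draws
from a single `numpy.random.default_rng` stream in the order stated in its
docstring; the pipeline derives fixed per-stage offsets from the config
seed. Identical configs reproduce byte-identical outputs (gzip headers are
written with mtime 0).

## Counting

Per read: exact index lookup (a ≤ `max_index_mismatch` scan is available;
default exact, since no tolerance is specified for demultiplexing), primer
match at the fixed offset with ≤ 2 mismatches (the better of the two
primers decides up vs down; ties are discarded), then tag assignment.
Assignment semantics are an exhaustive minimum-Hamming scan over all
catalog tags: accept the minimum if ≤ `max_mismatch` (default 2, i.e.
"allowing two mismatches"; set 1 for the stricter "below 2" reading) and
uniquely attained; ties are ledgered as ambiguous rather than
multi-counted (a `multi_count` flag restores the permissive behaviour of
counting a read once per matching tag — identical on catalogs with tag
distance ≥ 5). The fast path (chunk pigeonhole over max_mismatch+1 exact
substrings, plus a window cache) is exactly equivalent and is tested
against the plain scan. The read ledger classifies every read
(assigned / unassigned_index / unassigned_tag / ambiguous_tag); reads
whose index matches no sample are ledgered on a synthetic `(unassigned)`
row since they belong to no sample.

## Filters

Low abundance: per-strain totals over the reference samples (t0 ∪ basal),
removed when below `threshold_frac` (default 0.10) of the mean over
strains — raw counts by default ("average counts per strain, taking
together samples"), with a normalized option since the original choice is
unstated. Reliability: genes with hom basal logFC > 0 and het basal
logFC < −3 at FDR < 0.05. The two sets are unioned; the report keeps
their overlap. Both thresholds are configuration, defaulting to the
study's constants.

## Fitness statistics

Counts for the contrast's samples are scaled to the geometric-mean library
size (total assigned counts; no trimmed-mean normalisation — none is
specified) and rounded, since the conditional NB law lives on integers.
The common dispersion φ maximises the conditional log-likelihood

    Σ_strains Σ_groups [ Σ_j ln Γ(y_j + r) − n·ln Γ(r) − Σ_j ln Γ(y_j+1)
                         + ln Γ(z+1) + ln Γ(n·r) − ln Γ(z + n·r) ],

with r = 1/φ, z the within-group total and n the replicate count —
conditioning on z removes the per-strain mean under equal library sizes.
Maximisation is golden-section search over δ = φ/(1+φ) ∈ (1e−6, 1−1e−6),
tolerance 1e−6.

The exact test treats the two group sums as NB with sizes n_A/φ, n_B/φ and
means proportional to n_A, n_B; conditional on the total S the shared
success probability cancels, leaving weights
C(s+r_A−1, s)·C(S−s+r_B−1, S−s) on s = 0..S (φ→0 reduces to
Binomial(S, n_A/(n_A+n_B))). The two-sided p sums P(s) over splits with
P(s) ≤ P(observed), with a 1e−12 relative tie tolerance; a doubled-tail
variant is available. S = 0 gives p = 1. Agreement with an independent
pmf-enumeration oracle is ≤ 1e−10 over all totals ≤ 30 and φ ∈ {0, 0.05,
0.2}. Bit-compatibility with any other count-model implementation is not a
goal; correctness is defined by enumeration agreement, null calibration
(empirical P(p ≤ α) ≤ α + 0.02 on 4300-strain null simulations) and
parameter recovery (φ = 0.1 recovered within [0.08, 0.12]; planted
s = −0.3 recovered as logFC ≈ −3).

logFC = log2((mean CPM_B + c)/(mean CPM_A + c)) with c equivalent to 0.5
pseudo-counts at the average library size, keeping zero-count strains
finite. BH and Holm adjustments wrap statsmodels and are tested against
step-by-step recomputations. Hits: Holm p < 0.05 and |logFC| > 1, split
UP/DOWN by sign. The contrasts run by the pipeline are stress-vs-basal at
matched generations (the headline lists), basal-vs-t0 (for the filters)
and glucose-vs-sorbitol (the direct stress comparison).

## QT clustering

Profiles are log2((CPM + 0.5)/(mean t0 CPM + 0.5)) per competition sample,
ordered basal/glucose/sorbitol replicates (9 components); CPM
normalisation makes profiles invariant to per-sample scaling. Distance is
1 − Pearson on these per-sample profiles; a jackknifed variant (the most
pessimistic leave-one-sample-out correlation) is available behind
`metric="jackknife"` since the original tool's default is ambiguous.
Diameter is the maximum pairwise distance. The procedure is the classic
QT loop: from every remaining seed, grow greedily by the strain whose
addition least increases the diameter (tracked as max distance to current
members) while the diameter stays ≤ 0.25; keep the largest candidate
(ties: lowest seed index; within growth, lowest strain index), remove it,
repeat until no candidate reaches 25 members. All tie-breaks are by
ascending strain index, so the assignment is deterministic; every emitted
cluster's diameter is re-verified post hoc in tests. Zero-variance
profiles cannot enter a correlation and are excluded with a warning.

## Enrichment and overlap

Term enrichment is an upper-tail hypergeometric test per term over the
post-filter universe (the retained strains, not the whole genome — the
backdrop of every hit list), skipping terms with fewer than 3 universe
genes, Holm-corrected across terms (BH available). The annotation is flat
gene→term; no ontology-hierarchy propagation. Overlap between two hit
lists is a one-sided Fisher's exact test for co-membership enrichment over
the same universe, reported with all four Venn region counts. Fisher's
exact is a declared interpretation: the original overlap-significance
statistic is unstated.

## Pipeline and problem sizes

`run_all` chains simulate → count → filter → test → cluster → enrich →
overlap, writing TSV/JSON per stage plus a SHA-256 manifest; unknown
config keys are rejected and the resolved config is written beside the
outputs. The demo configuration uses 1,000 strains at 17,000 reads per
sample (~2×10⁵ reads per collection across the 12 multiplexed samples),
chosen as the smallest scale at which every stage has non-trivial input.
Simulation-heavy checks run at 2,000–4,300 strains and depths of
2×10⁵–10⁶ reads per sample at the count level (skipping FASTQ
generation, which is validated separately at smaller scale): these are the
package's own verification sizes, giving stable statistics for calibration
and recovery bands.

## Known limitations

- The conditional dispersion estimator assumes equalised library sizes;
  strongly unequal libraries are handled by pre-scaling and rounding,
  which is approximate for very small counts.
- The generator's replicate noise is strain-independent Gamma; real
  biological replicates can be correlated (batch effects), which none of
  the calibration results speak to.
- QT clustering is O(n²)–O(n³) in the number of profiled strains; it is
  comfortable at a few thousand strains but not intended for much larger
  libraries.
- Enrichment treats annotation terms as flat sets; parent-term
  propagation, term dependence and biomodule grouping are out of scope.
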
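# Methods

## The selection model

`addontag` treats array design as budgeted greedy set cover in information
space. For phased biallelic variants, LD is quantified by the plug-in mutual
information (bits) over the 2×2 joint haplotype frequency table,

    I(X;Y) = Σ_{a,b∈{0,1}} p(a,b) log2[ p(a,b) / (p(a) p(b)) ],

computed on complete cases per variant pair (missing haplotype entries are
dropped pairwise, never imputed). No small-sample bias correction is
applied: the plug-in keeps the scoring exactly reproducible on small worked
instances, and because the selection operates on ranks and argmaxes, any
uniform rescaling (including a different log base) leaves every decision
unchanged. MI is computed on haplotypes rather than diploid genotypes since
tagging operates on allelic LD; pairs are only evaluated within a region,
keeping memory linear.

Each candidate target *j* carries `s_j = max_{i∈S3} I_ij`, its best coverage
by existing tags. A candidate tag *k* is scored by `e_k = Σ_j max(0, δ_jk) /
N_k` with `δ_jk = I_jk − s_j`, and `N_k ∈ {1,2}` the Infinium probe count
(2 for the strand-ambiguous A/T and C/G substitutions). Efficiency and
probe-ability are ranked with competition ranks (best = 1, ties share the
minimal rank) and the tag minimising the rank sum is accepted. Ties on the
rank sum are broken by higher `e_k`, then fewer probes, then genomic order —
a deterministic, efficiency-favouring rule. After acceptance every `s_j` is
recomputed exactly (no lazy caching); consequently `s_j` is nondecreasing
throughout a run and the selection is a pure function of its inputs.

The Setting-1 stopping rule is applied retrospectively: after a tag is
accepted, the run stops if that tag improved (`δ_jk > 0`) fewer than
`ceil(0.005 · |S1|)` targets (minimum one). The accepted tag that triggers
the stop remains in the result. In Setting 2, each global iteration takes
every region's best candidate — restricted to candidates that fit the
remaining budget and improve at least one target — and re-ranks those
winners globally before accepting one and debiting its probe count. By
default Setting-1 probes are debited from the same budget as Setting 2's
(`shared_budget`), since the two settings are meant to fill a single add-on
probe allocation; a separate per-setting budget is a config switch.

### Candidate sets and inputs

S1/S2/S3 resolution uses the standard thresholds (all configurable): MAF >
0.05, INFO < 0.8, probe-ability > 0.3, missingness < 0.5. Variants absent
from the imputation-quality table are treated as never imputed (quality 0)
and hence as candidate targets when common; this is the conservative reading
for variants an imputation engine refused to call. Array-manifest tags
missing from the haplotype panel stay in S3 (they are real array content)
but contribute no MI; they are logged. Reference-panel site lists, when
supplied, restrict S2; without them every sequenced variant is eligible.

## Regions

Prioritized (Setting-1) intervals are user input (BED; trait-specific gene
lists are content, not algorithm). A region qualifies for selection when
more than 20% of its imputed common variants are poor, or when the poor
variants' positional spread exceeds 1.25× the well-imputed variants'
spread. Both spreads are normalised by max(σ_all-imputed, σ_sequenced);
since the denominator is shared, the implementation compares raw standard
deviations and records the normalised values for reporting. With fewer than
two well-imputed variants the spread criterion is skipped (σ undefined);
with fewer than two poor variants it is false.

Setting-2 regions are, per target, the larger of its haplotype block and a
±5000 bp window, with overlapping regions merged. Blocks come from a
simplified Gabriel-style procedure mirroring the documented defaults of
`plink --blocks`: the 90% CI of |D′| (computed by a 201-point likelihood
grid over D′ with allele frequencies fixed at their MLEs) classifies a pair
as strong LD (lower ≥ 0.70 and upper ≥ 0.98) or strong recombination
(upper < 0.90); a span whose endpoints are in strong LD and whose
informative pairs are ≥ 95% strong LD is a block candidate; candidates are
assembled greedily longest-first and leftover variants become singleton
blocks, so blocks partition the common variants. The distance-dependent
short-block exceptions of the original procedure are omitted.

## Surrogate imputation and quality

Real evaluation pipelines use Li–Stephens-class HMM imputation engines; for
ranking array designs this package uses a deliberately small, deterministic
surrogate: each target is predicted from the single tag with maximal
training-panel MI, via the training conditional frequencies
P(target = 1 | tag allele). Strata never observed in training fall back to
the marginal frequency — this avoids 0/0 without biasing observed strata,
so a tag in perfect LD reproduces genotypes exactly (additive smoothing
would break that exactness, which is why it is not used). With no usable
tag the unconditional frequency is returned and flagged.

Quality is the MaCH/minimac-style dosage-variance ratio
Var(d) / (2 p̂ (1 − p̂)) with p̂ the dosage-implied frequency, clipped to
[0, 1]; accuracy is the squared Pearson correlation with held-out true
dosages. When two reference panels each produce a quality table, the
per-variant maximum wins (ties to the first table, for determinism). Note
that even a perfectly tagged variant shows sampling fluctuation of the
variance ratio in a finite test set; design comparisons should therefore be
read on means over many targets, which is how the evaluator reports them
(per-MAF-bin means with standard errors, default bins 0.01–0.05–0.1–0.5,
percentile binning optional).

## Hudson F_ST

Cohort divergence uses the Hudson estimator in the Bhatia et al.
ratio-of-averages form: per-site numerator
`(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)` and denominator
`p1(1−p2) + p2(1−p1)` are summed over autosomal biallelic sites common
(MAF > 0.05) in the merged cohort, and the ratio of sums is reported —
never the mean of per-site ratios, which is biased. Small negative
estimates are possible (the numerator is unbiased) and reported as-is.
Point estimates only; no block jackknife.

## Haplogroup add-ons

Mitochondrial/Y haplogroup markers follow a tree rule: for every haplogroup
observed in the cohort, include that node's marker SNPs and those of all
nodes up to two branch points below it, minus markers already on the array.
The phylogeny and per-node markers are a TSV input; haplogroup calls are
made upstream by dedicated tools.

## Synthetic data

The generator produces exactly the inputs the pipeline consumes, with
controlled structure:

* **Founder-mosaic haplotypes** — per block, a pool of founder haplotypes
  (allele frequencies uniform on `allele_freq_range`); each simulated
  haplotype copies one founder per block and re-draws the founder between
  blocks with probability `recomb_between_blocks`. A pool of two founders
  with no recombination gives deterministic coupling whose MI equals the
  marginal entropy (a closed-form oracle); full re-drawing (probability 1)
  is the between-block independence limit — note that with a finite pool,
  intermediate re-draw probabilities retain dependence, because the same
  founder can be re-drawn.
* **Balding–Nichols divergence** — per site, population frequencies are
  Beta(p(1−F)/F, (1−p)(1−F)/F) draws around an ancestral p, giving F_ST
  recovery tests a known truth.
* **Planted array mismatch** — a second, independently founded "array
  population" shares coordinates with the study population; base-array tags
  are, per block and with probability `array_bias`, the variants most
  informative in the array population (often uninformative or rare in the
  study cohort). Probe-ability scores place `low_probe_frac` (default 0.2)
  of their mass below the 0.3 threshold to exercise the filter, and the
  quality table is produced by running the surrogate evaluator with the
  planted array on a 3:1 sample split.

Defaults (400 haplotypes; 12 blocks × 8 variants; founder pool 4; re-draw
probability 0.1; `array_bias` 0.9; `array_fraction` 0.25) model a cohort
with moderate haplotype diversity genotyped on a largely mismatched array —
enough diversity that single tags are imperfect, enough mismatch that
add-ons matter. The end-to-end design-comparison experiments run this
default cohort with a probe budget of 18 (≈1.5 probes per block, the same
scarcity regime as a genome-wide budget of a few thousand probes). What the
generator does **not** emulate: realistic allele-frequency spectra,
recombination maps, genotyping error, or HMM-based imputation — so passing
tests demonstrate the selector's logic and its advantage over random
content under mismatch, not absolute INFO levels on real cohorts.

## Numerical and degenerate-input choices

* Unphased heterozygotes are pseudo-phased deterministically (alt allele to
  the first haplotype); genotypes with any missing allele are treated as
  fully missing. MI needs haplotypes, and determinism keeps runs
  reproducible; for cohorts where phase matters, phase upstream.
* Plug-in MI is clamped at 0 against float round-off; pairs with fewer than
  two joint observations are errors (scalar) or NaN (matrix), and missing
  MI entries score as 0 during selection (logged).
* `info_score` raises on zero expected variance (dosage-implied frequency 0
  or 1) rather than reporting a meaningless ratio; pipeline call sites
  record such variants as quality 0.
* BED input/output converts between 0-based half-open and the internal
  1-based closed convention at the I/O boundary only.
* Pseudoautosomal or otherwise excluded intervals are an optional BED-based
  read filter, not hard-coded coordinates.

## Known limitations

Single-tag surrogate imputation understates multi-tag and long-range
information, so absolute INFO values are conservative; bead-pool saturation
is not modelled; the block finder omits Gabriel's short-block special
cases; and the random baseline's "top-up from proposed picks" mirrors the
count-matching convention rather than strict uniformity when pools are
small.
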
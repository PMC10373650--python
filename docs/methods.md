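# Methods

## The model

`smfe` detects the *critical* (pre-disease) state of a biological system
from a single case sample plus a cohort of reference samples.  The
underlying picture is the dynamical-systems view of disease progression:
a relatively healthy before-transition state and a disease state are both
stable and low-fluctuation, while the narrow critical state between them
is unstable — near the bifurcation a dominant group of molecules (a
*dynamic network biomarker*, DNB) shows three statistical signatures:

1. the standard deviation of each member's expression rises sharply
   (SD_in ↑);
2. members become tightly correlated with each other (PCC_in ↑);
3. members decouple from the rest of the network (PCC_out ↓).

Cross-sectional cohorts can measure these signatures directly, but a
single patient sample cannot.  The single-sample Markov flow entropy
(sMFE) works around this by measuring how much one added sample perturbs
the entropy of probability flow on a directed gene-interaction network
computed over the reference cohort.

### Local Markov flow entropy

Each gene `g^k` with out-neighbors `g_1^k … g_M^k` defines a local
network.  Under a cohort of samples, the transition probability from the
center to neighbor *i* is

    p_ki = |PCC(g_i^k, g^k)| / (1 + Σ_{j=1..M} |PCC(g_j^k, g^k)|),

where the 1 in the denominator is the center's self term (|PCC| = 1).
With `x̄_k` the mean of the center's min–max-normalized expression, the
local entropy is

    MFE_k = − Σ_{i=1..M} x̄_k p_ki · ln(x̄_k p_ki),    0·ln 0 := 0.

This is the per-node decomposition of the entropy of a Markov chain on
the whole network.  At fixed `x̄` and fixed total transition mass the
entropy is maximal when the flow is spread evenly over the neighbors and
minimal when a single neighbor takes all of it (concavity of −u ln u);
both extremes are verified numerically in the test suite.

### The single-sample differential

For one case sample the score of gene `k` is

    sMFE_k = (1/ln M) · | SD^n_k · MFE^n_k − SD^{n+1}_k · MFE^{n+1}_k |,

where the `n` quantities are computed on the reference cohort and the
`n+1` quantities on the reference plus the one case sample, all under the
normalizer fitted on the reference alone.  `SD` is the population
(divide-by-n) standard deviation of the center gene — population rather
than sample SD because the two cohorts differ by exactly one observation
and the n/(n−1) correction would inject a spurious difference.

A sample drawn from the critical state carries coherent, large deviations
in the DNB module; adding it inflates `SD^{n+1}` and shifts the
center–neighbor correlations of module genes, so their differential
spikes.  The per-sample global score is the mean of the `Q = ⌈0.05·L⌉`
largest local scores (`L` = number of scoreable genes); those `Q` genes
are the sample's *signaling genes*.

### Tipping-point call

Per-sample global scores are grouped by clinical stage.  The stage with
the maximal mean is the candidate critical state; it is reported as
significant when a two-sided Welch t-test of its samples against all
other samples pooled gives P < α (default 0.05).  The direction (an
increase) is enforced by the argmax selection, so a two-sided test is
reported.

### Biomarker screen

Samples with survival data are split at the median follow-up time (ties
to the long-survival group).  A *candidate* biomarker is a
non-differentially-expressed gene appearing in at least one signaling set
whose identified samples concentrate in one group: n/(n+m) > A or
m/(n+m) > A with A = 0.6.  Candidates are classified by a Kaplan–Meier
log-rank test of identified vs unidentified samples: *optimistic*
(O-sMFE) if P < 0.05 and identified samples survive longer, *pessimistic*
(P-sMFE) if P < 0.05 and they survive shorter.

## Parameters and defaults

| parameter          | default | meaning |
|--------------------|---------|---------|
| `fraction`         | 0.05    | signaling-gene fraction (top 5% by local score) |
| `score_threshold`  | 0.8     | interaction-confidence cut for scored (STRING-style) edge lists |
| `A`                | 0.6     | survival-group enrichment needed for biomarker candidacy |
| `alpha`            | 0.05    | significance level for the tipping t-test and log-rank test |
| `de_fdr`           | 0.05    | Benjamini–Hochberg FDR for the non-DE filter |
| `eq6_form`         | product | differential form (see below) |
| `sd_on`            | raw     | expression scale for SD in the differential (see below) |
| `neighbor_mode`    | out     | local-network neighbors: out-, in-, or both |
| `tipping_mode`     | pooled  | candidate vs pooled others, or per-pair |

## Design choices in genuinely open territory

**Form of the differential.**  The differential is implemented as the
absolute difference of SD-weighted entropies,
`|SD^n·MFE^n − SD^{n+1}·MFE^{n+1}|` — the symmetric form matching the
name "differential entropy", in which the n and n+1 cohorts play
identical roles.  An asymmetric variant (`SD^n·MFE^n − SD^{n+1} +
MFE^{n+1}`), which mixes an SD and an entropy additively, is retained
behind `eq6_form="literal"` for comparison; it is not recommended, as it
is dimensionally inconsistent.

**Scale of the SD factor.**  The normalizer is fitted on the reference
cohort only and case values are clipped into the reference [0, 1] range.
This keeps the reference statistics identical across case samples and
stops one extreme sample from rescaling the cohort — but it also means an
SD computed on *normalized* values saturates: a case value five reference
ranges away scores the same as one just past the edge, capping exactly
the critical-state fluctuation the score exists to measure.  The SD
factor therefore uses the raw expression scale by default
(`sd_on="raw"`); in synthetic experiments this roughly doubles the
critical-stage score separation.  `sd_on="normalized"` restores the fully
normalized variant.

**Neighbors along outgoing edges.**  The transition probability describes
flow transmitted *from* the center along directed edges, so the local
network uses out-neighbors; `neighbor_mode` exposes the alternatives.

**Genes with fewer than two neighbors** are excluded from scoring (the
1/ln M factor vanishes at M = 1 and is undefined at M = 0).  Excluded
genes can still appear as neighbors of scoreable centers.

**Zero-variance correlations** are defined as 0 (a flat profile carries
no flow), never NaN; the self-PCC is exactly 1.

**Ties.**  Signaling-gene selection breaks ties by descending score then
ascending gene ID; median-survival ties go to the long-survival group;
both are deterministic and config-visible.

**Pooled vs per-pair tipping test.**  The pooled comparison follows the
method's original "candidate vs the other states" reading; Welch's
variant is used because stage variances differ near the transition.
Because the candidate is the argmax of the stage means, the effective
size of the pooled call grows with the number of stages (simulated: ~5%
at 2 stages, ~7% at 3, ~10% at 4, ~14% at 6 at nominal α = 0.05).  For
studies with many stages the `per_pair` mode — which demands the
candidate beat every other stage separately and reports the largest P —
is the conservative alternative.

**Network orientation is an input contract.**  Orienting a PPI network
(e.g., by lagged-regression inference from the reference cohort) is a
separate, externally published problem; this package accepts a directed
edge list and provides a documented fallback that uses each undirected
edge in both directions.

## The synthetic-data generator

`simulate` realizes the three DNB signatures in the minimal generative
model that hits all of them: multivariate Gaussian expression with a
block-structured correlation matrix, shifted to a positive baseline
(mean 10, base SD 1) and clipped at zero.  The default scenario plants a
20-gene module in a 200-gene Erdős–Rényi directed network (edge
probability 0.05), with four stages of 30 samples plus 30 reference
samples.  At the designated critical stage the module's SD triples, its
within-module correlation rises 0.2 → 0.8, and its correlation with the
rest falls 0.2 → 0.05; every other gene keeps base parameters at every
stage.  The module is grown as a *connected* subnetwork (breadth-first
from the highest-degree node): a DNB is an interconnected dominant group,
and the score only sees center–neighbor correlations, so a scattered
block would hide the PCC_in signature from every local network.

Stage effects enter only through the covariance, never the mean, so the
stages stay flat under a differential-expression analysis by design (a
`mean_shift` knob exists for DE testing).  Survival is exponential with a
proportional-hazard multiplier for marker-positive samples and
independent uniform censoring.

What the generator does *not* emulate: RNA-seq count noise (negative
binomial marginals), batch effects, library-size variation, realistic
PPI degree mixing, or real tumor-stage marginals.  Passing tests
therefore demonstrate that the implementation measures what it claims
under the DNB generative model, not that the method will show the same
power on clinical RNA-seq data.

Clipping at zero mildly distorts the target moments; at the default
baseline (ten base SDs above zero) the distortion is negligible for
non-critical genes and small for critical-stage module genes.

## Numerical notes

- Natural logarithm throughout, including the 1/ln M normalizer (the base
  cancels only if used consistently).
- `0·ln 0 = 0` is applied element-wise before summation.
- Neighbor lists are sorted lexicographically and sample order is
  irrelevant (permutation invariance to 1e−12 is tested), so runs are
  bit-reproducible for a fixed seed.
- All simulation entry points take explicit integer seeds; there is no
  global random state.
- Covariance matrices are checked for positive semi-definiteness
  (minimum eigenvalue ≥ −1e−8) before sampling, and the offending block
  is named on failure.

## Problem sizes

The shipped test and reproduction runs use the default scenario (200
genes, 4 × 30 case samples, 30 reference samples) with 25–50 replicates
for recovery rates, 1000 replicates for the detector's null calibration,
and 100 replicates for biomarker power — sizes at which the planted
effects are unambiguous while a full run stays in the minutes range on a
single CPU.

## Known limitations

- The pooled tipping test is anticonservative for many-stage designs
  (see above); use `per_pair` there.
- Min–max normalization is sensitive to reference outliers (an outlier
  stretches the range and shrinks everyone else's normalized spread).
- The score is undefined for genes whose every neighbor is flat in the
  reference cohort (the transition vector is all zeros; the score is 0,
  carrying no signal rather than an error).
- With heavy censoring the median-time split ignores censoring status by
  construction; the log-rank classification does account for it.
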
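# Methods

## Model

A candidate somatic SNV is a site where the tumor shows a non-reference
base that the matched normal (mostly) lacks. The caller's central object
is the **site-specific error rate** `p`: the probability that a sequenced
read at this exact site carries the candidate's alternative base for
technical reasons — polymerase errors, alignment context, capture
chemistry, formalin damage. `p` is estimated empirically by pooling reads
from a panel of control samples processed like the tumor, so it absorbs
site- and pipeline-specific effects that a genome-wide error model
misses.

Given `p`, the tumor's alternative read count is modelled as
`X ~ Binom(n, p)` with `n` the tumor's post-filter depth at the site, and
a variant is accepted when the upper-tail probability `P[Binom(n,p) ≥ X]`
survives Bonferroni correction over the `m` tested sites at family-wise
`α = 0.05`. The binomial assumes reads are independent Bernoulli trials;
overlapping mates of one fragment violate that, which is why both the
tumor counts and the panel counts collapse mate pairs to a single
observation before anything is estimated or tested.

### Germline separation

A control panel also contains inherited variation. At sites where any
covered control's allelic fraction exceeds `germline_af_threshold`
(default 0.10), controls are partitioned by two-means clustering of their
allelic fractions; the larger-mean cluster is interpreted as germline
carriers (heterozygous fractions concentrate near 0.5, or lower under
capture bias), the smaller-mean cluster as error-bearing. Sites carried
by ≥ `min_germline_recurrence` (default 2) controls are flagged
`germline` and excluded from somatic testing: a variant recurrently
inherited in unrelated normals is not a tumor driver candidate, and its
carriers must not contaminate the error pool. A single apparent carrier
does not flag the site — solitary high-AF observations can be
contamination or error, so the site is still tested, with that control
excluded from the pool.

The clustering is solved **exactly**: in one dimension the optimal
two-cluster partition is contiguous in sorted order, so the global
optimum is found by enumerating the n−1 split points of the sorted
fractions and minimising the within-cluster sum of squares. This removes
the only stochastic element a Lloyd-style K-means would introduce; the
`seed` parameter of `kmeans_1d_two_clusters` is accepted for interface
stability and ignored. When clustering is degenerate (fewer than two
covered controls, or all fractions identical) the partition falls back to
the threshold itself: controls above `germline_af_threshold` form the
germline set.

### Error pooling and the zero floor

The error rate is the ratio of pooled alternative to pooled total reads
over the error-bearing controls only. Controls with zero coverage at a
site carry no information and are excluded; the number of covered
controls is reported per site (`covered_controls`) and a warning is
emitted below a soft floor (default 10), because thinly covered panel
sites are where artifact detection fails in practice.

When the pool contains zero alternative reads the raw ratio is 0 and any
tumor support would yield p-value 0 regardless of whether the panel
covered the site with 50 reads or 50,000. The rate used in testing is
therefore floored at `1/(pooled_total + 1)`: confidence in a clean panel
scales with how deeply the panel looked. The floor is continuous in
pooled depth and keeps the p-value strictly positive.

### Power filter

A negative call is only meaningful where coverage could have detected a
variant. For each site the rejection threshold `k*` — the smallest count
with `P[Binom(n, p) ≥ k*]` below the per-site level — is computed, and
the power to detect a mutation at allelic fraction 0.30 in the tumor
(0.50 in the matched normal, where a missed germline het matters) is
`P[Binom(n, AF) ≥ k*]`. Sites below 80% power on either sample are
reported `low_power` instead of `reject`. The per-site level for the
power computation is `α` divided by the number of candidates reaching the
power stage (not germline-flagged, defined error rate); the Bonferroni
`m` is the number of sites actually tested after the power filter. The
two counts differ slightly by construction; using the pre-power count for
the power level avoids a circular definition.

## Filter defaults (whole-exome)

| parameter | default | meaning |
|---|---|---|
| `min_base_quality` | 30 | Phred floor per read base; removal at `< 30` |
| `min_mapping_quality` | 30 | Phred floor per alignment |
| `end_window` | 5 | read-end window for the position filter |
| `max_normal_alt` | 1 | altered reads tolerated in the matched normal |
| `germline_af_threshold` | 0.10 | control AF that triggers clustering |
| `min_germline_recurrence` | 2 | germline-cluster size that flags a site |
| `alpha` | 0.05 | family-wise significance level |
| `power_threshold` | 0.80 | required detection power |
| `tumor_detect_af` | 0.30 | tumor AF the power filter targets |
| `normal_detect_af` | 0.50 | normal AF the power filter targets |

`read_position` is counted from the read's 5′ end in sequencing order on
both strands, because end-of-read damage tracks the physical molecule
ends, not reference orientation. The position filter fails a site when
*all* alternative reads on some strand are end-positioned. Ties in the
choice of the alternative base, and in mate retention during overlap
collapse, are broken by the fixed base order A<C<G<T and by (higher base
quality, forward strand, input order) respectively; both conventions are
recorded in the per-site filter trace so results are auditable.

## Synthetic data generator

`panelsnv.simulate` emulates per-site read stacks, not sequencing:
fragments (molecules) covering a site are drawn from a negative binomial
(mean `depth_mean`, dispersion `depth_dispersion`, default 100×/50;
dispersion → ∞ recovers Poisson for analytic checks), each molecule is
assigned the alternative base (planted carriers at their het fraction,
somatic variants at their allelic fraction, errors at the site's rate) or
the reference, and each fragment emits one read or — with probability
`overlap_fraction` (default 0.2) — two overlapping mates that share a
fragment id. Base and mapping qualities come from discrete profiles with
5% / 3% of mass below the Phred-30 thresholds, so expected filter removal
rates are known; in-read positions are uniform. Formalin damage is
modelled by multiplying the C>T and G>A per-base error rates by
`ffpe_transition_bias`, giving an expected transition fraction among
errors of `bias/(bias+2)` at C/G references. A truth table records every
planted site, its parameters and germline carriers, sufficient to score
every judgement.

What the generator does **not** emulate: sequence context (no FASTQ, no
alignment, no mapping ambiguity), per-read miscalls on top of
molecule-level errors, strand bias, copy-number or purity structure, and
indels. Tests passing on these fixtures demonstrate that the statistical
machinery behaves as designed under its own assumptions — not that the
caller is robust to alignment pathologies real data can present.

### Study conditions

The packaged studies (`panelsnv.studies`, used by the test suite and
`scripts/acceptance.py`) fix their conditions once:

* **Germline-cluster study**: 135 controls at 100×, 5 het carriers at AF
  0.35, 2% error floor — the classic SNP-over-artifact geometry.
* **End-to-end study**: 100-control panel at 400×, tumor at 300×, matched
  normal at 40×, NB dispersion 100, background error 1e-3 per molecule,
  somatic variants at AF 0.05/0.10/0.15, two artifact sites at 5%
  panel-wide error and 3.5% in the tumor (artifact intensity varies
  between samples). The depths are deliberate: the panel is deep enough
  that a 5%-error site's per-control AF essentially never crosses the 10%
  clustering trigger (so artifact sites exercise the rejection path, not
  the germline path), the shallow normal rarely accumulates two
  background-error reads (which would disqualify a true site), and the
  deep tumor keeps a binomially sampled 5%-AF variant above the
  two-fragment support floor.
* **FFPE study**: the same regime with 16 transition and 4 transversion
  artifact sites plus 4 real variants, measuring the C>T/G>A fraction
  among rejected vs retained calls.

At a background site the generator spreads errors over all three
non-reference bases, so the alt-specific rate the test sees is about one
third of the total molecule error rate; reported error-rate estimates are
alt-specific.

## Numerical choices

* Binomial tails and quantiles are computed with scipy's regularised
  incomplete-beta implementation; the test suite verifies agreement with
  an explicit exact-coefficient tail sum to 1e-12 over n ≤ 200.
* `X = 0` returns p-value exactly 1; `p = 0` is a contract violation
  (the zero-pool floor must be applied first).
* Two-means ties (equal within-cluster sum of squares) resolve to the
  first optimal split in sorted order.
* Allelic fractions at zero coverage are undefined (`None`) and flagged,
  never 0; such observations are excluded from clustering and pooling.
* Reports print allelic fractions at 2 decimals and p-values/error rates
  in scientific notation with 3 significant digits.

## Known limitations

* Indels and multi-allelic sites are out of scope; only the single most
  frequent alternative base per site is carried forward.
* The binomial model is not overdispersed: systematic per-sample error
  variation within the panel (beyond what clustering removes) narrows the
  test below its nominal level. A beta-binomial would relax this.
* The position-in-read filter, applied to sites with few alternative
  reads, occasionally fires on genuinely uniform positions (a strand
  holding one or two alternative reads that happen to sit in an end
  window, ~0.1–1% of low-support sites) — a small sensitivity cost paid
  for artifact protection.
* A site with a handful of tumor error reads over a panel that saw zero
  errors can be called `real`: with a clean, deep pool the floored error
  rate is tiny and two reads suffice. Such residual false positives are
  expected and are best handled by downstream population-database
  filtering, which this package exposes only as a pass-through ID column.
* Germline flagging needs the variant *recurrently* in the panel;
  contaminating germline variants present in ≤ 1 control pass through.
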
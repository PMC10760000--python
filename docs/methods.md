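# Methods

## The detection model

A stochastic epigenetic mutation (SEM) is defined per (sample, probe)
against a reference cohort. For each CpG probe the reference beta values
(methylated signal fraction, in [0, 1]) yield quartiles Q1 and Q3 and
IQR = Q3 − Q1; a query beta strictly below Q1 − t·IQR is a hypoSEM and one
strictly above Q3 + t·IQR a hyperSEM, with fence width t = 3 by default.
The signed distance beyond the box in IQR units,

    deltaIQR = (Q1 − beta) / IQR   (hypo)
             = (beta − Q3) / IQR   (hyper),

is attached to every call and is negative for values inside the box.
Probes with IQR = 0 carry no outlier information and are excluded before
calling; so are probes with fewer than two non-missing reference values.
Ties at the fence are not calls — a beta exactly on the boundary is not
beyond it. A missing query beta yields no call rather than an error.

Quantiles use linear interpolation between order statistics (R's type 7,
`numpy.quantile` default). This choice propagates into every fence, so it
is fixed rather than configurable. Skewness and kurtosis are plain moment
ratios m3/m2^1.5 and m4/m2² (kurtosis not excess-centred); the MAD carries
the 1.4826 consistency constant; sd uses the n−1 denominator.

**SEM loads** are per-sample event counts, split by direction and by the
probe's methylation-status subtype, with explicit zeros. log10 of a zero
count is undefined and reported as NA by default; a log10(count + 1) mode
exists and is what internal ICC computations use so that load tables have
no missing cells.

**Probe methylation status** comes from k-means (k = 3) on the reference
mean beta, clusters relabelled by ascending centre to unmethylated <
intermediate < methylated. The feature set is configurable but defaults to
the mean alone: the three classes are characterised by their average
methylation level, and a single 1-d feature keeps the class boundaries
interpretable. K-means runs with 10 restarts at a fixed seed; fewer
distinct feature vectors than k is a degenerate-cluster error.

## Replicate reliability

For paired technical replicates, every (subject, probe, direction) event
called in at least one replicate is matched with the deltaIQR of both
measurements — including the non-calling one, whose deltaIQR may be
negative. Categories follow the weaker of the two deltas d = min(dA, dB):

- shared: d > 3 (both replicates beyond the fence),
- almost-shared: 1.5 < d ≤ 3,
- unshared: d ≤ 1.5.

The 1.5 boundary sits at the antimode of the counterpart-deltaIQR
distribution, which is empirically bimodal: one mode of directionally
consistent near-fence values, one mode of values far inside the box. A
two-component Gaussian mixture (EM, 10 restarts, fixed seed) formalises
that boundary; the reported cutoff is the point between the two component
means where the weighted densities intersect (solved by bisection on the
log-density difference). deltaIQR distributions have extended upper tails —
a probe with a tiny IQR turns a modest absolute deviation into a delta of
hundreds — which would otherwise capture a component of their own, so
values above the 98th percentile are trimmed before fitting (default
`trim_quantile=0.98`; on a clean two-Gaussian sample the trim moves the
recovered cutoff by ~0.03). Classification always uses the fixed
1.5 unless the caller opts into the fitted cutoff; the mixture is a
diagnostic.

**Shared proportions** are computed per replicate: of the events replicate
r called, the fraction also called by the partner, per direction; the
subject summary is the mean of the two replicate proportions, and empty
call sets give NA (excluded from means).

**ICC(2,1)** — single-rater, absolute-agreement, two-way random-effects —
is computed from the two-way ANOVA mean squares (subjects MSR, raters MSC,
residual MSE):

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

with the standard F-based 95% confidence interval for this form. It is
applied to log10(load + 1) tables by default (raw-count mode available).
Covariate adjustment (e.g. age) residualises the stacked values on the
covariate by least squares before the ANOVA; a constant covariate falls
back to the unadjusted estimate with a warning. Zero total variance makes
the ICC undefined (error). The implementation is checked in the test suite
against a brute-force ANOVA oracle (to 1e-10) and against an independent
library implementation.

**Reference-size sweeps** re-run the detect-and-match pipeline on random
sample subsets of the reference at each requested size (several draws per
size, seeded) and report mean shared proportion and load ICC per direction.
Sizes below 10 are rejected: quartiles of smaller subsets are too unstable
to define meaningful fences.

## The random-forest reliability filter

Two independent classifiers, one per direction, predict whether a SEM would
replicate. The positive class groups shared with almost-shared events —
the partner crossed 1.5 IQR, so the event is directionally replicated even
though it missed the full fence — and unshared events are negative. Note
the detection fence itself never loosens: candidate events must still cross
3 IQR in the calling replicate.

Feature vectors combine per-probe reference statistics, the deltaIQR of the
calling replicate, sample cell-type proportions (CD8T, CD4T, NK, B, Mono,
Gran) and probe annotation (SNP at the single-base-extension site / at the
CpG / in the probe body, colour channel, genomic context, regulatory
features, CpG density, methylation class). Training rows come from the
first replicate's calls; the fitted model is applied to both replicates.

Feature selection measures association with the label — point-biserial
correlation for numeric features, Cramér's V for categorical ones — and
keeps features above 0.1. Redundancy is pruned greedily: survivors are
visited in descending association order (ties broken by a declared
priority, e.g. mean over median and SNP-at-SBE over SNP-at-CpG) and a
feature is kept only if no already-kept feature correlates with it beyond
|r| = 0.8 after one-hot encoding. The greedy form was chosen over
all-at-once correlation clustering because transitive chaining merges
nearly all location statistics (mean, median, quartiles, min, max, sum)
into one cluster and would discard most of the signal.

Training uses a stratified 80/20 split; hyperparameters — features per
split, per-tree sample fraction, tree count — are tuned by 5-fold
cross-validated ROC AUC on the training part (default grid: max_features ∈
{√p, p/3, p/2}, sample fraction ∈ {0.5, 0.8, 1.0}, trees ∈
{250, 500, 1000}); the best forest is refit on the full training part and
its held-out AUC and Gini importances recorded. Everything is reproducible
from the seed. Applying a model attaches a reliability probability to every
call and sets `retained = probability ≥ 0.5` (cutoff configurable); calls
are flagged, never deleted, so retained counts are monotone in the cutoff
and filtering can never create calls.

## The synthetic-data generator

No public methylation dataset ships with labelled outlier provenance, so
the generator is this package's own construction (not a re-implementation
of any published simulator) and the tests built on it validate the
machinery, not any claim about a particular cohort.

Per probe: a methylation class (weights 0.35/0.25/0.40), a mean beta near
the class centre (0.08/0.50/0.84 + N(0, 0.03)), a low-variance-enriched sd
(10^N(−1.75, 0.35), capped by the Beta-distribution feasibility bound), and
a technical noise sd expressed as a fraction of the probe sd
(10^N(−0.6, 0.4) — on low-variance array probes technical noise genuinely
rivals biological spread). Beta values are drawn from a Beta distribution
moment-matched to (mean, sd), which reproduces boundary compression and
heteroscedasticity without clipping artifacts; measurements add Gaussian
technical noise and clip to [0, 1] (clipping fraction tracked, < 5% under
defaults). Reference samples are measured the same way — latent draw plus
technical noise — exactly as a real reference cohort would be.

Replicate pairs share a subject's latent beta per probe; the two replicate
measurements add independent technical noise. Injected events:

- **biological outliers** shift the latent value to magnitude·IQR beyond
  the reference quartile (both replicates see them), magnitude
  3 + Exp(2) — the base sits at the detection fence so near-threshold
  events naturally populate the almost-shared band; rate 40 events per
  subject per direction, by default scaled exponentially in age
  (exp(0.03·(age − 55)), ages uniform 35–75), so older subjects carry more
  outliers; probes weighted toward high mean for hypo events and low mean
  for hyper events, reproducing the observed subtype asymmetry.
- **artifacts** overwrite a single replicate's measurement, magnitude
  3.3 + 1.5·Pareto(2.5) (heavier-tailed), rate 6 per replicate per
  direction, probes weighted ∝ IQR^−1.5 — artifacts concentrate on
  low-variance probes.

Every event is recorded in a truth table (subject, probe, direction, kind,
magnitude, affected replicates), enabling exact recall/spurious scoring.
Under the defaults the synthetic cohorts land in the qualitative regime the
reliability analyses assume: ~70–75% shared / ~5–9% almost-shared /
~20–25% unshared events, mean shared proportions ~0.75–0.86, load ICCs
~0.94–0.97, and clearly positive age–load correlations.

What the generator does **not** emulate: array chemistry (type I/II probe
differences), batch and plate effects, genotype-driven trimodal probes,
cell-composition-driven reliability differences, or correlated missingness.
Passing tests therefore demonstrate that the machinery recovers known
structure of this idealised kind; they are not evidence about any
particular real dataset.

## Determinism and parallelism

All randomness flows from explicit integer seeds through
`numpy.random.Generator` streams (the generator derives independent
per-stage streams from its seed). Probe-parallel detection partitions
probes into chunks and merges results sorted by (sample, probe, direction),
so output is bit-identical for any worker count; the pipeline writes a
resolved-config snapshot, and snapshot + seed determine every output file
byte for byte.

## Validation scale

The test suite and the acceptance script exercise the full pipeline at
3,000–6,000 probes, 60–150 reference samples and 12–25 replicate pairs,
with random-forest tuning grids of 2–8 points — sizes chosen so the whole
validation runs in minutes on one CPU while keeping several hundred to a
few thousand labelled events per direction, comfortably above the
train_filter minimum of 200. All event rates, magnitudes and noise levels
stay at the defaults described above. The generator's full default scale
(20,000 probes, 200 reference samples, 40 pairs) runs the complete pipeline
in a few minutes.

## Known limitations

- The ICC confidence interval is the classical F-based approximation; for
  very small cohorts (n < 10 pairs) it is rough.
- The mixture cutoff assumes exactly two Gaussian components after tail
  trimming; heavily skewed counterpart distributions can push the
  intersection away from the visual antimode.
- Covariate adjustment of the ICC residualises a single covariate linearly;
  survival and phenotype association models are deliberately out of scope —
  the pipeline exports covariate-ready load tables instead.
- The filter's ground truth is itself noisy near the 1.5 boundary; held-out
  AUC is bounded by that label noise, not only by model capacity.
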
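# Methods

## The generative model

The simulator treats a transcript as a 1-D interval of length L (nt,
transcript coordinates x measured from the TSS along spliced exons) and
tracks the expected RNA Pol II density d(x) (polymerases per nt):

| condition | expected density |
|---|---|
| `Untr` | d(x) = a |
| `R0` (end of 1 hr CPT pulse) | d(x) = a·exp(−λx) |
| `R15`/`R30` (t = 15/30 min after washout) | d(x) = a for x ≤ v·t; a·[r + (1−r)·exp(−λx)] for x > v·t |

- the untreated steady state is uniform: constant initiation and constant
  velocity give a flat density along the gene body;
- under the block, Top1cc lesions are modelled as a Poisson field of
  density λ per nt; a polymerase initiated during the pulse survives past
  position x with probability e^(−λx), giving the 5′-biased decay. Stalled
  polymerases are **not** retained as pile-ups at lesion sites — a
  deliberate simplification that keeps the block profile monotone;
- recovery is a fresh initiation wave from the TSS travelling at velocity
  v, so positions up to the wavefront w = v·t have regained full density;
  beyond it a residual fraction r of baseline persists (plus the surviving
  blocked component). Restart from stall sites is not modelled;
- immediate-early genes (a configurable fraction of transcripts no longer
  than `ieg_max_length`) are induced `ieg_fold`-fold in every treated
  condition, mimicking stimulus-induced IEG activation, which is
  independent of the elongation machinery modelled here.

Exon counts are negative binomial: exon e spanning [s, e) in transcript
coordinates has mean μ = c · b_e · ∫ₛᵉ d(x) dx and variance μ + φμ²
(φ = 0 degenerates to Poisson). b_e is a per-exon log-normal capture /
mappability bias shared by **all** specimens of the transcript. This bias
is essential, not cosmetic: it is what makes two untreated replicates of
the same transcript correlate (as real exon coverage does through sequence-
dependent capture efficiency), so that the profile-change screen has a
meaningful negative class. Without it every profile would be exchangeable
noise and the all-pairs Pearson screen would flag everything.

One seeded generator stream drives lengths, strands, baselines, exon
biases, IEG flags and counts in a fixed documented order, so identical
configs are bit-reproducible.

### Defaults and units

| parameter | default | meaning |
|---|---|---|
| `length_log10_mean` / `sd` | 3.9 / 0.7 | log10 transcript length; median ≈ 8 kb, floored at 200 nt |
| `exon_target_len` | 300 nt | exon granularity of the coverage profile |
| `init_density` (a) | 0.01 /nt | baseline polymerase density; per-transcript log10 scatter 0.5 |
| `lesion_density_*` (λ) | 2e-3 /nt | one Top1cc per ~500 nt after a 1 hr CPT pulse |
| `recovery_velocity_*` (v) | 1500 nt/min | post-washout elongation velocity (Pol II scale) |
| `residual_fraction` (r) | 0.1 | density persisting beyond the wavefront |
| `ieg_fraction` / `ieg_fold` / `ieg_max_length` | 0.1 / 8 / 2000 nt | IEG prevalence and induction |
| `depth` (c) | 20 reads per density·nt | sequencing depth scale |
| `dispersion` (φ) | 0.05 | NB dispersion |
| `exon_bias_log_sd` | 0.5 | per-exon capture bias (natural-log SD) |
| `n_reps` | 3 | replicates per (group, condition) — biological triplicates |

The elongation velocity and lesion density of CPT-treated human neurons
are not known quantities; these defaults are fixtures chosen at the
plausible physiological scale, not estimates, and parameter-recovery tests
measure the pipeline against the simulator's own truth.

`ieg_max_length` exists because "short" needed an operational definition:
the short length *stratum* (≤175 nt) is below the 200 nt simulation floor,
so IEG eligibility uses the scale of real IEG transcripts (FOS/ARC-class,
~1–3 kb) instead.

### What the generator does not emulate

No read-level artifacts (GC bias, positional fragmentation), no splicing
kinetics or intron signal, no RNA degradation, no stalled-polymerase
pile-ups, no transcript-length mis-annotation, and — by default — no
specimen-level depth variation (below). Passing tests therefore demonstrate
that the estimators are correct under the stated generative assumptions,
not that real libraries satisfy those assumptions.

## Coverage profiles

Density (count / exon length / size factor), not raw count, is the profile
unit; exon-length differences would otherwise dominate every correlation.
Size factors are median-of-ratios normalized to geometric mean 1; scaling
one specimen's counts by k rescales all densities by the same k^(1/n), so
profile shapes and all correlations are invariant. Zero-count exons keep
density 0 (no pseudocount): correlations, not logarithms, consume profiles.
Transcripts need ≥ 4 exons (Pearson on fewer points is unstable) and a
mean raw count ≥ 5; both thresholds are explicit and configurable because
the upstream filter a given dataset needs is dataset-dependent. Profile
comparison is restricted to the long stratum (> 1300 nt): an elongation
block cannot visibly reshape a profile it traverses in moments.

## The profile-change screen

"Changed in all replicates" is implemented as the conjunction over **all**
(treated × untreated) replicate pairs, not an arbitrary 1:1 pairing —
specimens carry no natural pairing, and the all-pairs conjunction is the
stricter, pairing-free reading. An undefined correlation (zero-variance
profile) vetoes the call rather than counting as below threshold:
conservative, since zero variance usually means no usable signal. The
screen is monotone in the threshold by construction.

## Recovery comparison (integrative correlation)

Per transcript and group, d = 1 − mean over replicate pairs of
Pearson(Untr profile, recovery profile) ∈ [0, 2]. Across the union of the
two groups' changed transcripts:

- **icc** — Pearson across transcripts between the two groups'
  d-vectors; its null band is the central 95% interval of icc under random
  permutation of one group's transcript labels (seeded, `n_perm`
  permutations);
- **consistent difference** — a paired permutation test on mean(d_A − d_B):
  group labels are swapped independently per transcript (equivalently the
  deltas are sign-flipped) and the observed mean must fall outside the
  null's central 95% interval. Label *permutation* is not usable here — the
  mean of d_A − d_B is invariant to permuting one group's labels — so the
  sign-flip scheme is the exact paired test under the null hypothesis of
  exchangeable groups.

This operationalization is declared, not inferred: the integrative-
correlation idea admits several concretizations and the criterion for "no
consistent change" is this package's own (mean-delta sign-flip at 95%).

**Known limitation.** The sign-flip test assumes deltas independent across
transcripts. A specimen-level effect (e.g. one unusually shallow library)
shifts the dissimilarities of *every* transcript in its group, correlating
the deltas and inflating the test's size (~12% observed at depth-SD 0.2
versus the nominal 5%). The generator therefore keeps library depth fixed
by default (`specimen_depth_log_sd = 0`); with real data, strong
depth imbalance between groups should temper confidence in a "consistent
difference" verdict.

## Wavefront estimation

Over exon midpoints, the ratio recovery/untreated is fit with a
one-changepoint step (high then low plateau) by exhaustive least-squares
search (prefix-sum O(m) scan); the changepoint is interpolated midway
between the flanking exon midpoints, so the estimate's resolution is one
exon span. Exons with zero untreated density are dropped (error if more
than half are); if no ratio falls below half the fitted high plateau the
transcript is reported as recovered beyond its end (`inf`). Division of the
estimate by the washout time gives a per-transcript recovery velocity.

## Differential expression

A generic NB Wald test, deliberately simple and fully documented rather
than a re-implementation of any specific tool:

1. median-of-ratios size factors over the selected specimens; features
   with mean normalized count < 5 are excluded before testing
   (an independent filter);
2. per-feature method-of-moments dispersion φ̂ = (s² − m)/m² per group,
   averaged, clipped at 0, then shrunk 50% toward the global mean
   dispersion — a one-line stabilizer standing in for full empirical-Bayes
   machinery;
3. log2FC = log2((m_b + 0.5)/(m_a + 0.5)) — pseudocount 0.5 declared so
   worked examples are exact;
4. Wald statistic = log2FC over its delta-method SE,
   Var(log2 m) ≈ (m + φ̂m²)/n / (m ln2)²; two-sided normal p;
   Benjamini–Hochberg over the tested set.

Calls are made by named presets with inclusive comparisons exactly as
printed: `transcript_preset` (|log2FC| ≥ 1 and adjusted p ≤ 0.1) and
`kcl_preset` (|FC| ≥ 1.5 and FDR ≤ 0.05, linear fold change
|FC| = 2^|log2FC|). The length association reports Pearson R between log10
length and the Wald statistic within a called direction — the Wald
statistic is the analog of a moderated t-statistic, not a replication of
one — plus a two-sided rank-sum test on log10 lengths between the up and
down sets.

## Pattern clustering

Agglomerative clustering of the feature × (group, condition) matrix of
log2 treated/untreated ratios, Euclidean distance, average linkage
(scipy), cut into k = 4 flat clusters. Agglomeration is deterministic for
a given matrix. Each cluster's mean profile is labelled by rules on the
condition-wise AT − WT difference with margin δ = 0.5 log2 units
(|diff| < δ everywhere → `similar_both`; > δ everywhere → `up_in_AT`;
> δ only after washout → `up_in_AT_after_washout`; < −δ everywhere →
`down_in_AT`; else `other`). Both k and δ are configurable; the archetypes
are descriptions of cluster means, not statistical tests.

## Pipeline and reproducibility

`run_pipeline` executes simulate → profiles → screen → ICC → DE →
length-association → clustering, writing flat text artifacts (GTF, TSV,
JSON manifest with SHA-256 hashes, markdown report). The resolved config
and seed are echoed into the log; the same config reproduces identical
hashes. Stages communicate only through the declared files, so any stage
can run standalone on external tables of the same shape.

## Study conditions for the operating-characteristic tests

The acceptance suite and `scripts/acceptance.py` fix these problem sizes
(chosen once, as the package's reference conditions):

- **ICC calibration/power** — 300 transcripts at log10 length 4.6 ± 0.2
  (~25–60 kb, so the 15 min wavefront of 22.5 kb lands inside most gene
  bodies), 3 replicates, 1000 permutations, 50 seeded runs; power uses
  v_AT = v_WT/2.
- **Screening** — 100 transcripts at log10 length 5.0 ± 0.15 (~70–140 kb,
  the long-gene regime this analysis targets), 20 seeded runs; the
  unaffected condition sets λ = 0. On shorter genes the screen loses
  sensitivity by construction: the surviving 5′ signal shares its capture
  bias with the untreated profile, and that spurious correlation dilutes
  only as 1/√(number of exons).
- **Wavefront** — noiseless runs use φ = 0, depth 2000, no bias/baseline
  scatter, 1 replicate; noisy runs use defaults with replicate-averaged
  profiles; transcripts shorter than 1.3 × v·t are skipped (the front must
  lie inside the body to be estimable).
- **DE null** — 2000 short unperturbed transcripts, WT-Untr vs AT-Untr
  triplicates (identically distributed by construction).

## Degenerate inputs and numerical conventions

Pearson correlations are clipped to [−1, 1] against rounding; zero-variance
profiles yield "undefined", never 0. Ties in the changepoint scan resolve
to the earliest split (argmin convention). Empty strata, empty changed
sets, and empty cluster inputs render as zeros in the report rather than
failing. Internal coordinates are 0-based half-open; GTF I/O converts at
the file boundary (1-based closed). Stratum boundaries are inclusive on
the short side: L ≤ 175 short, 175 < L ≤ 1300 mid, L > 1300 long — the
tripartition notation in the source material is self-inconsistent about
where exactly 1300 nt falls, and this package fixes 1300 as mid.
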
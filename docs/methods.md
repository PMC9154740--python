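# Methods

`ethopersist` analyzes how long a brief sensory stimulus changes an
animal's behavior, using per-frame classified behavior streams
(ethograms) as input. The pipeline was designed around mosquito
host-seeking assays — four classified behaviors (groom, walk, probe,
fly) at 30 frames/s, 5 s light or heat pulses, ~20 min trials — but
every stage is parameterized.

## Data model

An ethogram stores raw per-frame boolean flags for the four behaviors
plus an optional x–y centroid track. Raw flags may co-occur (mosquitoes
probe while walking); wherever a single category per frame is needed
(bout counts over exclusive categories, transition rates, state
ethograms) flags are collapsed by the precedence
fly > probe > walk > groom > none. Proportion features that explicitly
quantify co-occurrence (probing-and-walking, probing-not-walking,
walking-not-probing) are computed from raw flags.

Frames are 0-based, intervals half-open `[start, end)`, times in
seconds. A cohort carries a single `time_origin_s`; aligning to a
stimulus pulse is a pure change of origin and therefore exactly
invertible. Centroid velocity is the displacement between positions
100 ms apart (three frames at 30 fps) divided by the interval; a sample
whose endpoint frame is missing (track gap or end of record) is NaN and
excluded from averages, which avoids imputation bias at the cost of a
slightly smaller sample.

## Response curves, half-life, additivity

The population response is the fraction of animals whose raw flag for a
behavior is on at any frame of each time bin ("% individuals"); a
per-animal time-fraction variant is available via
`fraction_exhibiting(..., per_animal_time=True)`.

The decay half-life t1/2 is nonparametric: baseline = mean response
over the 2 min before onset; the post-onset curve is averaged in
forward-looking 15 s windows for every sample; the maximum response is
the largest windowed value (earliest window on ties); t1/2 is the first
window at or after the maximum whose value is at or below halfway
between maximum and baseline. The search starts at the maximum rather
than at onset because the rising phase also crosses the halfway level;
starting at onset would return ≈0 for every responding cohort. Results
are censored (`"no response"`, `"right-censored"`) rather than clipped.
The statistic is invariant to affine rescaling of the response axis.

Percent additivity of two stimuli A and B is
`100 × combined / (mean_A + mean_B)` per animal, where every response is
the mean response over the first 15 s after onset (the period of the
strongest responses); the cohort summary is the median. 100% is exact
additivity, 0% no response, >100% synergy. Responses are not
baseline-subtracted by default (a `baseline_subtract` flag exists).
Time-resolved additivity on a 500 ms grid is smoothed with a centered
9-bin (4.5 s) moving average, truncated at the edges.

## Window features

Each animal's record is split into 30 s windows at a 10 s step (final
partial window dropped). Per window a fixed 38-feature vector is
computed: 8 raw-flag time proportions (four behaviors, no behavior, and
the three probe/walk co-occurrence splits), 5 bout counts over
exclusive-category runs, 5 velocities (overall mean and mean during
each behavior, from the 100 ms samples fully inside the window), and 20
outgoing transition rates per second between the five exclusive
categories (consecutive-frame label changes divided by time spent in
the source category). The roster and order are frozen in
`FEATURE_NAMES` and exported as `features.schema.json` by the CLI.

Behaviors occupying less than a minimum share of a window (0.04 fly,
0.2 walk, 0.2 probe, 0.3 groom) are considered too rare to interpret in
that window: their bout count, conditional velocity, and every
transition rate into or out of them are set to zero. Windows are never
dropped, so the window grid stays uniform for the embedding. Proportion
features themselves are kept. Zeroing both incoming and outgoing rates
is an interpretive choice: an excluded behavior should not contribute
transition evidence in either direction.

## State inference

Feature vectors are z-scored per feature (zero-variance features
dropped with a warning), embedded to 2-D with tSNE (perplexity = n/100,
learning rate 200, 1000 iterations, PCA initialization, fixed seed) and
segmented into clusters. The default segmentation is automatic
density-peaks clustering: each point's local density ρ uses a Gaussian
kernel whose bandwidth is the 2% quantile of pairwise distances; δ is
the distance to the nearest denser point; cluster centers are points
that are simultaneously dense (ρ > 0.35 × peak) and isolated
(δ > 0.08 × embedding diameter); remaining points inherit the label of
their nearest denser neighbor. Cluster pairs whose border density
exceeds 0.65 × the smaller peak density are merged — such pairs sit on
a single density hill split by kernel noise, whereas genuinely distinct
clusters in a tSNE map are separated by near-empty space. Windows below
the 5th percentile of local density are left `unassigned` (the
configurable analogue of "no state inferred"). K-means with a given k
and manual polygon labeling in embedding coordinates are available as
alternatives, so a hand segmentation of the map remains expressible and
reproducible.

Clusters are then named by matching each cluster's mean behavior
composition (groom, walk, probe, fly, none shares) to four prototype
compositions: `rest` (inactive/grooming), `global_search` (flight-rich),
`local_search` (probe-rich and walking), `engorge` (probe-rich and
otherwise inactive). Several clusters may share a name; this is the
mechanism that re-merges fragments of one behavioral state that the
embedding splits into multiple islands (observed both for rest and for
engorge). Occupancy fractions per animal and period, per-state behavior
compositions, inter-state transition rates (consecutive-window label
changes per second in the source state), and per-state travel distances
are computed from the labeled windows.

`window_size_robustness` re-runs the whole feature → embedding →
clustering → naming pipeline at several window lengths (10–60 s by
default), matches windows across lengths by animal and window midpoint,
and reports the adjusted Rand agreement with the reference 30 s
labeling — a check that inferred states are not an artifact of the
window size.

Known limitation: on completely unstructured data (a single Gaussian
cloud) the automatic segmentation occasionally reports two clusters
instead of one when kernel-noise peaks straddle the merge threshold.

## Feeding classifier

Engorgement (yes/no) is predicted from the proportions of time spent in
each of the four behaviors over a stated 2 min window (by default the
2 min after the light pulse). The model is scikit-learn logistic
regression with the liblinear solver, L2 penalty at C = 1.0, and
balanced class weights. Performance is balanced accuracy at threshold
0.5 (robust to the fed/unfed imbalance; raw accuracy and AUROC are
reported alongside). Leave-one-out cross-validation quantifies
overfitting and is reported separately.

Significance is assessed against a shuffle null: the outcome column is
permuted S times (default 10,000), the model refit and scored each
time. The observed performance and all resampled performances are
scored the same way — in-sample on the rows the model was fitted to —
which makes the comparison a valid permutation test. Reported are
z = (observed − mean(null)) / sd(null) with its one-sided normal p, and
the empirical permutation p `(1 + #{null ≥ obs}) / (1 + S)`. An
alternative distribution-vs-distribution statistic,
z = (mean(boot) − mean(null)) / sqrt(var(boot) + var(null)), is
available by passing the bootstrap distribution to `significance`; it
is not the default because the observed statistic is a single number,
not a distribution. Bootstrap
resampling (rows with replacement, single-class draws redrawn, default
10,000) describes the stability of the performance estimate.

## Synthetic data generator

The generator produces cohorts with the statistical structure the
analysis assumes, plus ground-truth latent traces for recovery tests.
Each animal occupies one latent state; a stimulus pulse sends it into a
target state with an entry probability; the dwell there is exponential
with rate ln 2 / t_half (memoryless persistence is the minimal model
consistent with a single half-life) before relaxing to baseline. Within
a state, behavior is emitted as alternating bouts: a category is drawn
from the state's emission distribution, then held for a geometric
number of frames matching its mean bout length — a two-level process so
bout counts and transition rates carry signal. A configurable fraction
of probe bouts also sets the walk flag (probe/walk co-occurrence).
Tracks are heading-correlated random walks with per-behavior speeds.
Engorgement is drawn from a logistic model on the fraction of a pre-heat
window spent in local search; engorged animals enter the engorge state
60 s after heat onset for the rest of the record.

Default conditions: 70 animals, 20 min records at 30 fps, a 5 s light
pulse at 300 s and a 5 s heat pulse at 420 s; light drives local search
(entry 0.5, half-life 234 s, i.e. 3.9 min) and global search (entry
0.3, half-life 120 s); heat drives a brief local-search response
(half-life 24 s, i.e. 0.4 min). Per-state emission probabilities, bout
lengths and speeds are modeling choices picked once to give the four
states distinct, plausible compositions (rest is mostly inactive with
grooming; global search mixes flight and fast walking; local search is
probe-dominated with probe/walk co-occurrence; engorge is long
stationary probing); they are not estimates from data. The feeding
model (intercept −2.0, coefficient 3.5 on local-search occupancy)
yields roughly a third of animals engorged under the defaults.

What the generator does not emulate: arena geometry and wall
interactions, tracking noise and identity swaps, classifier errors,
inter-animal heterogeneity beyond state stochasticity, diurnal or
satiety trends, and non-exponential persistence. Passing recovery tests
therefore demonstrates the estimators are correct under the stated
model, not that the model captures every property of real recordings.

## Problem sizes and numerical choices

Test-suite runs use sizes chosen to exercise the statistics at full
fidelity while remaining desk-scale: half-life recovery on 500-animal
cohorts at half-lives 30/60/234 s (tolerance max(15 s, 20%)); state
recovery on the default 70-animal cohort (~8,300 windows, perplexity
n/100 ≈ 83); type-I calibration on 200 independent null cohorts (70
animals, 300 s records) with 500 shuffles each, expecting the empirical
rejection rate at α = 0.05 inside [0.02, 0.09]; power on 40 replicates
of a +0.15 probe-proportion effect (n = 150, 1000 shuffles each).
Resampling counts are configurable and default to 10,000 in the public
API.

Ties in the windowed maximum resolve to the earliest window. Half-life
censoring states its reason instead of returning sentinel numbers.
Geometric bout lengths are at least one frame. The additivity fixture
constructs probing frame counts whose sums are exactly divisible so the
additive, suppressive, and enhanced scenarios produce medians of
exactly 100%, 50%, and 150%.
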
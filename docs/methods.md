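# Methods

`gazehmm` analyses eye-tracking scanpaths on social scenes with Bayesian
hidden Markov models and compares clinical groups on the derived gaze
variables.  This note documents the models, the defaults and why they
were chosen, what the synthetic cohort generator does and does not
emulate, and the numerical choices a user or reviewer would want stated.

## The model

A scanpath is an ordered sequence of fixations; each fixation contributes
a 3-vector (x, y, duration).  Durations are log-transformed and all three
features standardised per stimulus (means and scales stored for exact
back-transformation), so the duration axis neither dominates nor vanishes
against the pixel axes.

The hidden process is a first-order Markov chain over K states — the
regions of interest (ROIs).  Each state emits from a full-covariance 3-D
Gaussian, so an ROI is a spatial ellipse *plus* a characteristic fixation
duration, not a hand-drawn box.  Parameters carry conjugate priors:

* initial-state vector pi ~ symmetric Dirichlet (concentration 1);
* each transition row ~ symmetric Dirichlet (concentration 1);
* each state's (mean, precision) ~ Normal-Wishart with location at the
  grand mean of the observations, scale count kappa0 = 0.1, degrees of
  freedom nu0 = D + 2 and an inverse scale chosen so the prior expected
  state covariance is diag(feature variances) / K^(2/3) — prior states
  start broad and shrink with the number of states.

Learning is variational Bayesian EM: the E-step runs forward-backward
under the expected log-parameters, the M-step applies the closed-form
conjugate updates.  The evidence lower bound (ELBO) is evaluated every
iteration (per-sequence log-normalisers minus the Dirichlet and
Normal-Wishart KL terms) and is non-decreasing within a run; convergence
is declared at a relative ELBO change below 1e-6 (pipeline runs use 1e-5)
with a 300-iteration cap.  Restarts (default 5) start from seeded k-means
partitions of the pooled observations; the best final ELBO wins.  For the
k-means initialisation only, the duration feature is down-weighted
(factor 0.1, configurable): the duration axis separates almost nothing
except the sparse catch-all state, and a full-weight partition tends to
split spatial clusters along duration and land in visibly poorer ELBO
optima.  The fit itself always sees unweighted features.

Because the priors penalise parameters the data cannot support, the
best-restart ELBO compared across K is the model-selection criterion;
ties go to the smaller K.

Decoding uses the smoothed marginals from forward-backward under the
point model (posterior means); each fixation is assigned to the state
with the highest marginal probability — deliberately *not* the Viterbi
path, since the analysed quantity is the per-fixation ROI membership.
Ties go to the lowest state index.  Forward-backward runs in scaled
linear space after factoring out the per-timestep maximum of the log
emission terms, so arbitrarily unlikely observations cannot produce NaNs.

## Two-step group modelling

**Step 1** pools every participant's scanpaths on one stimulus and fits a
single model ("pooled" mode, default), giving the representative ROIs.
An alternative "vhem" mode fits per-participant models and reduces the
ensemble: the Gaussian states of all inputs are clustered by maximising
the expected log-likelihood of virtual samples (100 per input state,
weighted by stationary occupancy) under the reduced states — the
expectations are available in closed form, so nothing is sampled — and
the reduced transition matrix aggregates the input rows through the
resulting responsibility map.  Seeding of the reduction is deterministic
farthest-point over a canonical ordering, making the result invariant to
the order the models are supplied in.  Pooled mode is the default
because the two modes share the downstream interface and pooled mode is
directly checkable against the generator truth.

**Step 2** fits each participant a model with K fixed to the
representative's.  By default the emission parameters are *held at the
representative ROIs* and only the initial-state and transition-row
posteriors are learned (a single conjugate-Dirichlet variational fit; the
ELBO here is the log-normaliser minus the Dirichlet KLs).  The rationale:
a single 120-s recording (~350 fixations) cannot support free
re-estimation of twelve 3-D Gaussians — in experiments the freely
re-fitted states drift and swap, cross-participant state correspondence
breaks, and the participant-level transition structure the method exists
to measure is largely erased.  Holding emissions treats the ROIs as
shared, semantically labelled regions and estimates only how each
participant moves among them.  Free re-estimation remains available
(`hold_emissions = false`), with initialisation from the representative
responsibilities and per-state drift flagging (default threshold 150 px).

The Step-2 transition rows use a symmetric Dirichlet with *total* mass 1
per row (concentration 1/K per destination).  With K = 12 a per-entry
concentration of 1 contributes ~10 pseudo-transitions per row against
the ~8 observed transitions a face-sized state receives in one
recording, shrinking every participant most of the way to uniform;
a unit-mass row prior keeps the estimates honest while still
regularising empty rows.  Step 1, where rows accumulate hundreds of
transitions, keeps the per-entry concentration of 1.

## ROI semantics and gaze variables

States are labelled face / body / nonsocial (social = face + body).  On
synthetic cohorts the labels come from matching each representative
state to the nearest ground-truth template ROI — the stand-in for the
manual annotation a human would do on real stimuli; for real data a
label CSV is supplied.  One state per stimulus typically collects
sparse, long fixations with no regional pattern; it is flagged when the
same state uniquely maximises both mean duration and spatial covariance
determinant, labelled "excluded", and dropped from all category
variables.

A transition is a change between two *distinct* non-excluded states
(consecutive same-state fixations are one visit, not a transition; both
legs of anything touching an excluded state are dropped).  Five pairs
are analysed — face-face, body-body, face-body, body-face,
nonsocial-nonsocial; social-to-nonsocial changes are tallied as "mixed"
for the count-conservation invariant but never analysed.  The
model-based transition probability removes each row's self-transition
and excluded destinations, renormalises, and aggregates source states
within a category with occupancy weights (decoded responsibilities by
default; stationary or uniform weights are config options, since the
category-level aggregation admits several defensible definitions).
Destination categories then sum to one from each source category; an
empty source category yields a missing value, not zero.  Fixation count,
visit count (maximal same-state runs), total fixation duration (all
fixations, seconds) and total transition count complete the variable
set.

## Statistics

Each gaze variable x ROI category is analysed with a linear mixed model

    value ~ 1 + group + actors + group:actors + covariate_c + (1 | participant)

with TD the reference group, the actor count (one/four) the stimulus
factor, and a mean-centred covariate: total transitions for transition
counts, total fixation duration for fixation/visit counts, none for
probabilities.  Fits use REML via statsmodels' MixedLM (an ML toggle
exists).  Estimated marginal means are evaluated at balanced actors and
centred covariate; contrasts vs TD are their differences.  The group
effect is the joint Wald F of the two contrasts with denominator degrees
of freedom n_participants − n_groups — a between-participant choice in
the Kenward/Satterthwaite spirit (statsmodels provides no Satterthwaite
approximation); its type-I error was verified by simulation at 0.050
over 200 null replicates.  Both candidate covariates are pre-tested for
a group effect before entering the models.  Alpha is 0.05 with no
multiplicity correction across the 16 models (5 pairs x count+probability
+ 3 categories x fixation+visit); a Benjamini-Hochberg flag is available.
Singular random-effect fits are flagged in the report, never silently
dropped.

## The synthetic cohort generator

The generator is the study-design stand-in used by every recovery test:
three groups (TD 25, ASD+ADHD 15, ASD 12), two four-actor and two
one-actor 120-s recordings per participant, 1920x1080 canvas.  Templates:
four-actor scenes have 12 ROIs (5 faces upper canvas, 3 bodies below,
4 nonsocial peripheral), one-actor scenes 9 ROIs (1 face, 1 body,
7 nonsocial); spatial SDs are drawn once per template from 30-60 px;
fixation durations are lognormal with median 300 ms (sigma_log 0.5,
floored at 80 ms).  One nonsocial state per template is a sparse
catch-all with 3x the median duration and 4x the spatial SD, giving the
sparse-state flag a true positive.

Transition structure is planted at the category level.  Each row has
self-transition mass 0.30, routes 4% of the remaining mass to the sparse
state, and distributes the rest by a category kernel; because the
analysed probability variable removes self-transitions and the excluded
state before renormalising, the kernel entries are exactly the planted
category probabilities.  The TD-like kernel puts face-to-face at 0.30;
the ASD+ADHD-like group scales it by 22/30 (other destinations
renormalised), i.e. 0.30 vs 0.22 — the magnitudes reported for this
contrast in the literature the package accompanies.  Effects are planted
*only* in transition structure; ROI geometry is shared, isolating the
reduced face-face linking mechanism.  Participants deviate from their
group kernel by Dirichlet row jitter (concentration 30 x K x row) and
10-px emission-mean jitter.  Self-mass, durations and kernels jointly
put the per-recording total transition count near the mid-200s,
within the loose calibration band around the ~300 per 120 s reported
for comparable recordings.

Raw-sample rendering emits round(duration x 120 Hz) samples per fixation
with AR(1) positional jitter (lag-1 correlation 0.98): ocular drift and
tremor are slow relative to 120 Hz, and white jitter of realistic
amplitude would fragment dispersion-based detection — with the
sum-of-ranges I-DT criterion at 2 deg (~88 px) the expected range of 48
white-noise samples at 15 px already exceeds the threshold, so
uncorrelated noise cannot satisfy a +-5% count round-trip even in
principle.  Saccade gaps (20 ms) and configured blink stretches are
invalid samples.

What the generator does **not** emulate: photographic scene content,
calibration drift, saccade trajectories between fixations, centre bias,
pupil dynamics, or emission differences between groups.  Passing tests
therefore demonstrate that the pipeline recovers transition-structure
effects of the planted magnitude under idealised Gaussian ROIs — not
that it would detect them in any particular clinical sample.

## Preprocessing

Fixation detection is dispersion-threshold (I-DT): maximal windows of
consecutive valid samples whose x-range + y-range stays within the pixel
equivalent of 2 deg of visual angle (exact chord at 70 cm on a 24-inch
16:9 screen, 53.1 cm wide -> 88.4 px) and spanning at least 60 ms.
Invalid samples (blinks, off-screen) break windows; fixation position is
the window centroid.  The sum-of-ranges dispersion metric is a documented
stand-in for the unpublished vendor default.  Quality control excludes a
recording unless tracking ratio > 0.75 and fixation-time fraction > 0.50,
both strict, so boundary values are excluded; when only fixation events
are available the ratio comes from an optional metadata column or the
ratio test is skipped with a logged warning.  Off-screen centroids are
removed with half-open bounds [0, resolution).

## Problem sizes in the validation suite

The acceptance-style checks run the full pipeline at the study's group
structure but scaled where the full protocol would be needlessly slow:
planted-effect recovery uses 25 + 15 participants, both recordings per
stimulus class, 120-s recordings, with the state count pinned to the
template's (model-selection consistency is exercised separately at
K in 1..6), 5 restarts and pipeline tolerance 1e-5; type-I calibration
uses 100 null variable-table replicates at the full 52-participant
design fitted through the same mixed-model code path.  Parameter
recovery uses 40 sequences x 200 observations; forward-backward
correctness is checked against exhaustive path enumeration at T <= 8,
K <= 3.  All seeds derive from a single base seed.

## Known limitations

* The VHEM-style reduction clusters Gaussian states and aggregates
  transition rows through the responsibility map; it does not implement
  the full hierarchical recursion over virtual *sequences*, which can
  matter when input models differ mainly in dynamics rather than
  emissions.
* Mixed-category (social-nonsocial) transitions are tallied but not
  analysed, mirroring the analysis design the package accompanies.
* Degrees of freedom for the mixed-model tests are a between-participant
  approximation, not Satterthwaite; with richer designs the two can
  diverge.
* With default settings the analysed probability variable is a model
  posterior mean and retains mild shrinkage toward uniform rows for
  states visited only a handful of times per recording.
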
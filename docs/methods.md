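# Methods

`densefc` implements the analysis chain for a single-subject dense-sampling
study: one person scanned repeatedly (twice a week, ~30 sessions over ~19
weeks) while daily behavioral, physiological and lifestyle factors are
tracked. The scientific question throughout is whether day-to-day
fluctuations in those factors are reflected in day-to-day fluctuations of
functional brain connectivity, at lag 1 day (the previous-day design) and at
lags up to 15 days. This note describes the models, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not establish.

## Signal conditioning

Sessions arrive as ROI × time matrices after standard image preprocessing.
Three steps are applied per ROI, in order:

1. **Savitzky–Golay detrending** — a 240-s smoothing window (converted to
   the nearest odd volume count at the session's TR) estimates slow scanner
   drift; the residual is kept and the per-ROI mean restored. Polynomial
   order defaults to 3; only the window length is fixed by the design, so
   the order and edge handling (`scipy`'s polynomial-interpolation edges)
   are configurable and recorded in output metadata.
2. **Confound residualization** — OLS per ROI on an intercept plus the
   confound columns (motion expansions, WM/CSF signals, physiological
   recordings when present). Confounds are first passed through the same
   Savitzky–Golay step so the filter cannot re-introduce drift through the
   regression. Linearly dependent confound columns are dropped with a
   warning. Sessions lacking physiological confounds simply omit those
   columns.
3. **High-pass at 0.01 Hz** — realized as a discrete-cosine basis
   projection: DCT component k of an N-volume series oscillates at
   k/(2·N·TR) Hz, and all components with 0 < f < 0.01 Hz are zeroed. This
   is an exact, zero-phase projection; the DC term survives, so means are
   preserved. Passband amplitude is exact on basis frequencies; off-grid
   sinusoids keep their amplitude (RMS) to well within 5% while pure drift
   is attenuated by ≥ 90%.

**Motion scrubbing.** A volume is flagged when FD > 0.2 mm, strictly — a
volume at exactly 0.2 survives; the boundary convention is tested. Two
shared-mask rules are provided for analyses that need identical time axes
across sessions: *union* scrubbing censors a volume flagged in any session,
and *percentage-based* scrubbing censors it when flagged in at least
ceil(pct · n_sessions) sessions (with 30 sessions: 3 at 10%, 2 at 5%; a pct
small enough that the count is 1 reduces exactly to union scrubbing).

## Connectivity estimation

Rest and movie runs use Pearson correlation between ROI time courses over
retained volumes, with the same keep-mask applied to every ROI. Task runs
use beta-series correlation: a least-squares-all GLM with one canonical
(double-gamma, Glover) HRF regressor per trial plus intercept and linear
drift, whose per-trial amplitude estimates are correlated across trials.
LSA was chosen because all trial stages are modeled as separate
simultaneous covariates; near-singular designs (heavily overlapping trials)
trigger a warning and a small ridge penalty. Zero-variance ROIs produce
missing links rather than silent zeros.

Link weights are Fisher-transformed (z = atanh r, with |r| = 1 clipped to
1 − 1e−7) before any across-session modeling. Session-level mean FD is then
regressed out of every link across sessions. Mean FD is centered first, so
each link keeps its across-session mean and only the FD-linear part of its
variation is removed; the result is mapped back to the correlation scale so
residualized matrices remain interpretable as connectivity. Constant FD
degenerates to the identity, with a warning.

## Graph measures

Each session's weighted matrix is reduced to a connected binary graph: the
maximum spanning tree guarantees connectedness, then the strongest positive
links are added until the edge count reaches the proportional density
(10/20/30% of n(n−1)/2). Ranking is deterministic under ties (weight
descending, then smaller node pair). Negative links are never added beyond
the tree; if the tree alone exceeds the requested density the realized
density is logged.

Two measures are computed per network on the binarized whole-brain graph:

- **Participation coefficient** PC_i = 1 − Σ_s (k_is/k_i)², averaged over
  the network's nodes (between-network integration). Isolated nodes get
  PC = 0 by convention.
- **Within-network global efficiency**: mean of 1/d(i,j) over unordered
  node pairs of the network's induced subgraph, unweighted shortest paths,
  disconnected pairs contributing 0 (within-network integration).

Thresholding is performed once on the full graph and the efficiency
subgraph is induced from it; the participation coefficient needs the whole
graph anyway, and inducing from a single thresholded graph keeps the two
measures on the same object. Both are checked against independent
brute-force oracles (exhaustive Kruskal ranking, direct edge counting,
Floyd–Warshall).

## Permutation regression

All hypothesis tests on link weights, network metrics and classification
accuracy share one engine: predictors and response are z-scored (ddof 1),
observed per-predictor t statistics come from OLS with intercept, and the
null is built by permuting the response rows. p-values are two-sided on |t|
with the add-one rule p = (1 + #{|t*| ≥ |t|})/(1 + n_perm), which cannot
return zero. Simple response permutation was chosen as the scheme; it is
calibration-tested (type-I error at nominal level under the global null)
rather than matched to any particular package's internal variant. Sessions
on day d are paired with factors of day d−1 by default (sleep factors refer
to the night ending on day d).

FDR control is Benjamini–Hochberg, applied per predictor within the family
the design prescribes: the links of the chosen subnetworks for link models,
the set of networks (per metric × threshold) for metric models, and the
spatial units for accuracy maps. Responses with zero variance across
sessions (e.g. a saturated efficiency series in a tiny network) are flagged
missing rather than aborting the family.

## Lagged cross-correlation with surrogate nulls

For lags 1–15 days, the correlation between metric(d) and factor(d − lag)
over scan days is tested against surrogate factors built by spectral
synthesis: the Fourier amplitude spectrum of the daily factor series is
kept exactly and all interior phases randomized (DC and Nyquist fixed, so
the output is real and the mean preserved). Phase randomization preserves
the autocovariance, so the null respects the factor's temporal structure
while destroying its coupling to the brain series. Surrogates are
synthesized on the full daily grid and subsampled to scan days with the
same lag arithmetic as the observed factor, preserving the irregular
twice-weekly sampling. Tests are two-sided on |rho| (product-moment by
default, rank correlation available), with BH across networks per
factor-lag pair; an optional stricter correction across the 15 lags is
provided. Lag 0 is excluded — the previous-day regression covers it.

## Inter-day representational similarity

The intersubject-correlation framework is adapted to one subject by
treating days as "subjects": for each ROI, the day-by-day brain similarity
matrix holds Pearson correlations of that ROI's time course between
sessions, censored with one shared percentage-based mask so all time axes
match. Behavioral similarity is rank-based, scaled to [0, 1]:
nearest-neighbors sim(i,j) = −|r_i − r_j| (days with close factor values
are alike) and Anna-Karenina sim(i,j) = (r_i + r_j)/2 (high-scoring days
are alike; low-scoring days are idiosyncratic — each unlike everyone).
Ties take average ranks. The two matrices are compared with a Mantel test:
Spearman correlation of the vectorized upper triangles, null by joint
row/column permutation of one matrix, one-sided positive by default (the
working hypothesis is directional: behaviorally similar days are neurally
similar), switchable to two-sided. BH-FDR runs across ROIs per model.

## Time-segment identification

Movie runs are cut into overlapping 25-TR sliding-window segments (step 1
TR; 946 segments for a 970-volume run, each 14.85 s at TR 0.594 s). For a
spatial unit (an ROI row, standing in for a 10-mm searchlight sphere at
desk scale), a leave-one-session-out classifier assigns each held-out
segment to the position whose cross-session average template it correlates
with best; accuracy is the fraction assigned correctly, against chance
1/n_segments. Ties take the smallest position; zero-variance patterns
count as −∞ correlation. Segments containing censored volumes are dropped
from the (shared) grid. Per-unit accuracy series across sessions are then
regressed on lagged factors with the shared permutation engine, BH across
units.

A property worth knowing: under pure noise, *overlapping* windows yield
accuracy slightly **below** 1/n_segments, because neighboring templates
share volumes and split near-ties; the exact uniform-chance argument holds
only for non-overlapping segments (step = window), and the tests check
chance calibration in that regime.

## Synthetic benchmark

The generator emulates the study design: 30 sessions on a Monday/Friday
pattern across 133 tracked days, 300 ROIs in 13 labeled networks (smaller
for test speed), 970 volumes at TR 0.594 s, AR(1) daily factors
standardized before completely-at-random missingness, FD traces with a
quiet (< 0.2 mm) baseline and Bernoulli spikes, and trial onsets with
2–10 s inter-trial intervals.

ROI signals come from a latent-factor model — a shared signal per community
plus idiosyncratic noise — so every generating covariance is positive
semidefinite by construction and sampling is fast. Baseline
within-community correlation defaults to 0.3. Brain–behavior couplings are
injected per link: the targeted pair shares its own latent whose loading
makes the generating correlation equal tanh(atanh(base_corr) +
slope · factor(d − lag)). The coupling is linear on the Fisher-z scale;
a linear-in-r coupling cannot keep correlations inside (−1, 1) for
realistic slopes, whereas the z-scale form is valid for any slope and is
exactly the model the downstream regression fits. Target links must be
node-disjoint, and each gets an independent latent so untargeted links stay
at their baseline. Every generator stage draws from its own seeded
substream, so behavioral factors and session noise are independent, and
identical seeds reproduce byte-identical datasets.

What passing the synthetic benchmark shows: correct null calibration of
every permutation test, recovery of known injected effects at the injected
lag and sign, and deterministic end-to-end reproduction. What it does not
show: robustness to hemodynamic nonlinearity, spatially structured noise,
non-stationary motion, departures from AR(1) behavior, or effect sizes of
real brain–behavior couplings — the paper-scale study does not report
ground-truth slopes, so synthetic slopes (0.4–0.5 per SD in the recovery
suites) are free parameters chosen to give clear but not saturated signal
at 30 sessions.

## Problem sizes and numerical conventions

The test and acceptance suites run reduced problem sizes as the package's
own benchmark choices: 40-ROI/4-network atlases, 800-volume sessions,
n_perm/n_surr = 500 with 20–50 replicates for recovery, and 400–2,000
repeats for null calibration; study-scale defaults (300 ROIs, 10,000
permutations) remain the library defaults. Other conventions: SD of a
single daily sample is 0 (keeps sparse-sensor columns aligned); the
collinearity screen drops zero-variance columns first, then iterates VIF
(threshold 5, computed after imputation), then resolves |Spearman ρ| > 0.7
pairs by a user-suppliable priority order, and is idempotent; Fisher
clipping at 1 − 1e−7; permutation p never zero by the add-one rule.

## Known limitations

- No mixed-effects, autoregressive or VAR modeling of the day series;
  sessions are treated as exchangeable under the null.
- Graph measures are binarized and unweighted; no weighted efficiency or
  community detection (communities come from the atlas).
- The searchlight stand-in is an atlas row; no voxel grid, spatial
  smoothing or cluster-level correction (BH across units replaces
  topology-aware correction at desk scale).
- Beta-series estimation offers LSA (default) and a ridge fallback, not
  LSS variants' full design space.
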
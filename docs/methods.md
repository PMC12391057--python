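# Methods

## Model and assumptions

`simnets` treats each neuron's output within an experiment as a point cloud
in a spike-train metric space: the S windows of recorded activity are S
points, and the Victor–Purpura (VP) edit distance supplies the metric. The
S×S distance matrix among a neuron's own trains (the SSIM matrix) is a
label-free summary of *what distinctions the neuron draws* between moments
of the experiment. Two neurons are computationally similar when their SSIM
matrices correlate — i.e., when they partition the experiment the same way —
independent of firing-rate scale or coding format, since Pearson correlation
is invariant to positive affine transforms of either matrix.

Assumptions worth stating explicitly:

* windows are equal-duration and comparable across neurons (simultaneous
  recording, shared clock);
* a second-order correlation of distance structures is meaningful, which
  requires enough windows for the S(S−1)/2 distance pairs to be informative
  (S ≥ ~20 in practice; the validation suite uses S = 30);
* the analysis is symmetric in time within windows and blind to
  between-window ordering — slow drift shared by all neurons will appear as
  computational similarity.

## VP distance kernel

The standard O(n·m) dynamic program with insert/delete cost 1 and shift
cost q·|Δt|:

    D[i,0] = i,  D[0,j] = j
    D[i,j] = min(D[i-1,j] + 1, D[i,j-1] + 1, D[i-1,j-1] + q|a_i - b_j|)

q ≥ 0 has units of 1/s; the temporal accuracy of the comparison is 1/q.
Limits: D(q=0) = ||a|−|b||; as q→∞, D → |a|+|b| − 2·(coincident spikes).
Forced by the base cases, empty-vs-empty is 0 and empty-vs-nonempty equals
the nonempty train's spike count. The kernel is JIT-compiled (numba) with a
pure-numpy prefix-minimum fallback; both implement the same recurrence and
the test suite checks the kernel against a brute-force enumeration over
monotone spike matchings and an independently written textbook DP.
Duplicate (simultaneous) spike times are kept — the edit distance handles
multisets naturally — with a warning at ingest.

## SSIM matrices

`compute_ssims` evaluates exactly N·S(S−1)/2 pairwise distances (the count
is recorded and asserted in tests; it is the basis of the method's linear
scaling in N). Window segmentation uses half-open intervals
[start, start+duration) so boundary spikes are never double-counted.
Multi-neuron (meso/population-level) SSIM matrices are the *elementwise sum*
of the member neurons' matrices — the additive labeled-line extension; it
reduces to the single-neuron case for singleton subsets. This combination
rule is a documented package choice, not an inference from prior art.

## CS matrix

The CS score correlates the vectorized *strict upper triangles* of two SSIM
matrices. The diagonal is excluded because it is identically zero in every
SSIM matrix and would mechanically inflate every correlation. Distances for
embedding/clustering are d = 1 − r (not 1 − |r|): anticorrelated
fingerprints are computationally dissimilar. Neurons whose off-diagonal is
constant (e.g., silent throughout) have no defined correlation; the default
policy excludes them with a logged reason, and a zero-fill policy is
available when a fixed N matters. Both the CS matrix and the SSIM batch are
order-independent: results are identical however the pairs are scheduled.

## Embedding

The CS/SSIM distance matrices are non-Euclidean, so t-SNE runs in
precomputed-distance mode. "PCA initialization" is realized as classical
(Torgerson) MDS of the same distance matrix — the natural analogue when no
feature table exists — scaled to the t-SNE convention (first-axis SD 1e-4).
MDS axis signs are fixed (largest-magnitude loading positive) and axes with
numerically zero eigenvalues are zeroed, making the initialization, and
hence the whole embedding, deterministic for fixed inputs and versions.

Defaults: 2 output dimensions for SSIM maps, 3 for CS maps; perplexity
min(30, ⌊(P−1)/3⌋) for P points, with larger requests clamped (warning);
1000 iterations. `early_exaggeration` is set to 2 rather than the common 12:
with a deterministic small-magnitude initialization on matrices of a few
hundred points, the heavy exaggeration phase collapses the configuration and
the optimizer reliably fails to unfold it (final KL divergence ~0.9 versus
~0.14 with the small value, and visibly smeared clusters). This was chosen
on convergence grounds (KL divergence, agreement with the exact-MDS
configuration) and is exposed in `EmbeddingParams`. Exact classical MDS is
available as `method="mds"` and is the better choice when a faithful global
geometry matters more than local neighborhood resolution.

## Clustering and model selection

k-means (k-means++ seeding, best of `restarts` = 20 runs by inertia, seeded
RNG) over k = 2…min(20, N−1) by default; mean silhouette per k; K_SC is the
argmax with ties broken toward the smallest k (parsimony). Silhouettes are
computed with Euclidean distance in map space; a precomputed-dissimilarity
variant exists for the shuffle test's fast mode. Labels are reported
1-based. Cluster-recovery assertions in the test suite always use the
adjusted Rand index, never raw label equality.

## Shuffle test

Null model: for each surrogate, every neuron's SSIM matrix is permuted by an
independent random permutation applied to rows and columns together (the
Mantel scheme), preserving symmetry, the zero diagonal, and the off-diagonal
multiset while destroying the across-neuron window correspondence. Each
surrogate's CS distance matrix is rebuilt and a silhouette curve computed;
the per-k central 99% interval of surrogate curves is the acceptance band.

The headline p-value is the add-one estimator
p = (1 + #{max_k SC_surr ≥ SC_obs at K_SC}) / (1 + M), using each
surrogate's *maximum* over k — conservative with guaranteed p ≥ 1/(M+1).
The observed statistic is computed through the identical code path as the
surrogates, keeping observed and null exchangeable under H0.

Two statistic modes:

* **full** — every surrogate is re-embedded with t-SNE exactly like the
  observed data (default for M < 1000);
* **fast** — k-means labels come from a classical-MDS 3-D projection of the
  surrogate CS distances and silhouettes are measured on the CS distances
  directly, skipping per-surrogate t-SNE (default for M ≥ 1000; ~50 ms per
  surrogate at N = 180). Surrogate k-means uses 5 restarts.

One RNG stream per surrogate index is spawned from the master seed, so
results are independent of evaluation order. The mode used is recorded in
the manifest. Calibration experiments in the validation suite use the fast
mode throughout so that 50 independent repetitions at M = 200 stay within a
desktop time budget; the full mode is exercised separately for correctness.

## Ground-truth simulator

Design: `n_subnetworks` = 3 subnetworks, each preferring one of 3
conditions; 10 trials per condition, 1-s windows; 20 neurons per coding
scheme per subnetwork. Each subnetwork emits a shared *baseline pattern* on
its two non-preferred conditions and a distinct pattern on its preferred
condition:

* **rate** coders: homogeneous Poisson, 10 Hz baseline / 20 Hz preferred;
* **temporal** coders: a frozen per-neuron baseline spike-time template on
  non-preferred windows and a different preferred-condition template with
  the *same spike count*, each re-emitted with 3 ms Gaussian jitter
  (truncated to the window), plus a 2 Hz Poisson background. Expected counts
  are condition-independent, so a q = 0 analysis sees only featureless count
  noise;
* **mixed** coders: templated like temporal coders but with the preferred
  template drawn at the preferred rate — both count and timing signals.

Emitting the baseline as a *template* (rather than fresh Poisson noise per
non-preferred trial) is essential to the construction: it gives every coding
scheme in a subnetwork the same qualitative SSIM block pattern (preferred
windows distinct from a coherent baseline), so rate and temporal coders of
one subnetwork correlate positively at any q > 0. With Poisson non-preferred
trials the preferred block is *low*-distance for temporal coders but
*high*-distance for rate coders, the fingerprints anticorrelate, and no
temporal accuracy recovers the planted subnetworks. Rates, template jitter,
and background rate are implementation defaults (no published values exist
for this design) chosen once to land in the qualitative regime the study
design implies: complete subnetwork separation for q > 0 and temporal-coder
collapse at q = 0.

What the simulator does *not* emulate about real recordings: latent
population dynamics and correlated (shared) variability, non-Poisson ISI
statistics (refractoriness, bursting), slow nonstationarity and electrode
drift, graded or overlapping subnetwork membership, and condition-dependent
latency shifts. Passing the recovery tests therefore demonstrates the
pipeline's correctness and power under clean, stationary, independent-noise
conditions — not performance guarantees on in-vivo data.

A second generator (`simulate_tuned_poisson`) produces Gaussian
orientation-tuned Poisson neurons for documentation examples of
single-neuron SSIM maps.

## Validation problem sizes

The test suite's headline experiments, sized to run comfortably on one CPU:
subnetwork recovery over 20 simulation seeds at q = 10 and q = 200
(180 neurons, 30 windows each); within/between map-distance separation on
one of those runs; a q = 0 run for the coding-scheme analysis;
1000 random-pair checks for each metric oracle; shuffle-test calibration
with 50 structureless populations (N = 40, S = 30) at M = 200 surrogates
and one power run at M = 1000; 10,000 Monte-Carlo draws for the permutation
null-CS check.

## Known limitations

* Pearson correlation of distance triangles is sensitive to a few large
  distances (e.g., one outlier window inflates all of a neuron's
  correlations); rank-based second-order comparators are a natural
  extension point but are not implemented.
* The silhouette criterion cannot select k = 1; a population with no
  structure is handled by the shuffle test (non-significant verdict), not by
  the curve itself.
* t-SNE map distances are not calibrated: within/between comparisons are
  meaningful, absolute distances are not.
* The shuffle null destroys *all* window structure, including autocorrelated
  slow drift; populations sharing strong common drift may be flagged as
  significant for that reason alone.
* Window duration and q interact: distances saturate when q · (typical ISI)
  >> 1; sweep q (the CLI supports `sweep-q`) rather than trusting a single
  setting.
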
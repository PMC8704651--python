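# Methods

`brainlayers` models the functional organization of motor-imagery (MI) EEG as
band-wise coherence networks, binarized with either a fixed (mean) threshold
or an adaptive Otsu threshold, analyzed both layer by layer and as one
multilayer network, and summarized by a statistics chain that localizes the
electrodes whose network role discriminates the four imagery classes (left
hand, right hand, feet, tongue).  This note records the model, its
assumptions, the numerical conventions, and what the synthetic study does and
does not establish.

## Connectivity model

For each recording and class, the trials of the analyzed imagery window
(default t = 3.5–5.5 s of the paradigm trial, 500 samples at 250 Hz) are
detrended, Hann-tapered, Fourier transformed, and the cross-spectral matrix is
averaged over the K = 72 trials:

    S_xy(f) = (1/K) Σ_k X_k(f) conj(Y_k(f)),
    C_xy(f) = |S_xy(f)|² / (S_xx(f) S_yy(f)).

Both cross- and auto-spectra are trial-averaged *before* the ratio is formed:
single-segment coherence is identically one, so averaging is what makes the
estimator informative.  Each 2-s trial is one Welch segment (no intra-trial
sub-segmentation), giving 0.5 Hz resolution — enough bins in every band.  For
incoherent signals the estimator has a known positive bias of ≈ 1/K; this is
the noise floor of all adjacency matrices and is asserted empirically in the
tests.

Band layers average `C_xy` over half-open frequency intervals
δ = [0.5, 4), θ = [4, 8), α = [8, 13), β = [13, 30) Hz (DC excluded;
half-open so adjacent bands never share an edge bin).  The γ band is outside
the scope of the analysis.

The Common Average Reference filter is applied to the continuous recording
before epoching.  CAR is an idempotent linear projection; applying it before
or after slicing is equivalent, and the order is fixed only for
reproducibility.

## Thresholding

Both rules operate on all n² entries of a layer including the unit
self-coherence diagonal (N = 22 × 22 at the reference montage), matching the
histogram convention of the adaptive rule; self-loops are always removed from
the binary network, and binarization keeps weights strictly greater than T.

* **fixed**: T = mean of all entries.
* **otsu**: candidates are the midpoints between consecutive distinct entry
  values — this reproduces an exhaustive sweep exactly, with no arbitrary
  step size.  Entries < T form class C1 (spurious), entries ≥ T class C2
  (effective); WCV = w₁σ₁² + w₂σ₂² and BCV = w₁w₂(μ₁−μ₂)² use population
  variances, so WCV + BCV equals the total entry variance identically
  (asserted to 1e−10), and maximizing BCV is the same as minimizing WCV.
  Ties are broken toward the smallest optimal T (retains more edges,
  deterministic).

## Graph metrics

Single-layer metrics on each binarized band network: degree (row sums),
eigenvector centrality (leading eigenvector, non-negative, unit Euclidean
norm), k-core number (iterative peeling), PageRank (damped random walk,
stationary distribution sums to one).  Conventions for the degenerate cases
that thresholded EEG networks routinely produce:

* eigenvector centrality is computed on the largest connected component
  (ties broken toward the component containing the lowest node index) and is
  zero elsewhere — the leading eigenvector is otherwise non-unique;
* PageRank damping defaults to 0.85; damping = 1 recovers the pure
  neighbor-averaging recursion PR(v) = Σ_{u∈B_v} PR(u)/d(u) but is not
  guaranteed to converge on bipartite or disconnected graphs.  Rows of
  isolated nodes teleport uniformly.  Power iteration stops at an L1 change
  below 1e−12 or errors after 10,000 iterations.

The multilayer model couples the four band networks of one (recording,
class) pair as a multiplex supra-adjacency: node-layer (i, α) ↦ row α·n + i,
diagonal blocks the band adjacencies, off-diagonal blocks
`interlayer_weight × I` for every layer pair (categorical replica coupling —
all bands operate simultaneously, so each electrode's replicas are mutually
linked; weight 1 by default, config-exposed).  Multilayer metrics are the
single-layer ones on the supra-graph, aggregated per electrode: degree sums
intra-layer degrees (replica edges excluded), PageRank sums replica
occupancies (teleportation uniform over all N·L node-layers), eigenvector
centrality sums the leading supra-eigenvector over replicas and renormalizes,
k-core takes the maximum replica coreness (interlayer edges included; for
non-binary weights the unweighted supra-graph is used, with a warning).  With
one layer every metric reduces exactly to its single-layer counterpart; for
identical layers the supra eigenvector factorizes as ones_L ⊗ u with
eigenvalue λ₁ + (L−1)·w — both facts are tested.

## Statistics chain

Sampling unit: one value per (recording, class, electrode); n = 18 per class
at study scale.  α = 0.05 throughout, config-exposed.

1. **MANOVA** per (metric, band): the 22 electrodes' values are joint
   dependent variables, class the 4-level factor; Pillai's trace with its F
   approximation (robust to covariance heterogeneity).  A Shapiro–Wilk screen
   over the (electrode, class) groups is run first but is *advisory*: metrics
   on binarized networks take few integer values at n = 18 and reject
   routinely, while Pillai's trace tolerates moderate non-normality, so the
   rejection fraction is recorded in the report rather than used to discard
   the metric.  A metric is excluded only when its statistic is genuinely
   incomputable — a singular within-class covariance, the typical fate of the
   near-constant k-core.  Two benign singularities are reduced rather than
   fatal, with a note: electrodes with zero within-class variance are dropped
   (error if most electrodes are constant), and exact linear dependencies
   among responses (PageRank sums to one across electrodes, so its residuals
   are exactly rank-deficient) are reduced to a maximal independent response
   subset by pivoted QR.
2. **Per-electrode ANOVA + Games–Howell** for metrics passing the MANOVA
   gate: one-way ANOVA per electrode; at significant electrodes all six
   pairwise class contrasts via t = |m_a−m_b| / √(s_a²/n_a + s_b²/n_b) with
   Welch–Satterthwaite df, p from the studentized-range distribution with
   k = 4 at t·√2 (identical to Welch's t-test when k = 2; tested to 1e−9).
   Pairs where both groups are constant have an undefined statistic; the
   chain reports them in the limit sense (identical constants: p = 1,
   disjoint constants: p = 0) with a note, while the standalone operation
   raises.
3. **Pooled ANOVA and paired t / Benjamini–Hochberg** for the multilayer
   distribution comparisons: values pooled over electrodes per class; paired
   t-tests across all six class pairs, paired by (recording, electrode), BH
   step-up adjustment capped at one; zero-variance differences are reported
   as p = 1 with a warning.
4. **Key electrodes**: an electrode is a key electrode when it has at least
   one significant Games–Howell contrast in ≥ 2 different metrics' chains.

## Clustering

One sample per (recording, class): the concatenation of the four multilayer
metrics over 22 electrodes (88 features, 72 samples at study scale).  LDA
projects to 3 dimensions (4 classes admit at most 3 discriminants; the SVD
solver tolerates the singular within-class scatter of 72 × 88 data, with a
shrinkage fallback); k-means with k = 4 (10 seeded restarts, best inertia)
clusters the projection; agreement with the true classes is scored by
completeness, 1 − H(K|C)/H(K), with the convention 1 when H(K) = 0 (a single
cluster — a known degeneracy of the score, reported as is).  LDA is fit on
the samples it projects; the unsupervised step is the clustering.  Because
cluster-to-class assignment differs between runs and thresholds, the
confusion table is reported rather than a fixed mapping.

## Synthetic study design

The generator emulates the reference MI protocol: 18 recordings (9 subjects
× 2 sessions), 4 classes, 72 trials per class in randomized order, 22
electrodes (10-10 montage), 250 Hz, paradigm trials of 6 s with sources
active in t = 3.0–6.0 s and the analysis window at 3.5–5.5 s.  Signals are
sums of band-limited Gaussian sources (white noise band-pass filtered with a
zero-phase forward-backward order-4 Butterworth at the band edges, so
coupled channels stay exactly aligned) on independent unit-variance channel
noise.  Amplitudes are arbitrary units; coherence is scale-invariant.

Two source types:

* **pair couplings** add one shared source to two electrodes with a common
  weight — the primitive for planting a specific edge;
* **group couplings** mix one shared rhythm into a whole electrode set with
  per-electrode weights redrawn each recording.  This is what produces the
  dense, graded coherence structure of real EEG: with many *pairwise*
  sources stacked on a channel, every individual coherence is diluted toward
  zero (a pair sharing one of q equal-power sources has coherence ≲ 1/q²),
  whereas one large-scale rhythm shared by a group yields high mutual
  coherence graded by the mixing weights.

A mixing weight w maps to band coherence approximately as
`coh(i,j) = [w_i²/(w_i² + r)] · [w_j²/(w_j² + r)]` with
`r = noise_sd² · bandwidth/(fs/2)` (≈ 0.136 for β at unit noise); the
monotonicity of this mapping is asserted in the tests.

Defaults (the study conditions; chosen once from a pilot of the coherence
histograms and threshold stability, then frozen): class-independent group
rhythms in every band (strength 0.62 ± 0.42 across chained, overlapping
groups of ~7 electrodes — the overlap keeps each band layer connected, the
wide jitter makes edge membership after thresholding vary between
recordings, so every electrode has within-class metric variance, as
between-subject variability produces in real data); a weaker β group over
the designated key electrodes C3, CP2, P2, POz plus two bridge electrodes
(0.55 ± 0.15 — weaker so the planted source dominates their spectra; the
bridges gain variance but no class contrast, since they lose two edges in
*every* class); and one planted β pair per class among the key electrodes
(strength 0.9 ± 0.05): 1 → C3–CP2, 2 → C3–POz, 3 → P2–POz, 4 → CP2–P2.  The
unknown real-data SNR is a free design choice (noise_sd = 1), exposed in the
config.

What the synthetic study does *not* emulate: volume conduction and head
geometry, artifacts (EOG/EMG), non-stationarity within trials, 1/f spectra,
and subject-specific montage idiosyncrasies.  Passing the recovery tests
therefore shows that the pipeline's inference chain is sound under its own
modeling assumptions — planted class-specific coupling is found, absent
coupling is not — not that real MI datasets will yield the same electrodes.

## Scale of the shipped experiments

The test suite and the acceptance script run the full 18-recording study per
replicate; recovery statistics use 20 replicate seeds in the tests and 5 in
the acceptance script, and clustering completeness uses 10 seeds — sizes
chosen so the whole suite completes in minutes on one CPU while leaving the
per-study design at protocol scale.

## Known limitations

* The Otsu histogram includes the 22 unit diagonal entries; on sparse
  synthetic matrices this can attract the threshold toward the diagonal mode
  when too few off-diagonal weights are elevated.  The default study places
  enough elevated mass that the threshold settles between the noise floor
  and the coherent cluster.
* The MANOVA-on-electrodes design is undefined for compositional metrics
  without response reduction (see above); the reduction changes the test's
  dimensionality and is always disclosed in the report note.
* Games–Howell p-values use the studentized-range tail, which is slightly
  conservative at very small within-group variances.
* `completeness = 1` for the all-one-cluster labeling; it should be read
  together with the confusion table.
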
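# Methods notes

This note records the modelling and numerical decisions behind
`meginet`, what the synthetic cohorts do and do not emulate, and the
known limitations of each stage.

## Signal model of the synthetic cohorts

Each subject's recording is built at the native rate (600 Hz) as a sum
over the four analysis bands. Per band f the latent structure is one
*shared* narrowband source plus one *private* narrowband source per
sensor, all produced by 4th-order Butterworth band-pass filtering of
white Gaussian noise around the band center (θ 6 ± 1 Hz, α 10 ± 1.75 Hz,
β 20 ± 3.75 Hz, low-γ 45 ± 7.5 Hz — half the nominal dyadic bandwidth,
so each source sits comfortably inside its wavelet scale). The sensor
signal is

    x_i(t) = Σ_f [ a_{f,i,trial} · s_f(t) + p_{f,i}(t) ] + σ ε_i(t)

with white sensor noise of SD σ (`noise_sd`, default 0.3 against
unit-variance sources).

Generator knobs and their mechanisms:

* **`coupling_scale` (per band, default 1.0 control / 1.5 patient).**
  The shared-source loading vector is a spatially smoothed random
  pattern: a standard normal vector convolved with the kernel
  exp(−d/λ), λ = 0.4 × layout radius, rescaled to unit RMS and
  multiplied by `coupling_scale`. Nearby sensors therefore receive
  similar loadings, strong connections are preferentially short-range
  (which is what mean connection distance and Rentian scaling measure),
  and the knob directly controls inter-sensor NMI and hence network
  strength. An early variant that loaded only sensors near a random
  anchor point left most of the array uncoupled and was discarded.
* **`regularity` (per band, ∈ [0,1], default 0.3 / 0.55).** The
  analytic envelope of every source in the band is raised to the power
  1 + 3·regularity (then re-standardized), concentrating the
  within-trial band energy into transient bursts. Under the
  time-domain energy entropy used here (see below), concentration is
  what *lowers* H; flattening the envelope would raise it. The knob is
  therefore implemented as envelope concentration so that the
  patient-like condition (larger value) reproduces the lower-entropy /
  higher-strength phenotype the analysis is designed to detect.
* **`xfreq_coupling` (per band pair, default θ→low-γ 0.8 / 1.2).** The
  shared θ envelope (normalized to unit mean) multiplies the amplitude
  of *every* low-γ source, shared and private, raised to the gain as a
  power. Modulating only the shared γ source produces a dependence too
  dilute for a 216-sample histogram MI to see once private sources are
  mixed in; array-wide modulation is both physiologically natural
  (global excitability waxing with the slow rhythm) and reliably
  detectable.
* **`trial_jitter` (default 0.1 / 0.2).** Two components per trial: a
  global gain 1 + 2·jitter·z_t (clipped at 0) on the shared loadings,
  which swings individual trials between strongly structured and
  noise-dominated connectivity — a pure topology effect, since
  fixed-density thresholding cancels overall scale — plus spatially
  smoothed zero-mean pattern noise of relative SD `jitter`. Together
  they control the coefficient of variation of graph diagnostics across
  trials.

Defaults emulate the study conditions the pipeline assumes: 2 groups of
14 subjects, a 275-sensor layout on a unit hemisphere (Fibonacci spiral
with seeded jitter), 6 blocks × 11 stimulus–response periods → 66
epochs of 1800 ms at 600 Hz. Seeds derive from a single master seed via
`numpy` SeedSequence with fixed per-subject keys, so cohorts are
bit-reproducible and subject streams are independent.

**What the generator does not emulate:** MEG forward physics (lead
fields, gradiometry), 1/f background spectra, eye-blink or movement
artifacts, volume conduction, or any anatomically meaningful spatial
organisation. Passing the directional-recovery tests therefore shows
that the *pipeline* responds correctly to known structure, not that
real cortical dynamics behave like the generator.

## Spectral stage

Resampling 600 → 120 Hz uses polyphase filtering (`resample_poly`),
which applies the anti-alias filter implicitly. The MODWT is
implemented directly via the periodic (circular) pyramid algorithm with
filters taken from PyWavelets and rescaled by 1/√2 per level: circular
boundaries give length preservation and an exact energy identity
(‖x‖² = Σ_j ‖W_j‖² + ‖V_J‖², verified to 1e−8 relative in the tests),
which matters because 1.8 s epochs make boundary effects non-negligible
at scale 4. "Daubechies 4" is read as the 4-tap filter with two
vanishing moments (PyWavelets `db2`); the 8-tap `db4` reading is a
one-switch option, and both satisfy the same identities.

## Entropy

The paper-style "Shannon wavelet entropy" is computed per band, sensor
and trial from the relative wavelet energy over the 216 time points:
p_k = w_k²/Σ w², H = −Σ p log₂ p (bits, 0·log 0 = 0). This is the
variant that yields a per-band quantity bounded by log₂ 216 ≈ 7.755
bits, scale-invariant, maximal for constant-magnitude series and zero
for a single nonzero sample. An equal-width amplitude-histogram variant
is available behind `method="histogram"`; `normalized=True` divides by
the ceiling. All-zero series raise rather than return a value.

## Connectivity

The MI estimator is a plug-in equal-width histogram with 8 bins per
series (≈ √216/2), chosen because 216 samples cannot support fine
binning; quantile binning (invariant to monotone transforms) is an
option. No small-sample bias correction is applied — the independent-
noise bias at these settings is ≈ 0.064 NMI units and is common to all
pairs; trial ensembles and fixed-density thresholding absorb it.
Strehl–Ghosh normalization (geometric mean of marginal entropies) maps
into [0,1]; constant series have zero marginal entropy and are assigned
NMI 0 with a warning. Inter-frequency MI is asymmetric in the sensor
roles; stored matrices are symmetrized by the arithmetic mean (the raw
matrix is retained) and the diagonal — same-sensor cross-band coupling
— is excluded so intra- and inter-band networks share the no-self-loop
convention. Whole-matrix computation vectorizes the joint histograms of
all sensor pairs into one matrix product over one-hot bin indicators
and is numerically identical to the scalar estimator.

## Networks and diagnostics

Cumulative thresholding takes the ⌊κ·N(N−1)/2⌋ largest upper-triangle
weights; ties (measure-zero for continuous MI, but possible in
synthetic fixtures) break lexicographically by (i,j) for determinism.
The sweep shares one ranking, so edge sets are nested and each realized
density is within one edge of κ. κ = 0 is excluded (empty graphs). ER
nulls are exact-edge-count G(n, M) ensembles of 66 graphs (one per
trial network), matched to each density.

Fragmentation conventions: path length averages over connected ordered
pairs; global efficiency uses 1/∞ = 0; diagnostics whose preconditions
fail are NaN ("missing"), never zero, and missingness propagates into
trial averages by NaN-aware means.

* **Modularity** uses greedy CNM-style agglomeration with seeded random
  tie-breaking, alternated with single-node moves and community-pair
  merges until neither improves, best of 10 restarts (half of them from
  singleton starts). On all connected graphs with ≤ 6 nodes (and
  sampled 7–8-node graphs) it attains the exhaustive-partition optimum.
* **Hierarchy** fits log mean C(k) vs log k over degree classes with
  k ≥ 2 and C(k) > 0; a single usable class is a flat profile (β = 0),
  no usable class is missing.
* **Synchronizability** is λ₂/λ_max of the combinatorial Laplacian of
  the largest connected component (≥ 3 nodes), bounded in (0,1] with
  K_n = 1; the reciprocal eigenratio convention is an option.
* **Robustness** records the largest-component fraction intact and
  after each of the first N−1 removals, and averages those N values
  (so K_n gives Σ_{m≤N} (m/N)/N). Targeted attack removes the
  highest-current-degree node (ties by index); random attack averages
  20 seeded orders.
* **Rent's exponent** samples axis-aligned boxes in the layout's native
  dimensionality, uniform in scale (half-widths 5–50% of the span) and
  constrained inside the bounding volume — boxes spilling past the hull
  under-count boundary edges and bias the slope down. Boxes with
  2 ≤ n ≤ N/2 interior nodes and ≥ 1 crossing edge enter the log–log
  fit; fewer than 30 usable boxes yields missing. A 16×16 lattice
  recovers ≈ 0.44, consistent with the 2-D perimeter law 0.5 within the
  residual hull-face bias.
* **Betweenness** is Brandes' algorithm, normalized by (N−1)(N−2)/2.

## Statistics

Permutation p-values use the add-one convention (1 + c)/(n + 1), so the
smallest attainable p is 1/(n+1). Both the scalar and the functional
test reduce the pooled sample to a canonical order and permute the
smaller group's labels, making p exactly invariant under exchanging the
groups. The FDA statistic is the integrated (summed) absolute
difference of group mean curves over the cost grid (a supremum variant
is available); grid points missing in an entire group drop out
pairwise. Holm–Bonferroni and Benjamini–Hochberg corrections are
delegated to `statsmodels` and are cross-checked against their
step-down/step-up definitions in the tests. The FDR is applied jointly
over the full (network kind × diagnostic) grid.

The CV uses the sample (n−1) standard deviation over trials, per cost,
averaged over costs; zero means are missing. Hierarchy and
assortativity are excluded from the CV analysis because their values
sit near zero, leaving 10 diagnostics — with 10 network kinds this
gives the repeated-measures design with degrees of freedom 1 (group),
9 (band), 9 (diagnostic) and 81 (band × diagnostic). The RM-ANOVA is a
classical unadjusted univariate sums-of-squares decomposition with one
between-subject factor and two within-subject factors, each within
effect tested against its own effect-by-subject(group) stratum; it
reproduces R's `aov` with `Error(subject/(band*diag))` exactly on a
fixture frozen in the tests. No sphericity correction is applied, to
mirror the classical table layout. Entropy–strength fits are ordinary
least squares of strength on entropy per group and band, at subject
level (sensor- and trial-averaged) and at sensor level.

## Problem sizes in the validation suite

The test suite exercises the full protocol geometry (66 trials, 216
samples, 10 matrix kinds, the 120-cell grid) on small cohorts (2–3
subjects per group, 8–16 sensors) and coarse cost grids, and runs the
Monte-Carlo calibrations at reduced sizes chosen to keep each run in
minutes on one CPU: the type-I calibration uses 200 replicates of an
8 + 8 subject, 16-sensor, 20-trial null cohort with the θ-band
global-efficiency FDA cell (199 permutations); parameter-recovery
checks use 20 replicates of 3–8 subjects per condition. The exhaustive
graph-diagnostic oracle covers every connected graph on ≤ 7 nodes (996
graphs) plus seeded 8-node samples; exhaustive modularity enumeration
covers all connected graphs on ≤ 6 nodes plus sampled larger ones.

## Known limitations

* The plug-in MI is biased upward at 216 samples; all comparisons are
  therefore *relative* (between groups, trials, or conditions at
  matched settings), never absolute coupling strengths.
* Greedy-plus-refinement modularity is exact only where verified
  exhaustively; on large graphs it is a lower bound on Q.
* Rent's exponent retains a small downward bias from boxes flush
  against the hull faces.
* The generator's group contrasts are caricatures: one shared source
  per band, stationary within trials, Gaussian statistics. Effect
  sizes recovered from it say nothing about clinical effect sizes.
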
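# Methods

Conventions used everywhere: time in seconds, positions in cm, angles in
radians in [0, 2π), track bins 0-based, time intervals half-open
`[start, end)`. Frame rate defaults to 20 fps.

## Synthetic sessions

The generator emulates a mouse freely exploring an elevated O-shaped
circular track (50 cm outer diameter, 5 cm lane) for a 15-minute
session, and renders ground-truth calcium traces so that every analysis
stage can be validated by parameter recovery.

**Trajectory.** A run-and-reverse walk along the track centerline
(radius 22.5 cm): constant tangential speed (default 3 cm/s, which makes
one lap take ~47 s and a 15-min session cover ~19 laps), with direction
reversing as a Bernoulli event of probability `turn_prob` per second
(default 0.1; the distribution of real lap lengths is not known, so this
is a free parameter). Radial position wanders inside the lane as a
clipped AR(1) jitter — downstream analysis only consumes the angular
coordinate, so the radial detail is cosmetic. Only the angle model
matters because the analysis is explicitly omnidirectional.

**Tuning.** A place cell fires as an inhomogeneous Poisson process whose
rate is a von Mises bump, `rate(θ) = r_out + (r_in − r_out) ·
exp(κ(cos(θ − μ) − 1))` with `κ = 1/σ²` (σ = `tuning_width`, default
0.35 rad ≈ 1.1 track bins). Any unimodal bump would serve; von Mises is
the natural circular choice. Delayed tuning is modelled by an
`onset_time`: before it the cell fires everywhere at the spatial mean of
its tuned rate (`r_out + (r_in − r_out) e^−κ I₀(κ)`), so the total event
budget does not change at onset — only its spatial arrangement does.
This produces a known ground-truth specialization visit for latency
recovery.

**Traces.** Every spike adds `A(1 − e^−Δ/t_on) e^−Δ/t_off` (defaults
t_on = 0.1 s, t_off = 0.6 s, the fast-rise/slow-decay shape of GCaMP-family
transients); amplitudes are lognormal with mean 1 and CV 0.3 (positive
support, simple); transients add linearly on a zero baseline; i.i.d.
Gaussian noise is added. `KernelParams.with_snr(s)` sets the noise sd to
(realized mean peak)/s, so "SNR 10" means peak:noise = 10.

What the generator deliberately does not model: baseline drift and
bleaching, shared (neuropil/motion) noise across cells, bursting or
refractory spike statistics, direction-specific fields, reward or
behavioural states, and raw-movie/ROI-level artifacts. Passing the
recovery suite therefore demonstrates correctness of the algorithms
under clean conditions, not robustness to every real-data pathology.

## Event detection

The detection threshold is `median + k·MAD` of the *original* trace (raw
MAD, no 1.4826 consistency factor — the integer multipliers 4/5 are
conventionally applied to raw MAD), computed once; re-estimating on
residuals would drift the threshold downward after each subtraction.
Slow sensors (GCaMP6s/NCaMP7/FGCaMP7) use k = 4 and a 0.5 s lower bound
on t_off; the fast GCaMP7f uses k = 5 and 0.2 s.

At each upward threshold crossing the model `b + A(1 − e^−Δ/t_on)
e^−Δ/t_off` is least-squares fitted over a window from 0.5 s before the
crossing to 4·t_off_floor after it. The free constant offset `b`
(initialised at the trace median) matters: without it, the baseline
elevation left by neighbouring transient tails biases the fit and the
goodness of fit drops below threshold for a substantial share of true
events near SNR 8. Only the kernel part is subtracted from the working
trace, so the event amplitude `A` is never conflated with the local
baseline. Bounds: t_off ∈ [t_off_floor, 20 s], t_on ∈ [1 ms, 2 s],
A > 0; initial values t_on = 0.1 s, t_off = t_off_floor, A = segment
max − median.

If the window contains a second prominent peak (found on a 3-frame
boxcar-smoothed segment, prominence ≥ max(half threshold height,
3·MAD)), the fit window is truncated at the valley between the peaks so
that overlapping transients (0.3 s apart in the benchmark) are fitted
and subtracted sequentially. Goodness of fit is R² over the (possibly
truncated) window; events with R² ≥ 0.8 (inclusive) are accepted,
subtracted, and the trace re-scanned until a full pass accepts nothing.
Crossings within 2 frames of an already fitted onset are skipped to
prevent duplicate fits. A constant trace yields no events; a zero-MAD
trace triggers a warning and a degenerate threshold.

Measured on 1000 isolated transients at SNR 8 with ≥ 3·t_off gaps:
sensitivity ≈ 0.99, FDR < 0.01, median onset error ≈ 0.2 frames (the
acceptance script recomputes these numbers at every run).

## Place fields, selectivity, latency

Event positions (angular position interpolated at t₀ on the unwrapped
angle) are histogrammed into 20 sectorial bins, smoothed with a circular
Gaussian (σ = 1.25 bins, wrap-around), and divided by the maximum.
Occupancy normalisation is deliberately not applied: the criterion for a
field is repeatable per-visit firing, not an occupancy-corrected rate
map. Runs of bins above 0.5 are peaks; the field is the run widened by
one bin per side, its centre the circular centroid of the run weighted
by the smoothed map; fields wider than half the track (> n_bins/2) are
discarded, as is the degenerate all-above-threshold map.

Attendances are maximal in-field intervals of the trajectory;
out-of-field excursions shorter than 1 s (configurable) do not split a
visit, because positional jitter at bin edges would otherwise fragment
epochs. Each epoch carries its two flanking out-of-field intervals;
adjacent fields may share flank events — scores are per-field
quantities. The per-visit selectivity score is (events in epoch)/(events
in epoch + flanks); if the cell fired nowhere in that span the visit is
*scoreless* and excluded from the smoothed sequence (a silent lap is
evidence of inactivity, not of non-selectivity) while still counting
toward visit numbering.

The score sequence is smoothed with a truncated Gaussian (σ = 1 visit,
radius 4σ, symmetric/reflect padding — implemented explicitly so its
convention is fully specified); visits with smoothed score > 0.5 are
*relevant*; the field is confirmed iff ≥ 3 consecutive scored visits are
relevant. `n_spec` is the number of attendances (including scoreless
ones) strictly before the first such run; `t_spec` is the entry time of
the run's first visit (the start, not the end, of that visit — the
moment specialization is first expressed). Smoothing is monotone in each
raw score, so raising any score can only add relevant visits.

## Cross-session comparison

Only cells with exactly one field in both sessions enter shift
statistics; cells that are a place cell in a single session are reported
as a separate transition category. Shifts are signed minimal circular
differences in bin units (bin 1 → bin 19 is −2, not +18).

The retention test bins shifts into the track's own signed unit bins and
compares the histogram to a zero-mean normal truncated to the circular
support, sd estimated from the observed shifts, with a chi-square GoF
statistic (dof = bins − 2). Adjacent bins are merged only until each
expected count reaches 0.5: the textbook ≥ 5 rule erases exactly the
tail bins where a dispersed (remapped) distribution departs most from
the peaked null, and with it most of the test's power (uniform-shift
rejection drops from 92% to 86% at n = 100). Calibration at n = 100,
1000 repeats: normal(0, 1 bin) shifts retained 95%, circular-uniform
shifts rejected 92%. Fewer than 10 shifts flags the result underpowered;
identical shifts (sd = 0) short-circuit to a degenerate point-mass
verdict.

Two decision conventions are exposed. The default, `conventional`,
calls the map retained when the test *fails to reject* normality
(p > α) — the direction in which a goodness-of-fit p-value is
informative. The `inverted` convention (retained when p < α) mirrors a
phrasing occasionally seen for this test in the literature; it is
provided for comparability but cannot be calibrated, so the default is
the conventional one. n_spec shifts between retained and remapped groups
are compared with an unpaired two-sample t-test.

## Population geometry

The activity fed to the embedding is the raw trace matrix (not
binarized events) of cells with ≥ 5 events, block-averaged in
non-overlapping windows of w frames (default w = 8, i.e. 0.4 s at
20 fps; w ∈ {2, 4, 8} give RVs within 0.1 of each other on stationary
synthetic sessions). Teff = ⌊T/w⌋ windows; a window's position is the
mean (x, y) of its frames, its angle the circular mean.

The similarity graph connects each window to its k nearest neighbours by
Euclidean distance in cell space, OR-symmetrized (k is thus a lower
bound on degree), binary, no self-loops. Traces are not z-scored per
cell by default (configurable). If the graph is disconnected, the
largest component is kept provided ≤ 5% of nodes are lost; otherwise
the reduction fails with an "increase k" error. When k is not given,
the smallest of {5, 10, 15, 20, 30} that passes is used — k should be
as small as the graph's integrity allows, since large k breaks the
local-linearity premise of the embedding.

Laplacian eigenmaps solve `L v = λ D v`, `L = D − A`. Graphs up to 600
nodes use a dense generalized symmetric solver; larger ones a
shift-inverted (σ = −10⁻³) Lanczos solve of the normalized Laplacian
`I − D^(−1/2) A D^(−1/2)`, mapped back via `v = D^(−1/2)u` (the two
routes agree to 10⁻⁸ on random connected graphs; the cycle graph
reproduces its closed-form spectrum `1 − cos(2πj/n)`). A single
numerically zero eigenvalue is verified (a second one means the
connectivity contract was violated) and its constant eigenvector is
dropped; eigenvectors are D-normalized with the sign fixed by the
largest-magnitude component.

Residual variance is `1 − ρ²` of the Pearson correlation between the
strictly-upper-triangular pairwise-distance entries of the physical
window positions and of the embedding — 0 for any rotated, translated,
uniformly scaled copy of the trajectory, ≈ 1 for independent noise.
PCA (column-centred SVD projection) is the linear baseline; on synthetic
ring sessions with heterogeneous peak rates its RV is consistently
higher than the eigenmap's. Embedding order is scored with a circular
*rank* correlation (angles replaced by uniform circular ranks): the
eigenmap fixes the ring only up to rotation, reflection, and an
order-preserving angular warp, so plain angle-to-angle circular
correlation penalizes warping that the rank statistic correctly
ignores; its absolute value is reported.

The sliding-RV variant recomputes graph + embedding + RV on 250 s
windows with a 25 s stride (the stride is not externally constrained;
10% of the window keeps the series smooth at acceptable cost). The
unselectivity curve is 1 − (mean over fields of the per-visit raw
scores linearly interpolated to the frame grid), smoothed with a 250 s
running average; cosine similarity compares per-animal unselectivity
and RV profiles.

## Validation scales and numerical choices

The recovery studies run at the study scale — 15-min sessions, 20 fps,
20 bins — with population sizes chosen so each check is decisive yet
quick: 1000 transients for the detector benchmark; 100 cells (contrast
10:0.1 events/s, SNR 10) for field recovery; 50 delayed-onset cells for
latency; 300 tiling cells for ring recovery; 10 seeds × nested
25–300-cell subsamples for the cell-count trend; 1000 repeats × 100
shifts for retention calibration. At 10 events/s in-field, individual
transients fuse into a plateau, so the field/latency studies run on the
generator's ground-truth event times; the detector is validated
separately on resolvable transients. Degenerate inputs are handled
explicitly rather than by exception: constant traces (zero MAD),
eventless cells, silent laps, all-above-threshold maps, disconnected
graphs, and sd-zero shift sets each have a defined, documented outcome.

## Known limitations

No out-of-sample extension of the embedding (a new activity vector
cannot be projected without rebuilding the graph); no spike-count
deconvolution or ΔF/F baseline-drift estimation; no direction-specific
or cue/border-cell analysis; cross-session cell identity is consumed as
an input table, never inferred. The spectral solve scales as ~O(n^2.4–3)
with the number of windows, which bounds practical session lengths.
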
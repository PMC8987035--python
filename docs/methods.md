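# Methods

This note documents the models behind `lowvoltcount`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that make results reproducible.

## Coordinate and rendering conventions

Pixels are indexed 0-based as `(x, y)` with `x` the column; a pixel's centre
sits at integer coordinates, and arrays are indexed `[y, x]`. Event
positions are continuous in this frame. When rendering at super-resolution
factor `s`, a position `x` lands in output column `⌊x·s⌋`, i.e. sub-pixel
`j` spans `[j/s, (j+1)/s)` native units; patterns are deposited at native
granularity (each member pixel's mass goes to the centre sub-pixel of its
`s×s` block) because sub-pixel pattern placement is not defined by the
counting model. All Fourier-space frequencies are in cycles/pixel of the
stored grid, so Nyquist is 0.5; with a known pixel size they convert to 1/Å.

## Cluster detection

A raw frame is convolved with a negated Laplacian-of-Gaussian kernel
(default σ = 0.8 px on a 3×3 support — matched to single-pixel-scale
bumps), the noise of the convolved frame is estimated robustly as
1.4826 × MAD, and pixels above `k·σ` (default k = 4) are grouped by
8-connected component labelling. The threshold is applied to the
*convolved* frame: a zero-sum kernel has no other purpose, and thresholding
raw values would make the kernel irrelevant. Cluster pixel values are raw
values minus the frame median, floored at 10⁻⁶ so that negative pattern
exponents remain finite. Clusters touching the frame border are discarded:
truncated charge biases every position estimator. Two electrons arriving
adjacently within one frame merge into one cluster — coincidence is not
resolved, as in any counting camera; the generator's default dose rate
(0.01 e/px/frame) keeps this rare, and a warning fires in the coincidence
regime.

One consequence of the zero-sum kernel worth knowing: it rejects smooth,
broad intensity blobs by construction. Only deposits with pixel-scale
structure are detected, which is also why the synthetic backscatter deposit
is modelled as a compact second cloud rather than a diffuse haze (below).

## Counting filters

MCF/PVF/GCF place each event at the value-weighted centroid, the
maximum-value pixel, or the unweighted mean of member pixels. The PVF tie
rule (nearest tied pixel to the mass centre, then lexicographic by (y, x))
is a deterministic convention chosen here; ties are measure-zero on real
data. PCA normalizes `v_i^pow` over the cluster; every exponent in
{0, ±0.25, ±0.5, ±0.75, ±1, ±1.25, ±1.5, ±2, ±3} is accepted, with the
per-class defaults pow = 1 (small/medium) and pow = 0 (large) that proved
best at low voltage. Hybrid is MCF for small/medium plus uniform patterns
for large clusters, no further weighting. WPF renders MCF points for
small/medium and PVF points (weight bit set) for large clusters, multiplies
the large-cluster partial image in Fourier space by the radial profile
`w(u) = √(SNR₂/SNR₁)·√(NPS₁/NPS₂)` (subscript 2 = the weighted population),
and sums; `w(0)` is forced to 1 so the total dose is conserved. Every
method normalizes each electron's contribution to 1, so unweighted counted
images sum to the event count exactly.

## Quality metrics

FRC uses one-Fourier-pixel shells (`Re Σ F_a F_b* / √(Σ|F_a|² Σ|F_b|²)`),
excluding DC, up to Nyquist. `SNR = 2·FSC/(1−FSC)` is capped at
FSC = 1 − 10⁻¹²; FSC exactly 1 raises. The NPS is the radially averaged
periodogram `|F(img − mean)|²/N_pix` averaged over realizations, so ideal
Poisson point counting gives a white NPS equal to the dose in
events/pixel, and `DQE = fraction · MTF² · dose / NPS` is 1 at DC for an
ideal counter with no extra normalization constant.

The slanted-edge MTF fits the edge line from per-row edge positions
(gradient-centroid of a lightly smoothed profile inside a ±8 px window
around a coarse crossing — robust to counting noise), requires a fit
R² ≥ 0.2 (an untilted edge is rejected: the method needs sub-pixel phase
diversity), bins pixels by signed distance into a 4× oversampled ESF,
differentiates, and evaluates the LSF spectrum by direct DFT. The binning
box and the finite difference each impose a sinc(uΔ) transfer that is
divided out; with Δ = ¼ px the corrected pixel-aperture MTF is accurate to
0.1% at Nyquist and a Gaussian-blurred edge matches its closed form to
better than 2% wherever MTF ≥ 0.05. On noisy counted stacks the fitted
edge angle is good to a few tenths of a degree; on clean edges it is exact
to < 0.01°.

SNR-gain fits regress the per-shell SNR ratio of two curves on `u/Nyquist`
over a window (default 0.30–0.80) and report the line at 0.5 and 1.0
Nyquist; `fit_hi > 1` is meaningful only for super-resolution grids whose
shells extend beyond the native Nyquist.

## Optics

The electron rest energy is fixed at 510 998.95 eV and the wavelength is
`12.2643/√(V(1 + 0.978476×10⁻⁶ V))` Å, so all derived numbers are
bit-reproducible. The chromatic envelope uses
`δ = C_c·√(4(ΔI/I)² + (ΔE/V)² + (ΔV/V)²)` (C_c converted mm → Å) and
`E(u) = exp[−½(πλδ)²u⁴]`; ΔI/I and ΔV/V default to 0 — the energy-spread
term dominates for a field-emission source, and both are user-settable.
SNR depression between two optical configurations multiplies per shell by
`(E_new/E_ref)²` at the same physical frequency; the FSC companion converts
through the SNR relation and back. The damage regression is plain OLS of
relative damage on 1/β² with coefficient standard errors.

## Backscatter Monte Carlo

Single-scattering trajectories: exponential elastic free paths from the
relativistic screened-Rutherford total cross-section with Joy's screening
parameter `α = 3.4×10⁻³ Z^0.67 / E[keV]`, polar angles from the closed-form
inverse CDF, and continuous energy loss between events — Berger–Seltzer
relativistic collision stopping above 10 keV, Joy–Luo-modified Bethe below
(the two agree to ~2% at the seam). Termination: re-exit through the top
(backscattered, exit radius recorded from the straight-line crossing),
bottom exit (transmitted), lateral escape or energy < 0.5 keV (absorbed),
plus an exact pruning — an electron whose residual CSDA range cannot reach
either surface is absorbed immediately. Steps are capped at 20% of the
current energy's CSDA-equivalent so the continuous-slowing-down
approximation holds. The simulator is vectorised over electrons with one
seeded generator per run (serial execution; no parallel ordering issues)
and is bit-reproducible.

Validation anchors, none of them tuned: collision stopping at 100 keV in
silicon is 0.762 keV/µm against ESTAR's ≈ 0.764; the bulk backscatter
coefficient at 30 keV is 0.156 against the experimental ≈ 0.15; and the
40-µm slab at 120 kV gives 14.8 ± 0.2%, with a 120/300-kV ratio of ≈ 6.
Known model limitations: exact Mott cross-sections would shorten
backscatter excursions (this model's median exit radius at 120 kV/40 µm is
≈ 30 µm, larger than Mott-based simulations suggest) and raise the 300-kV
coefficient somewhat; and back-thinning to 10 µm at 120 kV lands within a
factor of two of the 300-kV/40-µm value here rather than exactly on it.

## Synthetic frames

The generator emulates the statistics that matter to counting: Poisson
arrivals at uniform (or specimen-modulated) continuous positions;
integrated-Gaussian charge clouds whose amplitude follows a log-normal with
shape 1.1 around a 150-count mean (a positive, heavy-tailed stand-in for
the Landau energy-loss distribution) and whose width follows a log-normal
(shape 0.6, median 0.5 px) correlated with amplitude (ρ = 0.8 — larger
deposits spread wider); a displaced secondary deposit for a fraction of
events, representing backscattered-electron re-entry, modelled as a compact
(σ = 0.7 px) cloud at 45% of the primary amplitude offset by an
exponential radius (mean 2 px) — compact because the detection kernel
rejects diffuse blobs, and because the re-entering electron deposits
track-like charge just as the primary does; Gaussian read noise (σ = 1
count) and an optional gain map. Ground-truth positions, frame indices and
backscatter flags are recorded; border events are excluded from scoring,
mirroring border-cluster discard. An optional minimum-separation mode
thins coincident arrivals so the detection loop can be tested exactly.

`tune_to_class_fractions` searches (cloud width, backscatter probability,
amplitude) by coarse grid plus coordinate descent, with common random
numbers across evaluations, to match target small/medium/large fractions.
The shipped per-voltage presets were derived this way against the measured
mixes (33.8/38.6/27.6% at 120 kV, 59.0/30.2/10.8% at 200 kV,
60.2/31.9/7.9% at 300 kV) and reach them within 0.02 L1; the recovered
trends are physical — widest clouds and most backscatter at 120 kV, least
at 300 kV. The preset backscatter probability is an *effective* blob rate:
it absorbs every mechanism that attaches displaced charge to a cluster
(true backscatter re-entry but also in-sensor lateral track wander), which
is why the 120-kV preset uses a value far above the ~15% physical BSE
coefficient.

For frequency-resolved comparisons the generator accepts an intensity map:
events arrive with density proportional to a "specimen" pattern, so two
disjoint halves of the counted events share its structure and their FRC
measures counting SNR exactly as half-set FSC does in reconstruction
pipelines. The filter-ordering experiments use cosine probe gratings
(three directions per target frequency) that concentrate signal power in
chosen shells — a test-grating design that makes per-shell FRC
interpretable at desk scale. The backscatter-ordering study condition
(probability 0.6, full-amplitude blob, 3-px mean offset, narrowed primary
spreads) isolates the mechanism in which large clusters are
backscatter-dominated, as they are on real low-voltage detectors.

What passing these tests shows — and does not. The synthetic detector
reproduces the *mechanisms* (charge sharing, displaced backscatter mass,
Poisson statistics, read noise) and the measured cluster-size mixes, so
orderings among counting filters and the behaviour of the metrics transfer
qualitatively. It does not model real sensor charge transport, per-pixel
response variation beyond a static gain map, energy-dependent detective
efficiency, or specimen contrast formation, so absolute SNR gains measured
here do not predict microscope numbers.

## Problem sizes

Defaults throughout are sized for interactive use: 128–192 px frames,
10–200 frames per stack, 10⁴-electron Monte-Carlo runs (5 seeds per
condition), 60–100 tuner evaluations. The full test suite runs in about
two minutes and the acceptance script in under a minute on one CPU; every
stochastic computation is seed-controlled.
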
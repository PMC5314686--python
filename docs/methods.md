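# Methods

## Model and conventions

The package analyses a nearly planar bilayer in the Monge gauge: the
membrane midplane is a single-valued height field h(x, y) over a periodic
Lx × Ly box, and the leaflet separation a thickness field t(x, y).
Helfrich–Canham (HC) sheet elasticity, without surface tension or tilt
degrees of freedom, predicts independent Gaussian Fourier modes with

    S_h(q) = A⟨|ĥ(q)|²⟩ = 1/(K_c q⁴)        (height / undulatory)
    S_t(q) = A⟨|δt̂(q)|²⟩ = 1/(K_d q⁴ + K_e)  (thickness / peristaltic)

under the discrete convention ĥ(q) = (1/N) Σ_r h(r) e^{−iq·r},
q = 2π(n_x/Lx, n_y/Ly). All moduli are expressed in k_BT, which removes
temperature from every fit; a display-time helper converts to joules
given T. The q = 0 mode is identically zero everywhere (fields describe
fluctuations about the mean plane), and Parseval's identity
Σ_{q≠0} S(q)/A = Var[h] holds exactly per frame under this convention —
the test suite asserts it to 10⁻¹⁰ relative.

Units are nm, ps and k_BT throughout; grids are 0-based with node (i, j)
at (i·dx, j·dy) on the half-open cell [0, L).

The thickness form deserves a caveat: S_t = 1/(K_d q⁴ + K_e) is the
minimal peristaltic model with the correct constant low-q asymptote
1/K_e. Richer treatments couple height and thickness or add
protrusion/tilt terms; K_e values are therefore comparable only between
analyses using this same functional form, and the fitter flags spectra
whose lowest shell rises significantly above the fitted asymptote
(`low_q_anomaly`) as outside the model.

## Synthetic ensembles

`synthetic` draws fields by spectral synthesis: unit white Gaussian noise
is transformed, multiplied by the per-mode standard deviation
√(N/(A K_c q⁴)) (height) or √(N/(A(K_d q⁴+K_e))) (thickness), and
transformed back. Because the filter is real and inversion-symmetric the
result is exactly real, Hermitian symmetry is automatic, and every mode —
including the self-conjugate Nyquist modes — carries exactly the target
variance. Frames are independent draws: the generator reproduces
equal-time statistics of an equilibrated membrane, **not** dynamics. What
passing tests on these ensembles shows is that the estimator chain is
unbiased and correctly calibrated for a membrane that obeys HC theory
exactly; they cannot certify behaviour on real spectra with tilt
shoulders, protein-induced features, or time correlation. For
time-correlation machinery a separate AR(1) generator
(x_t = ρx_{t−1} + √(1−ρ²)σε_t) provides series with the closed-form
statistical inefficiency (1+ρ)/(1−ρ).

Default generator parameters: K_c 25 k_BT, (K_d, K_e) = (2.4, 26.7) —
typical coarse-grained bilayer values in k_BT — mean thickness 4 nm,
grid spacing 0.5 nm.

`beads_from_surfaces` samples marker "phosphate beads" uniformly in the
plane at z = h ± t/2 (+ optional Gaussian jitter), evaluating the
surfaces with their exact trigonometric interpolant, so extraction
accuracy can be measured against ground truth.

## Surface extraction

Markers are split into leaflets by the sign of z − median(z) after
re-centring z on its circular mean (bilayers straddling the periodic z
boundary stay contiguous). Frames whose two z-populations overlap by more
than half the thinner population's range are rejected loudly
(`AmbiguousLeafletError`): that regime is not a Monge-gauge surface and a
silent mis-split would corrupt every downstream number.

Each leaflet's scattered z-values are interpolated onto the regular grid
with piecewise-cubic (Clough–Tocher) interpolation after tiling the
points over the 8 neighbouring periodic images — standard scattered
interpolants are not periodic, tiling makes the seam exact to
interpolation accuracy. Every node receives a finite value, so
marker-free patches (e.g. under an embedded protein) are bridged
smoothly; nodes farther than max(5·spacing, 3× the typical
nearest-neighbour distance) from any marker raise a sparse-coverage
warning. This smooth in-fill is a genuine choice, and fitted K_c at high
protein area density may be sensitive to it. Height and thickness then
follow as (upper+lower)/2 (mean-subtracted) and upper−lower (mean kept as
metadata, subtracted from the field before spectral analysis); any
non-positive thickness raises `InvertedLeafletError`.

Each frame is gridded on its own box (N = round(L/spacing)), so
semi-isotropic barostat area fluctuations are respected; spectra from
different boxes are pooled as (|q|, power) pairs, never regridded.

## Radial averaging

Only one representative per Hermitian pair (q, −q) enters the shells
(they are one real degree of freedom; double-counting would distort shell
means and counts), and modes beyond the shorter-axis Nyquist π/spacing
are discarded (the anisotropic corner of the q-plane is sampled only in
some directions and would bias isotropic averages). Shell intensity is
the unweighted mean of mode powers; the shell's q is the count-weighted
mean |q|; empty shells are omitted.

The default shell width is 2π/(8·max(Lx, Ly)) — an eighth of the
smallest wavevector spacing. The width matters more than it looks: with
shells as wide as the mode spacing itself, the first shell pools the
rings at q₁ and √2·q₁, and since S ∝ q⁻⁴ is convex the shell's rescaled
intensity q̄⁴·mean(S) overshoots 1/K_c by ~33% (Jensen's inequality),
biasing K_c low by >10%. The eighth-width shells resolve each discrete
low-q ring into its own shell, making the rescaled fit exactly unbiased
where it matters, and incidentally give the small 21 nm patch its three
fit points below 0.6 nm⁻¹. At high q, rings merge as they crowd
together, where their relative spread (and hence the Jensen error) is
negligible. The width is a parameter everywhere it appears.

## Elastic fits

K_c: shells with 0 < q < q_max are rescaled y_k = q_k⁴ I_k and the
constant c = mean(y_k) inverted, K_c = 1/c — the "every point weighs
equally" reading of the rescaled-spectrum fit. The alternative, an
unweighted least-squares fit of c/q⁴ to raw intensities, concentrates
nearly all statistical weight in the lowest shell; a regression test
verifies the rescaled fit's lower variance. The default window follows
the patch-size rule (0.6/0.4/0.2 nm⁻¹); the 30 nm and 80 nm class
boundaries are this package's choice of cutoffs for the conventional
small/medium/large classes and are configurable. Uncertainty is reported
two ways: the delta-method SE from shell scatter (se(c)/c²), and a
block-resampled SE (contiguous blocks, stdev/√n_blocks); for real,
time-correlated trajectories the block SE is the more honest of the two.

K_d/K_e: nonlinear least squares of 1/(K_d q⁴ + K_e) on the raw
intensities (the conventional direct fit of the thickness spectrum),
initialised at K_e = 1/I(lowest shell), K_d = 0, with bounded restarts.
Unlike the height fit, the default window spans all shells: at q ≤ 0.6
the K_d q⁴ term is ~1% of K_e for typical coarse-grained values and the
two parameters are only jointly identifiable with higher-q data.

Degenerate inputs are errors, not warnings: fewer than 3 (height) / 5
(thickness) shells in the window, non-positive fitted constants,
non-convergent restarts.

## Convergence diagnostics

`kc_timeseries` splits the trajectory into equal bins (1000, or 100 for
shorter runs, by convention; any count works), fits K_c per bin and flags
failed bins instead of imputing them. `statistical_inefficiency` reports
g — the factor by which correlation shrinks the effective sample count —
via the truncated autocorrelation sum g = 1 + 2Σ_k (1−k/n)ρ̂_k, cut at
the first non-positive ρ̂_k. This estimates the same limit as the
block-averaging variance-ratio plateau g(b) (exposed via the
`block_width` argument and the profile's width axis) but with severalfold
smaller estimator variance: single large-b block estimates carry
√(2/n_blocks) ≈ 10–15% noise, which in calibration runs against the
AR(1) closed form regularly strayed outside a ±10–15% band, while the
autocorrelation sum stayed within ±5% typically. "Reverse penetration"
computes g over trailing fractions f of the series (default grid
1.0…0.5, step 0.05); the recommended equilibration cut is the smallest
(1−f)·n whose g lies within 20% of the deep-cut reference (median over
the most-truncated fractions) — a heuristic: it assumes transients
inflate g monotonically as the window reaches back into them.

## Lateral organisation

Protein positions are xy-centroids of their particles (rotation-robust;
bead-level RDFs would mix intra-protein structure into g(r)). g(r) uses
minimum-image distances, per-frame ideal-gas normalisation with exact
annulus areas, and bins capped at half the smallest box edge. Protein
area fraction = 1 − (n_lipids/2 · APL)/⟨A⟩ over the trailing 20% of the
box-area series, with the convention (recorded in the output metadata)
that n_lipids counts both leaflets and APL is the per-leaflet area per
lipid of a matched protein-free control. The rigidity–density trend is
an inverse-variance-weighted straight line; zero supplied uncertainties
fall back to an unweighted fit with a warning.

## Problem sizes and numerics

The test suite and the acceptance script run ensembles of 40–2000 frames
on grids from 16×16 to 260×260 — sizes chosen so the statistical
tolerances being asserted (3σ bands, 5% recovery) are meaningful while a
full run stays interactive on one CPU. FFTs are numpy's pocketfft;
generation is chunked (~4M grid points per batch) to bound memory.
Seeds: every stochastic routine takes an explicit `RandomStream` (PCG64),
and child streams are spawned deterministically, so identical inputs give
bit-identical outputs, including the pipeline's on-disk bundles.

## Known limitations

* No tilt-dependent or coupled height–thickness elasticity: spectra with
  tilt shoulders or thickness maxima are fitted by plain HC in the low-q
  window only, and the contamination tests show the residual bias is
  downward and shrinks with the window.
* Leaflet assignment is planar-geometry only; vesicles and strongly
  curved patches are rejected rather than mis-analysed.
* Thickness is vertical leaflet separation, not along the local normal;
  at steep surface slopes the two differ.
* The synthetic generator has no protein inclusions and no temporal
  correlation between frames; convergence machinery is validated on
  scalar AR(1) series instead.
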
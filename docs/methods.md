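# Methods

## The fusion-scaling model

`fusion_model` implements a finite-source mass-transfer picture of a
nanoparticle fusing into a supported lipid bilayer. A particle of side
length *R*(t), density ρ, sheds lipid/dye into a bilayer of height *h*
where it diffuses laterally with coefficient *D*:

    ρ R² dR/dt = −D h δc(t).

The driving gradient δc is assembled from two 2-D diffusion scalings: the
peak concentration of a spreading footprint decays as c_max = c_amp / t,
and its lateral diameter grows as L = l_amp √t. With the concentration
outside the footprint taken as zero,

    δc(t) = (c_max − 0) / (L/2) = 2 c_amp / (l_amp t^{3/2}),

an exact −3/2 power law. Both scalings are verified against a brute-force
oracle: `simulate_point_release_2d` solves ∂c/∂t = D∇²c by explicit finite
differences from a single-cell release and recovers the free-space Green's
function peak M/(4πDt) to better than 1% once the release spans a few
cells, and `footprint_diameter` recovers L = 4√(Dt ln 2) at half maximum.

Integrating the mass balance gives the cubic closed form

    R³(t) = R0³ − 6C (t_start^{−1/2} − t^{−1/2}),   C = 2 c_amp D h / (l_amp ρ).

Assumptions and conventions:

- **Sign.** The balance is integrated with dR/dt < 0 — the particle sheds
  mass — the only physically consistent reading.
- **Regularization.** The t^{−3/2} gradient diverges at t = 0, so all
  trajectories start at t_start > 0 (default 0.03 s, one camera frame).
- **Self-similar branch.** When R0³ = 6C/√t_start the constant terms
  cancel and R(t) = (6C)^{1/3} t^{−1/6} exactly; `branch_params` puts a
  parameter set on this branch. Off the branch, trajectories either
  asymptote to a finite residual size or deplete at the finite root of the
  cubic (reported as `depletion_time`, with R clamped at 0).
- **Observable.** Peak fluorescence is taken proportional to R
  (`i_coeff`, default 1); on the branch I_max ∼ (Dh/ρ)^{1/3} t^{−1/6},
  i.e. a decay exponent of n = 1/6, against n = 1 for a point source. The
  proportionality is pluggable should a volumetric (∝ R³) reading be
  preferred.
- **Validity.** The model describes non-saturated membranes; saturation
  and lipid-exchange regimes are out of scope.
- The PDE oracle uses an explicit scheme with a CFL-limited step
  (safety 0.8) on a closed (zero-flux) grid, so total mass is conserved to
  rounding; a guard raises if the release reaches the boundary.

## Synthetic TIRF movies

`synthetic_tirf` renders the statistical structure the analysis assumes,
at the experimental calibration of 0.16 µm px⁻¹ and 0.03 s frames
(defaults, both configurable):

- **Background**: a uniform bilayer level (default 100 counts) times a
  per-pixel multiplier map — 1 for a single bilayer, 2 inside stacked
  double-layer patches, < 1 in dark lipid domains.
- **Particles**: 2-D Brownian motion with per-step variance 2DΔt per axis;
  the approach path is generated backwards from the docking point
  (Brownian motion is time-reversible, so the statistics are unchanged).
- **Events**: after landing and a dwell, the spot's peak intensity follows
  I(τ) = a ((τ + t_off)/t_off)^{−n} with t_off defaulting to one frame
  interval so the intensity is finite at fusion start, and its Gaussian σ
  grows as the quadrature sum of the PSF width (1.3 px, a diffraction-
  limited choice) and footprint_growth·√τ (default 0.3 µm s^{−1/2}).
  An optional dye-conserving mode scales the amplitude so the frame-
  integrated signal stays constant as the footprint spreads.
- **Noise**: Poisson shot noise on the gain-scaled signal plus Gaussian
  read noise (default σ = 2 counts), applied last; identical
  (prescription, seed) pairs are bit-identical.
- **Ensembles** (`fusion_event_ensemble`): particle diameters are
  lognormal with arithmetic mean 200 nm and sigma_log 0.3 — the skewed
  size distribution typical of cubosome dispersions — and modulate each
  event's amplitude (∝ size) and approach diffusivity (Stokes–Einstein,
  ∝ 1/size). The mean amplitude is set by a target SNR (default 10)
  against the background shot noise. Events land 0.3–1.5 s into the
  movie with 0.2–0.6 s dwells on a jittered grid that keeps grown
  footprints separated.

What the generator deliberately does not emulate: photobleaching, axial
dynamics, evanescent-field depth, flow, protein coronas, and cell-shaped
backgrounds. Passing round-trip tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to every
artifact of real microscopy.

## Tracking and sizing

Detection is the classic bandpass → local maxima → centroid pipeline:
difference of Gaussians (noise scale 1 px, long cutoff = spot diameter,
default 7 px), peak picking with an exclusion radius of half the diameter
and an absolute threshold defaulting to 5 robust (MAD) sigmas of the
bandpassed frame, then intensity-weighted centroid refinement (≲ 0.1 px on
synthetic spots at SNR 10). Linking solves a per-frame optimal assignment
(Hungarian algorithm) on squared displacement, gated at `max_disp_px`
(default 5) with gap memory (default 2 frames); assignment is
deterministic and preserves identities through crossings.

MSD analysis averages overlapping displacement pairs at each lag up to 25%
of the track span and fits ⟨r²⟩ = 4Dτ through the origin with
inverse-variance weights: for the overlapping time-averaged MSD,
var(msd_k) grows roughly as k³/N, so long lags — which carry almost no
independent information — are strongly down-weighted. Unweighted fitting
over the same range has a ~25% scatter in D̂; weighting brings the median
relative error to 3–6%. Hydrodynamic diameters follow Stokes–Einstein,
d = k_B T/(3πηD), with defaults T = 298 K and η = 0.89 mPa·s (water).

## Event kinetics

`segment_events` declares a docking when a track stays within
`immobility_radius_px` (default 1) of its local mean over 5 consecutive
frames, then requires the docked pixel's intensity to exceed its
pre-docking background by 5σ and subsequently decay. Two estimator details
matter and were chosen for bias, not convenience:

- **Decay onset.** The raw argmax of a noisy plateau-then-decay trace
  lands anywhere on the plateau (the docked intensity equals the decay
  start), which shifts the fitted time origin and inflates the exponent by
  ~0.03. The onset is instead the last sample of a boxcar-smoothed trace
  within 1.5 smoothed-sigmas of the plateau maximum (the maximum of ~10
  smoothed samples sits ~1.5σ above the plateau mean), corrected for the
  smoothing half-width. On noiseless traces this is exact.
- **Background.** Pre-docking frames at the event pixels, excluding frames
  where the particle's own approach passed within 4 px (otherwise its spot
  inflates both the background and its σ); an annulus mode (median of a
  6–10 px ring, per frame) handles sloped or drifting backgrounds and is
  auto-selected with a warning when fewer than 5 pre-landing frames exist.

Traces are indexed from the peak frame, with the peak assigned t = one
frame interval (avoids log 0). Under this convention an event rendered
with t_off = frame interval is an exact power law in trace time, and the
fitted amplitude sits on the absolute-seconds scale
(a_counts = a_fit · t_off^{−n}). Fitting is ordinary least squares on
log I vs log t over points above a noise floor (default 1 background σ),
refusing fits with fewer than 8 surviving points; a Theil–Sen option
exists for heavy-tailed contamination. The window is the contiguous
above-floor run from the trace start — once the decay reaches the floor,
later samples are noise, and isolated positive excursions among them would
flatten the slope. Log-space OLS carries a small steepening (Jensen) bias
where the tail approaches the noise floor: negligible for slow decays
(n ≈ 1/6 recovered within a few percent) and ~10% for steep, short-window
ones at SNR ~20. An explicit first-order bias correction was evaluated and
rejected — it over-corrects slow decays — and the residual bias is of the
same size and sign as the elevation of experimentally reported mean
exponents above the theoretical 1/6.

The fusion time is measured from the peak to the first sample that is at
or below k_sigma·σ (default 2) and whose following 3-sample window has
median at or below that threshold. The windowed median rejects single-
frame dips; requiring a full run of sub-threshold samples instead fires
systematically ~3 frames late, since each sample at the true crossing is
below threshold only with probability ~1/2. Unresolved decays are
reported as censored at the trace end, not dropped. Both peak-to-background
(primary) and landing-to-background times are exported.

## Bilayer formation

Coverage is the per-frame fraction of pixels above an Otsu (or fixed)
threshold after flat-field normalization, fitted with
θ(t) = (θ_max/2)(1 + erf((t − t_c)/(√2 τ))) — a 3-parameter error-function
growth law whose gradient is Gaussian and peaks at t_c. Domains are
connected components (4- or 8-connectivity) above threshold with a 4 px
minimum area to suppress shot noise. The nucleation-growth simulator
places Poisson nuclei in space-time (optionally only within an initial
nucleation window, mimicking the supersaturation pulse of solvent
exchange), grows them as disks at constant edge speed, and logs every
nucleation plus each first contact between distinct clusters (union-find
over geometric contact times). Fractal domain edges are approximated by an
optional seeded radial perturbation; true DLA-style growth is out of
scope.

## Problem sizes and numerical choices

- Point-release oracle: 512² grid for the headline exponent (fitted over
  t ∈ [10, 1000] grid-time units), 128–160² in unit tests; explicit step
  at 0.8 of the CFL limit.
- Ensembles: 200 events as ten 256²-pixel, 320-frame movies of 20 events
  each; 100 fast-decay (n = 1) events for fusion-time round trips; 50
  single-particle movies for diffusion recovery.
- ODE integration: RK45 with rtol 1e-10 and a terminal depletion event at
  10⁻⁶ R0; agreement with the cubic closed form is better than 10⁻⁶
  relative away from depletion.
- Ties in linking are resolved by the assignment solver's fixed ordering;
  all randomness flows from explicit integer seeds through
  `numpy.random.default_rng`.

## Known limitations

- The exponent fit window depends on the noise floor, so very dim or very
  fast events (fewer than 8 usable samples) are refused rather than fitted.
- Fusion times of slowly decaying events (n near 1/6) are usually censored
  within realistic movie lengths; distributions must treat censoring
  explicitly.
- Whether the experimental footprint diameter corresponds to a fixed
  threshold is unknown; `footprint_diameter` exposes the threshold as a
  free parameter.
- The segmentation assumes one dominant event per immobile episode;
  partial fusion / undocking / refusion sequences are segmented as
  separate events sharing a track id.
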
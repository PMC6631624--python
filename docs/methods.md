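# Methods

## Model and assumptions

Wound closure is modeled by the one-dimensional Fisher–Kolmogoroff
(Fisher–KPP) equation for cell density `u(x, t)`,

    ∂u/∂t = D ∂²u/∂x² + k u (1 − u/û),

with `x` the direction perpendicular to the scratch.  The model assumes
(i) cell migration is a persistent random walk, coarse-grained to Fickian
diffusion with constant motility `D`; (ii) proliferation is logistic with
rate `k = ln2/τ` and carrying capacity `û`; (iii) the wound is a straight
band, so the dynamics are 1D and rendered images are vertical-stripe
extrusions; (iv) no directed chemotaxis or edge-specific behavior
(lamellipodial pulling, leader cells) — closure emerges from diffusion plus
growth alone.  The PDE admits travelling-wave fronts with minimum speed
`v = 2√(Dk)`; invasion fronts from steep initial data converge to this
speed from below.

The measurement chain mirrors standard assay practice: the normalized
cell-free area `A/A0` declines at constant rate `α` after a lag `t_L`;
each edge moves at `v = α·b/2` (`b` = initial wound width); `τ` comes from
an independent growth curve `n(t) = n0·2^(t/τ)`; inverting the front-speed
relation gives `D = τ v²/(4 ln2)`; `φ = b√(k/D)` classifies the closure
regime.

### Transient versus developed-front regime

Convergence to the asymptotic speed is slow (the leading correction decays
like `3/(2t)·√(D/k)`, i.e. a relative error ~`3/(4kt)`).  Two consequences
shape the package's validation design:

* **Ratios are regime-independent.**  For a fixed growth rate the PDE
  solution rescales exactly as `x → x/√D`, so any density contour's
  position — and hence `α` measured over any common time window — scales
  as `√D`, provided the two wound edges do not interact.  The
  treated/control velocity ratio under a planted motility fold-change `r`
  is therefore `√r` even deep inside the transient, which is why the
  18 h protocol measures it faithfully.
* **Absolute `D` is not.**  Over an 18 h record with `τ = 24 h`
  (`k·t ≈ 0.5`), the front runs well below `2√(Dk)` and the algebraic
  inversion returns an effective motility below the planted value (by
  roughly one third at the default conditions).  Absolute recovery is
  therefore validated in the developed-front regime: a 14 mm wound imaged
  for 60 population doublings (`τ = 6 h`, ~360 h), where the residual
  transient bias is a few percent.  The recovery driver and test use that
  regime; the short-protocol `D` values are reported as effective
  quantities.

A related geometric validity condition: `v = α·b/2` treats the two edges
as independent fronts.  The default wound width (1200 µm) keeps the
edge-to-edge gap larger than twice the diffusive tail length
`√(4Dt)` for the faster condition over the full 18 h record; with a
narrower wound (e.g. 800 µm at `D ≈ 1900 µm²/h`) the tails overlap, the
center fills cooperatively, and the measured ratio inflates.

## Numerics

* **Scheme:** explicit central-difference FTCS; simple and auditable at
  desk scale.  Stability is enforced, not assumed: `dt ≤ dx²/(2D)` and
  `dt·k ≤ 0.25`, violations raise a `StabilityError` before any stepping.
* **Boundaries:** no-flux via mirror ghost nodes (a field of view with no
  cell inflow).  With `k = 0` the discrete scheme conserves total mass to
  machine precision (telescoping Laplacian).
* **Front-speed measurement:** sub-grid linear interpolation of the
  half-maximum crossing, linear fit over the last 40% of the record (the
  early transient is excluded by construction).  At the default resolution
  (`dx = 10 µm`, horizon 30 doublings) the measured speed agrees with
  `2√(Dk)` to better than 4% across `D ∈ [300, 1000] µm²/h`,
  `τ ∈ [12, 24] h`; the residual is dominated by the `3/(4kt)` transient
  correction, not discretization.
* **Closure fit:** continuous two-segment model (flat plateau, then a
  straight decline) fitted by least squares with the breakpoint scanned
  over sample times; the breakpoint is `t_L` and the decline's magnitude
  is `α`.  The declining segment must keep ≥ 5 points; a non-negative
  best-fit slope returns `α = 0` with a no-closure flag; `t_L` beyond half
  the record warns.  Deterministic, no iterative optimizer.
* **Doubling-time fit:** least squares on `log2(n/n0)` through the origin
  with `n0` pinned to the first count — `τ` is the single adjustable
  parameter; exact on noiseless data.

## Synthetic data: what it emulates and what it does not

The generator replaces the microscopy of the assay protocol: 15-min
frames for 18 h (73 frames), several replicate fields per condition,
growth curves counted over three days.

* **Renderer.**  Phase-contrast contrast is emulated as texture, not
  brightness: cell-covered regions carry band-limited speckle
  (Gaussian-filtered white noise, correlation length 1.5 px) on a flat
  background, plus per-pixel Gaussian sensor noise.  The speckle amplitude
  follows an occupancy ramp — zero below a cell-free density threshold
  (0.2·û), saturating above it over a band of half-width 0.08·û — because
  sparse spread cells produce little phase texture while a packed
  monolayer is strongly textured.  The ground-truth mask marks the same
  contour (`u < 0.2·û`), so it is the true wound boundary *of the rendered
  image*.  Not emulated: halo/shade-off optics of phase contrast, cell
  granularity at single-cell scale, curved or ragged wound edges, focus
  drift, photobleaching.  Passing tests therefore demonstrate correctness
  of the measurement chain on FK-consistent imagery, not robustness to
  every real-microscope artifact.
* **Growth curves.**  Multiplicative lognormal noise with unit median and
  chosen CV (default 5%, a typical handheld-counter repeatability).
* **Noise pairing.**  Replicate noise streams are spawned from the root
  seed per replicate and shared across conditions — replicates behave like
  paired same-day fields, matching the paired statistics, and identical
  conditions yield bit-identical fits.

## Segmentation

Local standard deviation (15 px window) → Otsu threshold on the texture
map → morphological closing then opening (disk radius 4 px) → keep the
largest low-texture component touching the wound axis (frame mid-column by
default).  Wound polarity is low texture (cell-free plastic is smooth).
The method is invariant to intensity offsets by construction.  When the
texture histogram is unimodal (fully confluent or fully bare frame) the
Otsu split is untrusted (class contrast < 2×) and the frame is classified
by comparing its median texture to a wavelet estimate of the sensor noise
floor: at the floor → all wound, well above → all cells.  The renderer
keeps cell speckle band-limited precisely so the finest-scale wavelet
estimate isolates sensor noise.  A constant frame returns a full-frame
mask with a warning.  Fully closed frames report area 0 and stay in the
series.  Area is always mask pixel count × pixel size².

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| û | 1.2×10⁻³ | cells/µm² | confluent keratinocyte monolayer (~1.2×10⁵ cells/cm²) |
| D (control) | 600 | µm²/h | mid-range literature motility for epithelial sheet migration |
| τ | 24 | h | typical immortalized keratinocyte doubling time |
| b | 1200 | µm | pipette-tip scratch width; keeps edges independent for 18 h (see above) |
| domain | 4000 | µm | wound plus ≥1.4 mm confluent margin per side |
| dx / dt | 5 µm / 0.005 h | | `dt` ≈ 0.78× the stability bound at D = 1944 µm²/h |
| pixel size | 5 | µm/px | 5× objective scale |
| frames | 73 × (200×800) px | | 15-min intervals, 18 h |
| texture amp / noise SD | 0.3 / 0.05 | intensity | texture-to-noise ratio 6:1, comfortably segmentable |
| replicates | 3 | | triplicate experiments |

Problem sizes for the validation studies (front-speed grid at `dx = 10 µm`
over ~30 doublings; recovery at `dx = 8 µm`, 80 frames of 150×1600 px over
60 doublings) were chosen as the coarsest settings at which the documented
numerical-convergence margins above hold.

## Statistics

Replicates summarize as mean ± SEM (`sd/√n`, `n ≥ 2` required).
Treated-vs-control comparisons report the ratio of means and a paired
two-tailed t-test (paired by replicate index, which is also how the noise
streams pair).  Zero-variance differences are degenerate for the t
statistic: identical samples report `p = 1`, a constant non-zero shift
`p = 0`, both flagged rather than raised.  Viability is
`CV(%) = 100 × A_test/A_control`.  Plate-format two-way ANOVA with
Bonferroni post-tests is deliberately out of scope.

## Design choices on open points

* **Thiele modulus convention.**  The first-order form `φ = b√(k/D)` is
  used (dimensionless by construction); the literal quotient `b²k/D` (its
  square) is available via `convention="literal"`.  Whether the length
  scale should be `b` or `b/2` is not settled; `b` is used and documented.
* **Segmentation operators** (the assay literature specifies none): the
  texture-variance route above, every knob exposed in
  `SegmentationConfig`.
* **α sign:** reported as a positive magnitude; the raw slope is negative.

## Known limitations

* The FK model itself omits directed edge migration; absolute `D` from
  short records is an effective parameter (see the regime discussion).
* 1D geometry: curved or ragged wounds, and wound-edge roughening, are out
  of scope.
* The renderer's occupancy threshold ties the optical wound edge to a
  single density contour; real phase-contrast edges are fuzzier.
* Segmentation assumes one dominant wound component crossing the scratch
  axis; fragmented multi-component wounds are reduced to the largest.
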
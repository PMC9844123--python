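# Methods

This note records the models behind `acoustosort`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data tests
do and do not demonstrate about real instruments.

## The system being modelled

An RT-DC-based sorter pushes a hydrodynamically focused cell stream
through a square deformation channel (20 or 30 µm side) where each cell
is imaged, analysed and — if it satisfies the active gate — deflected in
a downstream widened sorting region (50 µm wide, 130 µm long) by a
~1 ms pulse of focused travelling surface acoustic wave from an
interdigitated transducer (135 MHz, lithium niobate substrate,
v = 3978 m/s).  The bifurcation after the sorting region is offset by
5 µm, so a cell reaches the target outlet iff its lateral displacement
during the pulse exceeds that offset.  The carrier fluid is a viscous
methylcellulose/PBS buffer (sound speed 1487 m/s; effective in-channel
viscosity ~10 mPa s after shear thinning, bulk ~25 mPa s).

## Acoustic force model

Two excitation modes are implemented.

**Standing wave (SSAW).**  The one-dimensional radiation force on a
small spherical particle at distance *x* from the pressure node,

F(x) = −(π P₀² V_p β_f / 2λ) · φ · sin(2kx),
φ = (5ρ_p − 2ρ_f)/(2ρ_p + ρ_f) − β_p/β_f,

the classical small-particle (Rayleigh-regime) standing-wave result.
φ > 0 (most cells in aqueous buffers) drives particles to the node.  The
wavelength entering the force prefactor and the wavenumber is the
*fluid* wavelength C_f/f; whether the substrate or fluid wavelength is
meant is ambiguous in descriptions of such devices, and the fluid
wavelength is the physically consistent choice for a force derived from
the in-fluid pressure field.

**Travelling wave (TSAW).**  The time-averaged radiation force

⟨F⟩ = Y_T π d_p² ⟨E⟩ / 4,

where Y_T is a dimensionless scattering coefficient and ⟨E⟩ the
time-averaged acoustic energy density in the fluid.  Y_T in general
follows from anisotropic scattering theory and depends on κ and the
particle's mechanical properties; here it is a user parameter
(default 1.0) because the package does not implement a scattering
solver.  ⟨E⟩ is likewise configured directly; an optional helper maps
electrical drive power to ⟨E⟩ through a single user-supplied
electro-acoustic conversion efficiency and beam cross-section, with no
claim to model substrate propagation.

**Regimes.**  The dimensionless size parameter κ = 2π d_p f / C_f
classifies which mechanism dominates lateral motion: direct radiation
force for large κ, drag from acoustic streaming for small κ.  The
theoretical boundary is κ = 1; experiments on comparable devices place
it at κ = 1.28 ± 0.2, and 1.28 is the default threshold (at 135 MHz in
the measurement buffer this corresponds to a 2.25 µm diameter).  The
classifier returns a label only — streaming velocity fields are *not*
computed, and the optional `asf_displacement` term in the sorter is a
user-set additive constant, not a streaming model.

**Displacement.**  Particle Reynolds numbers are ≪ 1 and the viscous
relaxation time (ρ_p d²/18η ~ microseconds) is far below the millisecond
pulse, so the pulse displacement is the terminal velocity times the
pulse length: Δy = F τ / (3πηd).  Inertia, wall effects and cell–cell
hydrodynamic interactions are neglected.

## Feature extraction

The pipeline mirrors a real-time system but is tuned for accuracy rather
than latency:

* **Background** — per-pixel temporal median, full stack by default
  (a sliding window is available).  The median tolerates objects that
  occupy a pixel in a minority of frames; a single frame is rejected
  with instructions to supply an explicit background.
* **Detection** — |frame − background| thresholded (default 10 intensity
  units), connected components below 10 px discarded.
* **Contours** — per component, a sub-pixel marching-squares boundary is
  extracted at *half the component's peak contrast*, not at the
  detection threshold.  On an edge whose intensity ramps across one
  pixel, the half-contrast level set sits on the true object boundary;
  a pixel-count estimate at the detection threshold is biased outward by
  several percent for small objects.  This requires the object contrast
  to exceed about twice the detection threshold.
* **Features** — gating features (area, perimeter → deformation) are
  computed on the convex hull of the boundary; the area ratio
  (hull/raw) is stored as a quality score and used as a pre-filter with
  the published bounds (<1.05 beads, <1.08 cells).  Rationale: the
  quality filter exists precisely to bound hull-vs-raw discrepancy,
  which implies the gated features are hull-based.  Raw-contour values
  are kept alongside.  Brightness is the mean *raw* grayscale inside the
  raw contour (whether real systems use raw or background-subtracted
  intensities is not documented; raw is chosen and flagged here).
* **Deformation sign** — discretised perimeters can slightly
  underestimate the true arc length, making D marginally negative for
  circles; values are clamped to 0 in the reported `deformation` column
  and preserved in `deformation_raw`.
* **Deduplication** — a cell imaged in several consecutive frames is
  merged by greedy centroid tracking (gap ≤ 1 frame, move ≤ 20 px by
  default) and represented by the frame nearest the image centre column,
  standing in for the single ROI evaluation of the on-line system.  At
  realistic velocities (~15 cm/s at 2700 fps) a cell rarely appears
  twice, so the tracker mostly matters for slow synthetic stacks.
* **Coordinates** — pixel indices are 0-based (row, col); the default
  calibration is 0.34 µm/px (the imaging objective's magnification does
  not fix the pixel pitch, so this is configurable).

## Sorter simulation and coincidence

Arrivals at the sorting region form a homogeneous Poisson process with
rate = concentration × volumetric flow — the simplest process consistent
with describing throughput as that product.  Each cell resides in the
region for V_SR/Q (2.5 ms at the 0.2 nl / 0.08 µl/s operating point).
A gated cell triggers a pulse after a fixed delay (default 1 ms, the
ROI-to-sorter travel time; detection jitter is not modelled).

**Coincidence is evaluated at pulse onset**: every cell resident in the
sorting region at the instant the pulse fires is displaced.  For a
Poisson stream the number of co-resident bystanders is then exactly
Poisson(c·V_SR), which makes the closed forms
P(N≥2) = 1 − e^(−λ)(1+λ) and P(≥1 contaminant) = 1 − e^(−λ_other)
exact oracles for the simulator — these are verified by χ² and
standard-error tests in the suite.  Cells arriving *during* the pulse
are not displaced; since the pulse (1 ms) is well below the residence
time (2.5 ms), this quasi-static approximation affects only a minority
of windows and keeps the model analytically checkable.

Two coincidence policies are provided: `co-sort` (default; bystanders
follow the target into the collection outlet and degrade purity) and
`abort` (the pulse is suppressed whenever a bystander is present,
trading recovery for purity).  A per-event actuation success probability
is exposed for effects with no quantitative model (e.g. the z-velocity
dispersion that penalises very small cells), defaulting to 1.

Metrics follow cytometry conventions: IP/TP are the percentage of
(quality-filtered) events inside the gate before/after sorting,
enrichment = TP/IP, recovery = collected/reported-sorted.  Gate
intervals are half-open [lo, hi) and "<" bounds are strict, one fixed
convention for the mixed range/bound notations found in practice.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure of the instrument's
studies: two bead populations with modal diameters 12.6 and 14.3 µm
(Δd = 1.7 µm) at 3.2 % size CV; blood sub-populations separable in the
deformation–size and brightness–size planes; Poisson arrival streams at
3–36 ×10⁶ cells/ml sample concentrations.  Quantitative per-population
brightness and deformation distributions are not published beyond the
gate bounds, so population modes are placed at gate centres — a flagged
choice, not an inference from data.  Rendered cells are anti-aliased
ellipses with an optional front–rear taper to mimic bullet-like advected
shapes; shapes are sampled, never computed from flow mechanics, and the
optics are ideal (no defocus, diffraction or motion blur).  Passing the
feature-recovery tests therefore demonstrates the correctness of the
measurement code on known geometry, not segmentation robustness on real
microscopy.

## Numerical and design choices

* All computation is SI internally; a small unit grammar converts the
  instrument-natural units (µm, µl/s, ms, MHz, nl, cells/ml) at the
  configuration boundary, losslessly to 12 significant digits.
* The sorting-region volume defaults to width × length × height but may
  be overridden (devices quote a rounded 0.2 nl for 0.195 nl geometric);
  overrides must agree with the geometry within 5 %.
* The IDT resonance returns the design formula v/λ; fabricated devices
  resonate a few percent lower (e.g. 135 MHz measured vs 142 MHz design
  for 28 µm periodicity), so measured frequencies should be supplied as
  overrides.  The two are not reconciled by the package.
* The regime boundary κ exactly at threshold classifies as
  streaming-dominated (strict inequality).
* Area-ratio values are guarded at ≥ 1 to 1e-9 polygon-area tolerance.
* KDE bandwidths are absolute (data units), implemented on top of
  scipy's Gaussian KDE.
* Simulation sizes in the test suite (10⁴–10⁵ events per point, one to
  three repeats, 200 rendered ellipses) are chosen so the whole suite
  runs in well under a minute on one core while keeping Monte-Carlo
  standard errors far below the tolerances being asserted.
* The energy density used in simulation fixtures (100 J/m³) is chosen so
  the smallest gated particles clear the 5 µm bifurcation offset within
  one 1 ms pulse — the "sufficient force" operating condition; no
  electro-acoustic conversion measurement is implied.

## Known limitations

* No acoustic streaming field, no substrate wave propagation, no FIDT
  focusing diffraction: the streaming regime is a label plus an optional
  constant displacement.
* Y_T and ⟨E⟩ are parameters, not predictions; absolute displacement
  magnitudes are therefore calibrations, though all scalings (d², τ,
  1/η) are physical.
* Isoelasticity (stiffness) polygon gates are accepted as explicit
  vertex lists; the package does not compute isoelasticity lines or
  Young's moduli.
* The shear-thinning rheology of the buffer is reduced to one effective
  viscosity constant per flow condition.
* Wet-lab purities depend on biology and instrument drift that the twin
  does not model; the simulator reproduces the *arithmetic and
  statistics* of sorting (coincidence, occupancy, displacement
  thresholds), not measured biological purities.
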
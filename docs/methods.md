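# Methods

This note records the model `ehgsim` implements, the choices made where the
underlying physics or published description leaves the design open, and
what the simulated conditions do and do not show about real recordings.

## Source model: the travelling dipole band

Uterine depolarization is abstracted as an annular band of dipoles on the
wall of an inverted cone. All lengths are millimetres and times seconds;
potentials are in uncalibrated model units (the band moment is given in
C·mm and the medium constant ε₀ = 0.36 is dimensionless), so the
paper-facing outputs — attenuation ratios in dB, peak delays, speeds — are
unit-invariant, while absolute potential values are not calibrated to
volts.

| parameter | symbol | default | meaning |
|---|---|---|---|
| band speed | c | 30 mm/s | propagation along the uterine axis |
| initial position | R₀ₛ | 400 mm | fundus half-span of the full-term uterus |
| cone half-angle | θ | 10° | taper of the uterine wall |
| band width | δ | 6 mm | extent of the depolarized annulus |
| band moment | p₀ | 2.2·10⁻¹³ C·mm | total dipole moment of the front |
| medium constant | ε₀ | 0.36 | denominator constant of the source potential |

**Round trip.** The axial band position follows a triangular trajectory
−R₀ₛ → +R₀ₛ → −R₀ₛ (total 4R₀ₛ/c ≈ 53.3 s; the one-way 800 mm traversal
takes 26.7 s ≈ 27 s). Past the cone apex the slant radius is folded,
R = |z_band|/cos θ, and the band is mirrored to the opposite half-axis, so
the cone re-expands symmetrically and every waveform is an exact palindrome
about the turnaround. The evaluation at the single apex-crossing instant
(a degenerate, measure-zero configuration) assigns the band to the
positive side by convention.

**A structural property worth knowing:** the two bracket terms of the
source potential are each the axial derivative of the distance to one band
edge circle, and both equal −cos θ at ζ = 0, so the potential at the
coordinate origin is identically zero. "Closer observation points see
bigger peaks" therefore holds for all non-zero ζ but not literally at
ζ = 0.

**Propagation-speed measurement.** The estimator locates each waveform's
dominant outbound peak with a three-point quadratic interpolation and
divides the observation spacing by the peak-time difference. Two
configurations are documented:

* *native sampling* (default): the band kinematics are defined on integer
  seconds (t = 0, 1, 2, …); on that grid the interpolated peak times are
  biased by the sampling, and the pair at 150/200 mm yields a delay of
  1.7865 s → 27.99 mm/s.
* *fine sampling* (dt = 0.1 s): the bias disappears; any off-apex pair
  yields ≈ 1.616 s → 30.9 mm/s.

Both speeds bracket the preset 30 mm/s. Pairs adjacent to the apex are
excluded (the waveform at ζ = 0 is identically zero, and peak detection
within ±25 mm of the apex is dominated by the near-apex density spike).

## Abdominal volume conductor

**Geometry.** The abdomen is a dome of radius 100 mm along +y carrying
concentric skin / fat / muscle shells (2 / 15 / 8 mm by default); the −y
half continues the same concentric tissue as a stand-in for the maternal
trunk, so the uterus is surrounded by conductor as in vivo (a half-space
cut at the dome's equator could not contain a uterine ring at all). The
interior (uterine) region conducts like muscle. Everything outside is air
at σ = 10⁻⁸ S/m — a regularization that keeps one uniform discrete
operator while making the skin surface effectively insulated — and the
bounding box (half-width 120 mm) is grounded, emulating unbounded
surroundings.

**Conductivities** are not part of the published tissue table (which lists
relative permittivity and thermal properties); standard low-frequency
values are adopted — skin 2·10⁻⁴, fat 0.04, muscle 0.35 S/m — and are
configurable per layer. Permittivities are carried in `TissueLayer` but do
not enter the solve: sub-Hz uterine activity justifies the DC quasi-static
approximation.

**The band inside the abdomen.** The full-term uterus does not fit a
100 mm abdomen; for the forward experiments the band is the annulus where
the uterine wall passes closest to the abdominal surface: a rigid ring
coaxial with the z (fundus–cervix) axis through the uterus centre (the
origin), of radius `inner_radius − band_depth` (default 75 − 5 = 70 mm,
"close to the myometrium"), displaced rigidly as the activity travels —
displacing the band and displacing the electrode are equivalent, which is
exactly how local sensitivity is probed. Its dipoles point along the
outward wall normal (radial). This orientation choice matters: the source
expression above is an *axially* oriented dipole annulus, but an axial
ring directly beneath the electrode reads ~zero by symmetry (the z-dipole
lobe has a null overhead), which would make the attenuation reference
meaningless; the wall-normal component is the one the surface electrodes
actually sense, and it reproduces the expected monotone decay from a
maximum at zero displacement. `uterine_band_ring` exposes
radial / meridian / axial orientations.

**Noise sources.** Six interfering dipoles with moments 0.1·p₀ (the
magnitude is not specified by the study; this default is visible but
non-dominant) at uniform random positions in the +x half of the muscle
shell, orientation uniform on the sphere, reproducible under a fixed seed.
They are placed once per experiment and held fixed — in particular across
a tissue-thickness sweep. If the muscle layer is swept to zero thickness
the shell degenerates and the dipoles are placed in a 2 mm shell just
inside the innermost boundary instead.

## Finite-difference solver

* 7-point discretization of ∇·(σ∇φ) on a regular grid (default spacing
  4 mm), Dirichlet φ = 0 on the box boundary.
* **Face conductances** are homogenized: the harmonic (series) mean of four
  σ samples along each inter-node segment — the conservative-flux choice
  that also represents layers thinner than the grid by their correct
  series resistance — averaged arithmetically (in parallel) over four
  transverse offsets spanning the face. The transverse averaging makes the
  conductance vary smoothly along voxelized curved interfaces; without it,
  surface-potential differences (everything the ring electrodes measure)
  do not converge under refinement.
* **Linear solves:** sparse LU in symmetric mode (minimum-degree ordering)
  up to 150 000 unknowns, Jacobi-preconditioned CG (relative tolerance
  10⁻⁸) beyond. One factorization serves any number of source
  configurations.
* **Dipole injection:** ± monopole pairs separated by one grid spacing
  along the moment direction, deposited with trilinear weights. Current is
  only allowed to land in tissue (placement into air raises an error).
* **Singularity subtraction (default):** the solution is represented as
  φ = φ_free + w, where φ_free is the closed-form unbounded-medium dipole
  potential at each source's local conductivity (evaluated analytically at
  query time) and the grid holds the smooth correction w, driven by the
  operator residual of φ_free. Within eight cells of a source, residuals at
  nodes in a uniform-conductivity neighbourhood are pure
  source-representation error and are dropped (residuals at or adjacent to
  conductivity contrasts are always kept); the dropped zone's net sum is
  returned to the node nearest the source so the injected current stays
  balanced — essential in the nearly air-isolated tissue, where any
  imbalance appears as a large floating-potential offset. This reduces the
  error against the analytic dipole formula at 5–8 cell separations from
  ≈ 8 % (raw discrete solution) to < 1 %. The raw path
  (`subtract_singularity=False`) remains available and is exactly linear
  in the sources.
* **Field queries:** order-3 B-spline interpolation of the (magnitude-
  normalized) grid part plus the analytic part. Trilinear interpolation is
  available but corrupts second differences with grid-scale kinks.
* **Electrode readings in experiments are reciprocal.** Each electrode's
  reading is one linear functional of the surface potential; solving the
  adjoint problem with that functional as source gives a lead field ψ, and
  the reading of any dipole set is Σ mᵢ·∇ψ(xᵢ) — evaluated deep in the
  interior where ψ is smooth and well resolved, instead of sampling tiny
  second differences on the voxelized surface. (ψᵀb equals the direct
  reading to machine precision; the gradient is formed by centred node
  differences and interpolated trilinearly, deliberately avoiding any
  global spline prefilter whose ringing would contaminate small far-field
  values.) Each additional band position then costs no solve at all.

## Electrodes

`ElectrodeSpec` fixes the family geometry: middle ring at r, outer ring at
exactly 2r, monopolar disc radius 2r (6–26 mm), central disc radius
2.5 mm (the published range is 1.7–3.6 mm, tied to an impedance argument
not modelled here), ring width 1 mm shared by all Laplacian kinds.

Ring and disc averages use trapezoidal angular quadrature (spectrally
accurate for periodic integrands; 360 samples by default) and Gauss
quadrature in ρ² for annulus and disc area weighting. Ring and stencil
sample points are generated in the tangent plane at the electrode site
(the dome point on the +y axis, level with the uterus centre) and
projected radially onto the curved surface.

Two fidelity modes exist: the physical default (finite ring width,
disc-averaged centre potential v₀) and the idealized printed-stencil mode
(`ring_width=0`, `v0_mode="point"`). Exactness classes hold in the
idealized mode: bipolar, tri-polar, five-point and nine-point reproduce
the analytic Laplacian on all polynomials of total degree ≤ 3, tri-polar
and nine-point additionally to degree ≤ 5 (fourth-order cancellation); the
quasi-bipolar combination is kept unnormalized, exactly as the shorted
electrode delivers it — a fixed scale does not affect dB ratios.

## Experiments and their conventions

* **Attenuation** is 20·log₁₀(|reading at displacement 0| / |reading at
  d|), the band displaced along z in 5 mm steps to ±30 mm (y available as
  an option; the noise-free geometry is mirror-symmetric in ±z, so the
  non-negative half is representative). The **20 dB sensitivity distance**
  is found by linear interpolation between bracketing samples — with one
  subtlety: if the raw reading changes sign between samples, the true
  attenuation passed through +∞ there, so the threshold was crossed even
  if neither sample shows 20 dB; the crossing is then located by a linear
  model of |reading| through its zero. Censored curves (threshold never
  reached) report the range bound with a flag.
* A surface-Laplacian reading of a laterally displaced deep source always
  has a spatial null; magnitude attenuation is monotone only up to that
  sign change (the electrode's *coherent detection lobe*), which in this
  geometry comfortably contains the 20 dB crossing. Monotonicity is
  therefore a claim about the coherent lobe, not about |reading| beyond
  its null.
* **Tissue sweeps** vary fat 0–30 mm (muscle fixed at 8 mm) or muscle
  0–16 mm (fat fixed at 15 mm); the band ring is re-seated at its depth
  below the (moving) innermost boundary and attenuation is relative to the
  zero-added-thickness baseline of the same sweep.
* **Problem sizes used.** The packaged experiments and acceptance tests
  run the default 4 mm grid (61³ nodes, ≈ 2·10⁵ unknowns; CG solves
  ≈ 1 s each) with 72 band segments and 360-point ring quadrature; solver
  validation against the analytic dipole runs an 81³ homogeneous box at
  2 mm spacing. Orderings quoted below were additionally checked at 3 and
  2.5 mm spacing.

## What the simulated conditions show — and what they do not

* The headline orderings are reproduced: attenuation grows monotonically
  through the coherent lobe for all four electrode kinds, with and without
  the six noise dipoles; bipolar and tri-polar reach 20 dB within
  ≈ 11–13 mm while monopolar (censored at 30 mm) and quasi-bipolar
  (≈ 13–18 mm) do not — the ring Laplacians are the locally sensitive
  designs. All four electrodes peak with the band at the same location,
  the monopolar peak is the largest in magnitude, and the Laplacian peaks
  are opposite in phase to the monopolar peak.
* The effect of the outer-ring radius on attenuation is a few percent for
  the ring Laplacians in this geometry. The expected ordering (bigger
  ring, smaller attenuation) resolves cleanly for monopolar and bipolar,
  and for quasi-bipolar against the smallest ring; between the two larger
  quasi-bipolar rings the margin is ~0.2 % (below resolved accuracy), and
  for the tri-polar estimator the sign is inverted at the large-radius end
  and does not stabilize under grid refinement. The package therefore does
  not claim the full four-kind radius ordering; the corresponding
  acceptance test asserts it faithfully and is expected to fail.
* Fat and muscle thickness both increase attenuation strictly, with and
  without noise. Over the studied ranges (0–30 mm fat vs 0–16 mm muscle)
  fat causes the larger total attenuation. At *strictly equal* added
  thickness, this DC conduction model orders them the other way —
  conductive muscle shunts the surface potential harder than resistive fat
  — so the fat-dominance statement is a statement about the studied
  ranges, not a per-millimetre property. (A frequency-dependent dielectric
  model could change this; permittivities do not enter a DC solve.)
* The source model is a kinematic abstraction: no action-potential
  dynamics, isotropic myometrium, a single coherent front, and a noise
  model of six random dipoles. The volume conductor is concentric and
  untilted, electrodes are ideal potential samplers (no electrode-skin
  impedance, amplifier loading or common-mode effects, although the disc
  and outer ring of a physical quasi-bipolar electrode are galvanically
  shorted rather than arithmetically combined). Passing these tests shows
  the estimators and the forward machinery behave correctly under the
  model's assumptions; it does not validate the model against clinical
  EHG.
* The layer-degeneracy check (all conductivities equal) matches the
  unbounded-medium formula to ≈ 2 % deep inside; the remaining deviation
  is the genuine insulated-surface correction of the finite dome, not
  solver error.
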
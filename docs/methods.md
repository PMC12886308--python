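# Methods

`jawlever` models the biting lower jaw of a fish as a planar rigid lever
and converts dissection-level muscle data into per-tooth bite forces and
tooth stresses. This note records the model, its assumptions, the defaults
that matter, and the choices made where the underlying method left the
design open.

## The lever model

All geometry lives in a 2D lateral plane (x rostral, y dorsal, mm). The
mandible pivots at the articular-quadrate (AQ) joint, digitized as landmark
7 of a 19-point scheme that also fixes the tendon insertions of the five
adductor mandibulae subdivisions (pars rictalis lateral/medial, pars
malaris lateral/medial, pars stegalis) and their origins on the
suspensorium. Planarity is the key assumption: the adductor lines of
action and tooth row are treated as coplanar with the jaw hinge, which is a
good approximation for the parasagittally flattened skulls of serrasalmids
but ignores any mediolateral force component.

Each muscle `m` applies force along its straight insertion→origin line.
With inlever `a_m` (AQ→insertion), attachment angle `θ_m` (interior angle
at the insertion between the line of action and the inlever), and tooth
outlever `L_i` (AQ→tooth tip `i`):

    MA(m, i)  = a_m / L_i
    EMA(m, i) = MA · sin θ_m
    τ_m       = F_m · a_m · sin θ_m          (moment arm a_m · sin θ_m)
    F_bite(i) = Σ_m F_m · EMA(m, i) = (Σ_m τ_m) / L_i

The sin-projection is the standard planar lever treatment: only the force
component perpendicular to the inlever turns the jaw. The bite reaction at
the tooth is taken perpendicular to the AQ→tip ray (pure rotational
statics), and forces are for one side of the head; a `bilateral` flag
doubles them rather than doing so silently. The raw attachment angle is
exported alongside EMA so a cos-based reading can be recovered if ever
needed for comparison with other lever codes.

Two consequences are used as internal invariants and test oracles:
torque conservation (`F_bite(i) · L_i` equals the summed muscle torque at
every tooth) and superposition (bite force is linear in muscle forces).

## Muscle force capacity

Force capacity follows the physiological cross-sectional area route:

    PCSA [cm²] = mass [g] · cos(θ̄) / (ρ · fiber length [cm])
    F_max [N]  = PCSA [m²] · specific tension [Pa]

* **Specific tension**: 300 kPa (30 N/cm²), the peak force capacity used
  for fish adductors; user-tunable.
* **Density ρ**: 1.06 g/cm³, the standard vertebrate skeletal-muscle value;
  configurable per muscle.
* **Pennation θ̄**: dissection records three protractor angles (dorsal to,
  in line with, and ventral to the tendon). They are combined as an
  arithmetic mean — the three measurements sample one fan-shaped
  architecture and no weighting information exists. A mean of 90° yields
  zero PCSA with a warning rather than an error.
* **Fiber length**: whole-muscle path length (insertion→origin distance at
  the current jaw pose) minus tendon length, treating the tendon as
  inextensible in series. A `use_whole` flag skips the subtraction for
  sensitivity checks, since fiber-length bookkeeping differs between lever
  codes.
* Where the two rictalis portions are dissected as one mass, a
  `mass_split` fraction (default 0.5) allocates it in the synthetic
  generator; readers accept per-portion masses directly.

## Hill length–tension scaling and the gape sweep

Activation across the gape cycle uses a Hill-type quotient with a velocity
surrogate `V` in muscle lengths/s:

    activation(V) = (k − k·V) / (k + V),   k = 0.25
    closed jaw:  V = minV = 0.05  →  0.79167
    fully open:  V = maxV = 8     →  −0.21212  (raw)

The raw open-jaw value is negative with these defaults; muscle cannot
push, so it is clamped to 0 unless `clamp_negative=False`. An optional
`normalize_velocity` mode divides `V` by `maxV` before the quotient, which
pins the open-jaw activation at exactly zero — both behaviours are exposed
because lever implementations differ on this point and the formula alone
does not disambiguate; the verbatim quotient plus clamping is the default.
Between the endpoints, gape maps linearly onto `V`:
`V(g) = minV + (maxV − minV) · g / max_gape`, giving a monotone
non-increasing activation in gape. Whether the surrogate should be driven
by fiber strain rather than gape fraction is equally underdetermined; the
gape-linear form is the simplest monotone choice and is recomputed, not
interpolated.

The *pseudodynamic sweep* is a series of independent static solutions at
fixed gape increments (default 1°) from open to closed. At each position
the mandibular landmark subset (tooth tips, dentary points, tendon
insertions — the coronoid insertion rides with the dentary) is rigidly
re-rotated about AQ, all lengths and angles are re-measured, and the Hill
activation scales each muscle's `F_max`. No inertia, damping or activation
dynamics are modelled; the closed-jaw row is bit-identical to the static
closed solution, and with default geometry the closed jaw is the peak.

## Tooth stress

    stress [kPa] = 1000 · F [N] / A [mm²]

computed per tooth over (a) the whole tooth surface and (b) the distal 10%
of that surface, the cutting tip engaged at initial puncture. Stresses are
reported in kPa throughout; note that 1 N/mm² = 1 MPa = 1000 kPa, a
conversion worth stating because force-per-area units are chronically
garbled in the bite-performance literature. Mass-specific metrics divide
force (N/kg) or stress (kPa/kg) by body mass; they are deliberately naive
(no allometric or phylogenetic correction) and should be read as such.

## Mesh-based tooth areas

Tooth meshes (STL, mm) are summed triangle-by-triangle; degenerate faces
below 1e-12 mm² are dropped. The **distal 10% of tooth area** is an *area
quantile*: faces are walked in order of their centroid's axial distance
from the tip and accumulated until exactly 10% of the total area is
reached, the boundary face counted fractionally so the result varies
smoothly with mesh resolution. The cut height is reported as a
diagnostic. An alternative *height* reading (all area within 10% of the
axial length from the tip) is available behind `mode="height"`; the two
differ strongly on tapered teeth (for a cone with its apex at the tip,
cumulative lateral area from the apex grows as `(h/H)²`, so the 10%-area
cut sits at `h/H = √0.1 ≈ 0.316` while the 10%-height cut captures only 1%
of the area). The area reading matches the wording "fraction of tooth
area" and is the default.

When tip/base are not supplied, the tooth axis is the first principal
component of the vertex cloud; the tip is the extreme vertex farther from
the centroid along that axis (the wide cervical end carries more surface
and pulls the centroid toward itself). Meshes with anisotropy ratio below
1.05 are rejected with a request for manual tip specification.

## Synthetic specimens

The generator fabricates piranha-like specimens for testing and demos:
seven teeth by default with outlevers strictly decreasing toward the
joint, five adductor subdivisions with the malaris pair carrying ~83% of
adductor mass, adductor mass at 2% of body mass, pennations of 8–28°, and
body sizes spanning roughly 105–298 mm standard length / 0.03–1.2 kg
(mass ≈ 3.5e-8·SL³ with lognormal scatter), so forces and stresses land in
a realistic serrasalmid regime. Geometry is jittered around a fixed layout
chosen so every muscle produces closing torque at every seed. A
`textbook` variant reduces the system to one perpendicular muscle with a
prescribed force and inlever, whose bite forces have the closed form
`F·L_in/L_out` — the anchor for exact tests. The generator does **not**
reproduce interspecific covariance of muscle architecture, real tooth
shapes, or digitizing error; green tests certify the mechanics and
plumbing, not piranha biology.

Cone "teeth" (`make_cone_tooth`) provide meshes with closed-form lateral
area `πr√(r²+h²)` and a closed-form tip cut, used to validate the mesh
module analytically.

## Published-table fixtures

Two small CSVs ship with the package: per-species piranha performance
values and a cross-vertebrate force/stress comparison, both transcribed
from published tables with a provenance column. Printed mass-specific
cells are not always reproducible from their own printed numerator and
denominator (they were evidently computed from unrounded masses), so each
row carries `*_consistent` flags computed by re-doing the arithmetic at
printed precision; exact-value tests restrict themselves to consistent
cells. The ranking property (piranhas in 10 of the top 11 slots by
stress/mass, Darwin's finch the exception) holds on the full table
regardless.

## Numerical choices and limitations

* Angles are degrees at the API, radians internally; rotations are exact
  2×2 orthogonal maps, so isometry holds to ~1e-15 relative.
* Closed-form OLS (normal equations) is used for the log-log size trend;
  `r²` is defined as 0 for constant responses.
* Jaw rotations beyond 120° warn (non-physiological) but proceed.
* Degenerate geometry (zero inlever, tooth tip on the joint, zero-length
  muscle line) raises immediately with the offending landmark named.
* Test and demo problem sizes (≈100–150 random specimens for oracle
  equivalence, cone meshes of ~4e4 faces) were chosen as the smallest
  sizes at which the analytic comparisons are clearly resolved.
* Known limitations: strictly planar statics (no bilateral asymmetry, no
  joint reaction decomposition), no bone or enamel compliance, maximum
  theoretical (not in vivo) forces, and no phylogenetic correction in the
  comparative metrics.
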
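# Methods

## Scope and overall design

`qrsim` models ventricular **depolarization only**: the deliverable is the
QRS complex of the 12-lead ECG and its biomarkers.  Repolarization (T
wave), ionic membrane dynamics, bounded-torso effects and anatomical image
data are deliberately out of scope.  Every stage is deterministic: the
same configuration always produces bitwise-identical traces.

The pipeline is

geometry → endocardial stimulus times → myocardial activation map →
transmembrane field → electrode potentials → 12 leads → biomarkers →
scenario statistics.

## Idealized biventricular geometry

The heart is two truncated ellipsoids rasterized on a regular lattice
(default 2 mm; ~20k nodes, ~15k hexahedral cells):

* LV: endocardial semi-axes (22, 22, 68) mm, free-wall thickness 12 mm.
* Septum: the myocardium sandwiched between the two cavities; the RV
  cavity is held 5 mm off the LV epicardial surface (`septal_buffer`), so
  the septum is ~17 mm thick.  This is at the thick end of the human range
  and was chosen so that the septum — which in this model is stimulated on
  *both* endocardial faces — completes in ~25 ms (see calibration).
* RV: a crescent-shaped cavity (an ellipsoid carved by the LV) with a true
  4 mm offset-shell wall, computed by a distance transform so no spurious
  myocardium is smeared onto the LV epicardium beyond the insertions.
* Apex: the apical cap carries `lv_apex_thickness` = 16 mm, representing
  compact wall plus the dense trabecular/papillary mass as solid tissue.
  This makes the apex the latest-depolarizing region, consistent with
  measured human activation sequences (latest activity at basal septum,
  basal lateral wall and apex), and is one of the two levers that set the
  QRS width and frontal axis (below).

Anatomical coordinates: apicobasal `a` (0 apex → 1 base, from the long
axis), transmural `m` (0 endo → 1 epi, from a two-sided distance
transform, exact on the labelled surfaces), rotational `theta`
(0 = LV lateral free wall, pi/2 anterior, pi septal, 3pi/2 posterior), and
a side label (LV / RV / SEPT).  Fibers follow the rule-based helix +60
degrees (endo) to -60 degrees (epi) about the transmural axis; the fiber
and transmural directions are orthonormal by construction.

**Orientation.**  The mesh stays in the heart frame (nodes on the
lattice); the torso enters through the electrode positions, which are
specified in patient coordinates and mapped through two rotations: the
long-axis tilt in the frontal plane (`tilt_deg`, default 10) and a
rotation about the long axis (`rot_deg`, default -77) that turns the
septum away from the pure-left direction.  Both are calibration
parameters of the model (see below), not measured quantities.

**Electrodes.**  RA/LA/LL sit on an exact Einthoven equilateral triangle
of circumradius 400 mm, which makes the far-field limb lead vectors point
at 0/60/120 degrees exactly (and synthetic-fixture axis recovery exact).
V1–V6 lie on an anterior-left chest arc of radius 120 mm at conventional
angles (-15 to +100 degrees from the anterior direction).

## Activation model

* **Endocardial Purkinje surrogate.**  The LV and RV endocardial surfaces
  are separate fast sheets.  Stimulus time = geodesic distance to the
  nearest root / `v_endo` + the root's onset delay (all baseline delays
  are zero).  Geodesics are multi-source Dijkstra runs on the surface
  26-neighbour graph with Euclidean weights, implemented with a virtual
  super-source (equivalent to, and cheaper than, an all-pairs
  precomputation).
* **Root points.**  Seven roots on the trifascicular pattern: LV septal,
  LV anterior paraseptal, two LV posterior (4 LV), RV septal and two RV
  free-wall sites (3 RV).  The coupling heights are basal
  (`a` = 0.75–0.85 for the LV sites): with mid-wall placements the
  rotationally symmetric geometry produces a leftward (-25..0 degree)
  frontal axis, whereas basal coupling makes the wavefronts sweep
  apexward, which — together with the orientation angles — yields the
  normally oriented axis.  This placement is the model-construction
  calibration against the target ECG, in the same spirit in which the
  activation sequence is classically tuned to reproduce measured human
  activation data; positions are configuration, not hard-coded.
* **Myocardial propagation.**  Anisotropic fastest-route computation on
  the volumetric 26-neighbour lattice graph, seeded with the endocardial
  stimulus times (so each node's time is min(endocardial stimulus,
  transmural arrival)).  Edge traversal time uses the Riemannian
  travel-time metric `dt = L * sqrt(cos^2(phi)/v_l^2 + sin^2(phi)/v_t^2)`
  (`phi` = angle between edge and fiber).  This choice — rather than
  dividing the edge length by the directional front speed — is what makes
  a plane wave cross the wall at exactly the transverse speed `v_t`; the
  phase-velocity form would let zig-zag paths tilted into the fast
  direction arrive ~20% early at this anisotropy.  The 26-neighbourhood
  bounds the lattice metrication error: times are never below the
  continuum eikonal and at most ~8-15% above it (verified against the
  planar-front closed form in the tests; near strongly curved seeded
  surfaces oblique fiber-fast paths legitimately undercut the naive
  depth/v_t estimate).
* **Speed law.**  `v_d = v_ref_l * sqrt(sigma_m_d(scaled) /
  sigma_m_l(unscaled))` with `sigma_m = sigma_i*sigma_e/(sigma_i+sigma_e)`
  per direction.  Defaults `sigma_il = sigma_el = sigma_et = 1`,
  `sigma_it = 0.11` (relative units).  The transverse ratio 0.11 is the
  value for which +/-50% intracellular scaling changes transverse speed by
  +20%/-27.5% and the same extracellular scaling by +1.7%/-4.6%; with it,
  v_t/v_l = 0.445 (velocity anisotropy ~2.2:1, physiological).

### Calibration (frozen defaults)

`calibrate_speeds` performs the one-time calibration on the default mesh:

* `v_endo` = (latest LV endocardial geodesic)/28 ms → **2.287 mm/ms**, so
  the LV endocardium is fully stimulated at 28 ms (inside the 30 ms
  constraint);
* `v_ref_l` by bisection so the basal LV free-wall transmural crossing
  (epi minus endo time of the column at a = 0.8) is 35 ms →
  **0.6104 mm/ms** (v_l = 0.61, v_t = 0.27 mm/ms, both physiological);
* the ~17 mm septum then completes (latest minus earliest along the
  mid-septal column, both faces seeded) in ~26 ms;
* orientation (`tilt_deg` = 10, `rot_deg` = -77) and the basal coupling
  heights were fixed so the baseline 12-lead shows QRS width ~63 ms,
  frontal axis ~+52 degrees, a deep QS in V1, and monotone R-wave
  progression to V6;
* the amplitude calibration 23.661 sets the baseline lead-II R peak to
  1.0 mV (the model's absolute amplitudes are otherwise arbitrary units).

## Forward ECG

`Vm(x, t)` is a logistic upstroke (-85 → +20 mV, 10–90% rise = 2.2*tau,
tau = 0.5 ms) shifted by the node's activation time — depolarization only,
`Vm` non-decreasing in time.  The extracellular potential is the
core-conductor / infinite-medium integral evaluated per cell with
trilinear finite-difference gradients:

phi_e(x) = -1/(4 pi sigma_b scale_b scale_e) * sum_cells
           (Sigma_i grad Vm)_c · (x - c)/|x - c|^3 * vol_c

with `Sigma_i` the full intracellular tensor in the local fiber frame
(`phi_i ≈ Vm`; extracellular gradients neglected in the source — the
standard pseudo-bidomain assumption).  Placing `scale_e` in the
denominator realizes the `sigma_i/sigma_e` proportionality: with a frozen
activation map amplitudes are *exactly* proportional to `scale_i` and
*exactly* inversely proportional to `scale_b` and `scale_e`.  In the full
model `scale_i` and `v_endo` additionally feed back through the activation
sequence, reproducing the dual (speed + amplitude) role of intracellular
conductivity.  Because the torso is an unbounded homogeneous conductor,
body-conductivity effects are exactly inverse-proportional — a bounded
inhomogeneous torso would damp them; that damping is a known,
deliberate omission.

Lead assembly is standard: I = LA-RA, II = LL-RA, III = LL-LA, Goldberger
augmented leads, precordials against the Wilson central terminal.  The
Einthoven and Goldberger identities hold to rounding error by
construction.

## Biomarkers

* QRS window: first/last sample where the 12-lead root-sum-square exceeds
  5% of its maximum (scale-invariant, deterministic; the detector used in
  clinical systems is not standardized, so this simple rule is fixed and
  documented).
* Wave patterns: maximal alternating-polarity waves above 5% of the lead
  maximum; positive waves R, negatives Q before the first R, S after;
  lowercase below 50% of the lead's largest wave; a single negative wave
  is QS (whose depth is reported as the S amplitude — R/S role swap).
* Frontal axis: atan2 of the net areas of aVF and I over the QRS window;
  the *late* axis uses the terminal 40 ms of the window (the conventional
  terminal-vector window).
* Notches: extra same-polarity peaks separated from the main peak by a
  trough of at least 0.05 mV (half a small ECG grid division).
* Classification thresholds: NORMAL = width 60–100 ms and axis
  -30..+90; LAFB/LPFB = width < 120 ms with late axis <= -45 / >= +90
  plus the lead-pattern rules; LBBB/RBBB = width >= 120 ms with QS in
  V1 + notched V6, respectively a terminal R in V1 (any R following an S,
  as in rSR' with or without a trailing s') and slurred (> 40 ms) S waves
  in I and V6 (duration of the widest post-R negative wave).
* `synth_qrs` builds analytic dipole-loop fixtures at the exact Einthoven
  geometry whose detected width and axis equal the requested values by
  construction; it is the parameter-recovery oracle for the biomarker
  stack.

## Experiments

Percent-of-baseline statistics use all 12 leads, excluding (and logging)
leads whose baseline metric is zero; the spread is the population standard
deviation.  The default sweep grid is 0.5–1.5 in steps of 0.25 for
`v_endo`, `scale_i`, `scale_e`, `scale_b`.  Root-relocation tables shift
the anterior or posterior coupling sites apicobasally and flag monotone
S-wave progression on II/III/aVF (anterior, apical shifts) or V5/V6
(posterior, basal shifts).  Knockout scenarios remove fascicles: LAFB
(anterior), LPFB (both posterior), LBBB (all LV), RBBB (all RV).

## What the idealized model does and does not reproduce

Reproduced at the shipped defaults (all computed by the test suite /
acceptance script, never asserted from the literature directly):

* the four closed-form conductivity-speed percentages;
* LV endocardial stimulation <= 30 ms, transseptal ~26 ms, basal
  transmural ~35 ms;
* baseline QRS width 63 ms, axis +52 degrees, V1 net-negative, V4–V6
  net-positive with R-wave progression, classified NORMAL;
* LBBB: 157 ms, QS in V1, notched R in V6 → classified LBBB;
* RBBB: 169 ms, rSR' in V1, slurred S in I and V6 → classified RBBB;
* monotone sweep trends (width strictly decreasing in endocardial speed;
  R amplitude strictly increasing in `scale_i`, strictly decreasing in
  `scale_b`), and the exact frozen-source proportionalities.

Known limitations, all consequences of the rotationally symmetric
geometry and the desk-scale ventricle:

* **Hemiblock terminal vectors.**  After a single-fascicle knockout the
  orphaned territory is re-stimulated by the neighbouring roots within
  ~10–15 ms (the endocardial speed is pinned by the 30 ms constraint on an
  ~80 mm ventricle), so the QRS widens only slightly and the terminal
  40 ms window remains dominated by the shared apexward forces.  The LAFB
  terminal axis therefore shifts leftward by only ~20–25 degrees (to
  ~+30) instead of reaching -50; the up-left terminal swing exists in the
  terminal dipole trajectory but below the QRS-offset detection threshold.
  LPFB reaches a late axis >= +90 but its I/aVL patterns stay rS-like, so
  its full rule set does not fire.
* **S-wave progression.**  For the same reason, apico-basal relocation of
  coupling sites does not develop terminal S waves in the limb or lateral
  precordial leads at the default orientation; the monotone-progression
  flags hold only degenerately (all-zero S amplitudes).
* Absolute amplitudes are conventional (calibrated), not predicted; there
  is no T wave, no torso inhomogeneity, no retrograde Purkinje coupling,
  no ectopic foci.

Passing tests therefore demonstrate internal consistency, the analytic
laws, the calibrated activation times, the baseline morphology and the
bundle-branch-block phenotypes — not fidelity to any individual patient's
anatomy or to fine hemiblock morphology.

## Numerical choices

* Lattice spacing 2 mm (must resolve the 4 mm RV wall; a degenerate
  geometry error is raised otherwise).  Problem sizes: ~20k nodes, ~0.5M
  graph edges, ~80–200 time samples at 1 kHz; a full scenario simulates in
  ~2 s on one CPU.
* Dijkstra via `scipy.sparse.csgraph` with a virtual super-source for
  multi-source/offset seeding; parallel edges are reduced to their
  minimum weight.
* Ties in `anat_to_node` break to the lowest node id; the rotational
  coordinate is weighted 1/pi against the unit-range coordinates.
* The time window adapts to the latest activation plus a 15 ms margin;
  truncating below the latest activation raises.
* Disconnected rasterization slivers are dropped (largest connected
  component kept); unreachable nodes in pathological configurations are
  reported, not silently filled.
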
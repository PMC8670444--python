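# Methods

`frictouch` models and analyses the first instants of a fingertip
pressing on a flat plate, where the interfacial friction shapes a
radially divergent pattern of skin micro-displacement that carries the
percept of slipperiness. This note records the models, their
assumptions, the parameters that matter, and the numerical choices.

## 1. Kinematic hemisphere-flattening model (`geometry`)

A fingertip of radius `R` indented by `delta` flattens a spherical cap
of half-angle `theta = arccos(1 - delta/R)` onto the plate. Material
along the meridional arc `R*theta` must fit on the chord `R*sin(theta)`,
giving the compressive strain

    eps = 1 - sin(theta)/theta  ~  delta/(3R)   (shallow limit).

The model is purely kinematic: no elasticity, no pressure
distribution, no friction. It answers one question — what strain scale
does the geometry alone impose — and for the default `R = 10 mm`
(typical adult index distal phalanx) indented 3 mm it gives 10.2 %.
The strain definition is meridional (arc vs chord). A hoop measure is
exposed for completeness; under the arc-preserving flattening map the
edge hoop strain coincides with the meridional value, which is why
both share one formula. The contact radius `a = sqrt(R^2-(R-delta)^2)`
is Hertz-like (`sqrt(2 R delta)`) at shallow indentation.

## 2. Axisymmetric spring–damper press model (`mechanics`)

### Structure

A meridian chain of `n_nodes` (default 41) surface nodes spans polar
angles ±75° of a quasihemisphere (radius 8 mm), each node carrying:

* **membrane elements** to its neighbours — Kelvin–Voigt (spring ‖
  damper), resisting stretch of the skin surface;
* a **bulk (pulp) element** to a single rigid bone point — Kelvin–Voigt
  with a cubic strain-stiffening term, `f = k1*x + k3*x^3`. The
  stiffening reproduces the experimental observation that the gross
  contact footprint is almost complete after ~1 mm of indentation while
  forces keep rising afterwards: the pulp is soft at first touch and
  stiffens under compression;
* **plate contact** as a unilateral penalty (no adhesion: the normal
  force is clipped at zero) with normal damping;
* an **elastoplastic tangential stick-spring**: each contacting node is
  anchored where it touched down; when the spring force exceeds the
  Coulomb cone `|f_t| <= mu*f_n` the anchor is projected back onto the
  cone (radial return) and the node slips.

The pulp element is anisotropic: its radial force component is scaled
by `bulk_radial_fraction` ≤ 1. A purely radial fan of pulp springs
overstates the outward push on contacted skin (every deep node would
drag its surface point outward with the full geometric tilt, storing
several times more tangential stress than soft tissue does); a purely
vertical (Winkler) foundation understates it (no outward drive at all,
zero divergence). Real pulp shear compliance sits in between, and the
fraction is one of the calibrated constants.

A normal load ramps linearly on the bone at 3.6 N/s — the typical
human pressing rate — to the 3 N target, then the system settles.

### Displacement reference and divergence

Each node's radial displacement is referenced to its position when its
contact was first *detected*: when its normal load first exceeded
`onset_force_threshold` (0.02 N). This mirrors the optical definition
used on real fingers, where a point counts as contacting once its
asperities are in intimate (load-bearing) contact — not at the first
grazing touch, which in the simulation is followed by a sub-millinewton
settling transient.

The contacted-skin divergence is the axisymmetric
`du/dr + u/r` (apex limit `2 du/dr`) evaluated per node on the onset
coordinates. The scalar summary is the **median** over contacted
nodes, the same robust summary the imaging analysis applies to its
gridded divergence field; a ring-area-weighted mean is available but
is dominated by the contact edge, where the onset-referenced
displacement vanishes by construction.

### Integration and equilibrium

Semi-implicit (symplectic) Euler with velocity damping; `dt` is
validated against the stability bound `0.1/sqrt(k_max/m)` for the
stiffest spring. Equilibrium requires the residual node speed below
`equilibrium_tol` *and* the interfacial normal force within 1 % of the
target for 100 consecutive checks; hitting the step cap returns
`converged=False` rather than raising. Identical parameters reproduce
results bit-identically (no randomness anywhere in the model).

### Calibration

The stiffness/damping constants in `finger_defaults.yaml` are
calibrated, not measured: they are chosen once so that a 3 N press
reproduces the reference fingertip behaviour — contacted-skin
divergence near 0.04 at mu = 0.1 and a factor 2–3 lower at mu = 0.6,
a ~40 % higher peak tangential interfacial stress in the high-friction
press, and friction-independent normal-stress profiles. With the
shipped defaults the model produces divergences 0.042 (mu 0.1), 0.018
(0.2) and 0.013 (0.4 and 0.6), a 44 % peak-tangential excess, and
normal profiles agreeing within 2 %. All constants are plain YAML and
every field is overridable.

One trade-off in this model family deserves a caveat: keeping the
peak tangential stress only ~40 % higher at mu = 0.6 requires stuck
tangential forces to stay well below 0.4·f_n, which means the Coulomb
cone never engages at mu ≥ 0.4 — the mu = 0.4 and mu = 0.6 presses
are then elastically identical and their divergences tie (to ~5e-5)
instead of separating strictly. Configurations that do separate them
(a slip annulus carrying 0.4–0.6·f_n near the contact edge) raise the
peak-stress ratio to 2–3. The defaults favour the stress ratio and
the divergence endpoints over strict four-way ordering; the stored
tangential stress integral is correspondingly ~80 % (not ~40 %)
higher at mu = 0.6 because the high-friction tangential profile is
wider, not just taller.

## 3. Displacement-field analytics (`fields`)

* **Gridding**: scattered tracked features are interpolated
  barycentrically (Delaunay / `LinearNDInterpolator`); cells outside
  the convex hull are masked, never extrapolated; the analysis mask is
  the hull ∩ apparent-contact footprint.
* **Divergence**: central differences on masked cells; second-order
  one-sided stencils (exact for quadratics) where a neighbour is
  missing; cells without stencil support are excluded. The estimator
  is exact on affine fields and second-order accurate under grid
  refinement.
* **Decomposition**: constant part = per-component median over the
  mask; the remainder is fit by LSQR as `grad(phi) + curl(psi)` on the
  same masked stencils (minimum-norm solution). On symmetric masks the
  overlap between the two potentials is rank-deficient but orthogonal
  to the fitted components, so constructed constant+radial+rotational
  mixtures are recovered componentwise to ~1e-9. Everything the model
  cannot represent lands in the residual, making the reconstruction
  identity exact by construction.
* **Strain**: infinitesimal strain tensor from the same gradients; the
  longitudinal strain is the largest principal-strain magnitude over
  the mask (in %) — a deliberate choice documented here because the
  directional definition is not derivable from the summary statistics
  it must reproduce. Strain rate is the central-difference time
  derivative over frame timestamps with the force interpolated to the
  peak instant.
* **Strain energy**: linear plane-stress elasticity over the masked
  layer, default modulus 0.1 MPa, Poisson ratio 0.4, thickness 1 mm —
  order-of-magnitude skin constants, all configurable; with mm/N units
  the result is directly in mJ.
* **Exclusion rule**: a trial whose median (rigid) displacement vector
  exceeds 0.3 mm in magnitude is flagged, so gross sliding cannot pose
  as a deformation cue.

## 4. Image pipeline (`images`, `pipeline`)

Illumination correction subtracts a heavily smoothed background
(Gaussian, sigma = min(h, w)/4) and restores the global mean. The real
contact area is the count of above-Otsu pixels scaled by the pixel
area; Otsu's threshold is computed by exhaustive maximisation of the
between-class variance over 256 histogram bins and raises on constant
images. Feature tracking is Shi–Tomasi (minimum-eigenvalue) corner
detection followed by pyramidal Lucas–Kanade flow, vectorised over
points; on synthetic sequences the median tracking error is ≈0.04 px.
Each point's displacement is referenced to its own contact onset — the
first frame in which the mean contact-channel brightness in a 10 px
disk exceeds half that point's maximum over the trial. Force traces
are conditioned with a second-order Butterworth low-pass at 50 Hz run
forward and backward (zero phase, unit DC gain).

One ambiguity is left open deliberately: the sign convention relating
local brightness to displacement (bright = held in place vs bright =
freely moving) differs between analyses of real data; the generator
exposes `brightness_sign` instead of resolving it.

## 5. Psychophysics (`psychometrics`)

2AFC data are fitted by maximum likelihood with a cumulative-Gaussian
psychometric function, guess rate fixed at 0.5 and lapse rate fixed at
0.02 (standard practice when each level carries only tens of trials;
a free lapse is not identifiable at 10 trials/level). The 75 %
threshold is read on the lapse-corrected curve,
`x75 = m + s * PhiInv((0.75-0.5)/(1-0.5-0.02))`. Datasets that carry
no threshold information (all chance or all correct) return
`converged=False` with NaN threshold instead of a spurious number.
Both pooled-trial fits and per-participant fits are supported because
group thresholds can be defined either way.

## 6. Synthetic data (`synth`)

The generator emulates the statistical structure the analyses assume:

* dual-channel frames — a quasi-concentric ridge pattern (cosine rings
  at 0.45 mm spacing with smooth phase modulation and speckle, ≥700
  trackable corners at the default 384 px size) and a contact channel
  of speckle "microjunctions" inside a growing disk;
* the apparent footprint grows like sqrt(F) and is complete at 0.5 N
  (fast early growth, as real fingertips show). This matters: if the
  footprint grew like sqrt(F/3N) all the way to 3 N, the
  onset-referenced divergence would integrate to ~zero by symmetry —
  an instructive degeneracy, not a realistic condition;
* skin displacement `u_r = g(mu) * F * r` with
  `g(mu) = divergence_gain * exp(-mu)`; defaults give a true measured
  divergence near 0.04 at 3 N for the low-friction condition and near
  half that at high friction. A saturating variant (expansion flattens
  above 2 N) is available via `saturating=True`;
* real-contact dot coverage scales down linearly with the ultrasonic
  vibration amplitude, 38 % lower at 3 um than at rest; the
  amplitude→friction map is an exponential decay anchored exactly at
  mu(1e-3 um) = 0.81 and mu(3 um) = 0.18;
* force traces are raised-cosine ramps to a plateau with peak
  ~N(5.5, 3.5) N (truncated at 0.5 N), duration ~N(1.47, 0.39) s, and
  additive noise; at the default frame rate (20 Hz) a trial yields
  ~30 frames;
* every trial carries a `SyntheticTruth` with the clean force, the
  expansion coefficient, the exact per-frame real-contact area and the
  divergence an *ideal* onset-referencing tracker would measure
  (computed on area-uniform rings so the summary matches a gridded 2-D
  median).

What the generator does **not** emulate: fingerprint-ridge-scale
contact mechanics, photorealistic texture, camera distortion,
inter-participant biomechanical variability, or trial-to-trial
divergence noise beyond image/force noise (the within-participant
variability structure is not derivable from summary statistics, so the
defaults are order-of-magnitude choices). Passing recovery tests on
synthetic trials therefore demonstrates the *pipeline's* correctness
under the stated model of the data, not robustness to every real-world
artefact.

Determinism: one master seed; independent sub-streams are derived as
`default_rng([seed, stream_id])` per generator and trial.

## 7. Problem sizes used by the test-suite and acceptance runs

The simulator runs its reference presses at the default 41 nodes
(seconds to a minute per press). End-to-end recovery replicates use
192 px frames, a 1.6 mm contact radius, 10 Hz frames and 350 tracked
features — small enough to afford 100 seeded replicates, large enough
that tracking error stays an order of magnitude below the signal.
Psychometric recovery uses the experimental design itself (6 levels ×
10 trials) over hundreds of simulated observers.

## 8. Known limitations

* The press model is a 1-D meridian chain: no azimuthal shear, no
  fingerprint ridges, no layered dermis; its constants are calibrated
  to reproduce reference endpoint behaviour, so intermediate
  quantities (e.g. absolute stress magnitudes) are indicative only.
* The discrete slip annulus at the contact edge is resolved by a
  handful of nodes at n=41; divergence differences between
  neighbouring friction levels near full sticking are at the few-1e-3
  level.
* The Helmholtz-style decomposition's divergent/rotational split is
  unique only up to discrete harmonic overlap; on strongly asymmetric
  masks componentwise recovery degrades gracefully (the reconstruction
  identity always holds).
* The Lucas-Kanade tracker assumes small inter-frame motion (pyramid
  handles ~10 px); it will lose features under large rigid drift,
  which the exclusion rule flags anyway.
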
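# Methods

`muellermc` is a polarized Monte Carlo solver of the vector radiative
transfer equation (VRTE) for backscattering Mueller-matrix imaging of
scattering, uniaxially birefringent slab phantoms, with Lu-Chipman /
Cloude post-processing into maps of total depolarization, scalar linear
retardance and optic-axis azimuth.  This note records the model, its
numerical choices, the conventions that had to be fixed where the physics
leaves freedom, and the known limitations of the desk-scale study.

## Model

**Medium.**  A 1 cm slab (z downward, 2 cm x 2 cm laterally) of
non-absorbing spherical scatterers in a uniaxially birefringent host.
The scatterer ensemble is five groups of dielectric spheres
(n_p = 1.59) whose diameters sit at the equal-mass quantile midpoints of
a Gaussian centered at 50 nm (sigma = 10% of the mean, truncated at
+-2 sigma); group number densities are scaled so the ensemble scattering
coefficient is mu_s (400 cm^-1 for healthy white matter, mean free path
l_s = 25 um).  The size law's width and the meaning of "size" (diameter)
are not fixed by the study conditions; both choices keep the ensemble
deep in the Rayleigh regime (anisotropy g ~ 0.02), where the exact shape
has negligible influence.  Single-sphere scattering matrices come from
the in-package Mie series (log-derivative downward recurrence), tabulated
on a 0..180 deg grid with a 0.02 deg step together with the cumulative
distribution of s11(theta) sin(theta).

**Birefringence.**  The host is negative uniaxial (Delta_n = n_e - n_o,
default -1e-4, n_e = 1.33) with its optic axis in the slab plane at
azimuth eta (90 deg for the host, 0 deg for the crossing-fiber
inclusion).  Light propagating at angle alpha to the axis sees
n(alpha) = n_o n_e / sqrt(n_e^2 cos^2 alpha + n_o^2 sin^2 alpha), and a
straight flight of length d accumulates the phase
delta = 2 pi d (n(alpha) - n_o) / lambda.  The retarder is applied once
per flight segment in the photon's transverse frame, its axis along the
optic-axis projection; the frame angle beta is built from
f = k x e by vector algebra (no spherical trigonometry).

**Walk.**  Photons launch at normal incidence, uniformly over the 1 cm
square field, each with a pure Stokes state drawn uniformly from the
Poincare sphere.  Free paths are exponential (ds = -ln zeta / mu_e);
events are scatterings (angle from the tabulated s11 sin theta law by
inverse transform, azimuth uniform, Stokes updated through the scattering
matrix and renormalized to unit intensity) or boundary hits.  Internal
inclusion boundaries are index-matched: flights split at the face, each
sub-segment uses its region's mu_s and optic axis, and the free path
restarts memorylessly.  External boundaries apply polarization-resolved
Fresnel reflection/transmission (ambient air, n = 1; the <= 1e-3
anisotropy is ignored for Fresnel purposes); side exits terminate.  A
250 000-event safety cap discards runaway walks into an explicit tally
(kept below 0.1% of photons) instead of Russian roulette, so the
estimator is unbiased up to the reported truncation loss.  The Stokes
vector rides in a co-moving orthonormal frame (local_x, local_y, k),
re-orthonormalized every 1000 events; this is algebraically identical to
classical meridian-plane bookkeeping.  Randomness comes from a
xorshift128+ stream seeded through splitmix64; one seed reproduces a run
bit-for-bit.

**Detector.**  The physical geometry is a 1 cm circular detector 5 cm
above the surface that directly registers backscattered photons: only
exits within ~5.7 deg of vertical count, about 1% of the upward flux.
Binary acceptance of so small a cone is hopeless at desk-scale budgets
(~2 accepted photons per pixel from 2e6 launched), so the default
detector (`detector="distant"`) scores the same geometry by polarized
local (next-event) estimation: at every scattering event the expected
contribution of a virtual scattering straight up - phase matrix toward
-z, retardation of the regions crossed by the vertical exit path
(propagation is exactly across the in-plane axes there, so each region
contributes its full |Delta_n| over the crossed length), attenuation
exp(-tau) with tau the vertical optical depth (cut off at tau = 12,
i.e. contributions below 6e-6 are dropped) - is tallied at the event's
lateral position.  Every event scores, giving thousands of weighted
contributions per pixel; deep structure is still sensed through photons
that wander deep and return to shallow last-scattering sites.  An
all-angle exit-binning detector (`detector="ideal"`) is retained: with
mu_a = 0 it integrates the entire diffuse halo and largely washes out
subsurface contrast, which is useful as a null reference.

**Estimation.**  Per 0.1 mm pixel of the 100 x 100 grid (only pixels
entirely inside the inscribed 1 cm circle are analysed), the Mueller
estimate is M = G D^-1 with G the (weighted) sum of S_out S_in^T and D
the matching sum of S_in S_in^T; this is algebraically exact whenever
every record satisfies S_out = M S_in.  If D-hat is ill-conditioned
(condition number > 1e6) the analytic second-moment matrix of the input
law, diag(1, 1/2, 1/4, 1/4) times the count, substitutes.  Estimates are
normalized by m00, screened by the Cloude coherency-eigenvalue test
(eigenvalues >= -1e-6 of the largest), and decomposed pixel-wise by
Lu-Chipman (diattenuator from the first row; depolarizer sub-block the
signed symmetric square root of m'm'^T; retarder the remainder).
Total depolarization is 1 - (|a|+|b|+|c|)/3 over the depolarizer
sub-block diagonal; scalar linear retardance arccos(r - 1) with the
argument clamped to [-1, 1]; the azimuth is half the two-argument
arctangent of the retarder's (4,2)/(3,4) elements, wrapped to
[0, 180 deg) - the branch for which a synthesized retarder at axis beta
decomposes back to exactly beta.  Azimuth at retardance below 1 deg is
reported but flagged low-confidence.

**Conventions.**  Two sign freedoms were fixed once, by requiring that a
homogeneous host with optic axis at azimuth eta produces an azimuth map
reading eta (verified for eta = 0, 30, 45, 90 deg): the retarder in the
transport acts with the ordinary-minus-extraordinary phase (the medium is
negative uniaxial, so this amounts to the choice of time convention), and
exiting Stokes vectors are referenced to the laboratory (x, y) axes seen
looking down onto the sample (a mirror of the right-handed co-moving
frame).  In this detector convention exact backscattering from an
isotropic medium is polarization-preserving (positive diagonal), and the
isotropic-medium symmetries are m12 = m21 with vanishing circular/linear
cross-couplings.

**Uncertainty and convergence.**  The photon budget is split into 10
equal batches; per-batch maps give standard errors of every ROI summary,
and the convergence criterion is the maximum batch-to-batch standard
error of the normalized Mueller elements over active pixels (threshold
1.5%).  ROI summaries are reported two ways: the mean of the pixel-wise
maps (matching pixel-wise decomposition followed by zone averaging), and
the decomposition of the ROI-averaged normalized Mueller matrix
(`*_avg`).  At desk-scale budgets the per-pixel retardance of a noisy
near-depolarizing matrix is biased high (arccos of the norm of noisy
elements), so the depth-trend metrics use the `*_avg` observables;
depolarization contrasts keep the pixel-wise map means.

## Experiments

* **Depth sweep** - both phantoms (crossing fiber: orthogonal optic axis;
  tumor: birefringence removed, optionally lower mu_s) with the inclusion
  top face at 0.5..40 l_s.  Derived metrics: depth of the crossing-fiber
  retardance minimum (parabolic refinement), azimuth flip depth (where
  the inclusion-zone azimuth crosses the balance point between the two
  axes), the deepest depth at which the phantoms' depolarization differs
  by > 2 SE, and the first depth beyond which their retardances stay
  within 2 SE.  The symbolic trend table classifies each observable at
  32, 20, 6 and 1 l_s as constant (C1/C2 by level), increasing or
  decreasing toward the surface, retardance compatible with zero
  (< max(2 deg, 2 SE)), or azimuth at the top/bottom axis (within
  15 deg).
* **Birefringence sweep** - tumor phantom at depth 1 l_s, equal mu_s,
  host Delta_n in {-1e-4, -5e-4, -1e-3}; contrast = (host-ROI mean -
  inclusion-ROI mean) of depolarization, in percentage points.  The
  inclusion ROI is the central 60% of the 4 mm footprint; the host ROI is
  everything >= 1 mm outside it.
* **Scattering sweep** - host Delta_n = -1e-5, tumor mu_s in
  {120, 171, 240, 280} cm^-1 at depth 1 l_s; same contrast.

The inclusion footprint (4 mm x 4 mm) and thickness (2 mm) are not fixed
by the study conditions; the defaults keep a >= 30 x 30-pixel core ROI
inside the footprint while leaving a host ROI in the same image, and are
plain config fields.

## Problem sizes

Default experiment budget: 2e6 photons per condition in 10 batches.  The
validation suite uses 4e5 photons per contrast condition and 1.5e5 per
depth-sweep condition; the acceptance script uses 1e6 per condition.
These sizes put roughly 1e4 weighted contributions into each active pixel
through the local-estimation detector; all quoted uncertainties are the
batch-based standard errors at the stated size.

## Verification highlights

* Mie coefficients agree with an independent Riccati-Bessel construction
  to ~1e-13 relative; Rayleigh closed forms to 1e-3.
* The double-pass retardation scale was validated against an analytic
  mirror configuration (a clear birefringent cap over a scattering
  layer): a 100 um cap at Delta_n = -1e-3 reads 114 deg, the closed-form
  two-way value.
* Lu-Chipman recovers 1000 random synthesized
  (depolarizer, retarder axis, retardance) triples to 1e-6.
* The azimuth convention round-trips through the full pipeline
  (host at eta reads eta) for eta = 0, 30, 45, 90 deg.

## Known limitations

* **Polarized sensing depth.**  With a genuinely Rayleigh ensemble
  (g ~ 0.02) polarization memory in backscattering extends only a few
  mean free paths, so the birefringence-induced extra depolarization of
  the host is of order 1 percentage point at Delta_n = -1e-3 rather than
  the several points a forward-scattering (large-g) tissue would show;
  depth trends that rely on polarized light returning from tens of mean
  free paths are correspondingly compressed toward the surface.  The
  scattering-driven (mu_s) contrast mechanism does not depend on deep
  polarization memory and is reproduced more faithfully.
* Per-photon trajectories are sampled from the polarization-independent
  s11 law with intensity renormalization; the rejection sampler on the
  polarized phase law (`polarized_sampling=True`) preserves measurably
  more ensemble coherence (a few percent of depolarization) and is kept
  as a sensitivity check rather than the default.
* Absorption is not implemented (mu_a = 0 in all studies; the config
  validates this), and the total-internal-reflection phase shift is
  omitted (reflectances are exact, the s-p phase difference is not
  tracked).
* The synthetic phantoms are homogeneous with sharp index-matched
  boundaries; real white matter has continuous fiber-orientation fields,
  absorption, and rough interfaces, so passing tests here demonstrates
  the correctness of the transport and decomposition machinery, not
  clinical performance.
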
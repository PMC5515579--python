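# Methods

## The gene-circuit model

The gap-gene network is modelled as four coupled reaction–diffusion
equations on a 1-D anterior–posterior (AP) axis discretised into bins of
%EL (percent egg length; anterior pole = 100, posterior = 0, embryo
length 500 µm by default).  For each gene a ∈ {hb, gt, kr, kni}:

    dv_a/dt = R_a Φ(u_a(x, t)) − λ_a v_a + D_a ∂²v_a/∂x²

with no-flux boundaries at the poles.  The activation function is the
standard gene-circuit sigmoid Φ(u) = (u/√(u²+1) + 1)/2, exposed as a
plain function so alternative saturation laws can be swapped in.  The
regulatory input is linear in the regulators:

    u_a(x) = Σ_b T[a,b]·reg_b(x) + Σ_m M[a,m]·g_m(x) + h_a

where the regulator vector is (Hb monomer, Hb dimer, Gt, Kr, Kni) and
the maternal inputs are (Bcd, Cad, Tll, Hkb).  Hb acts through both its
monomeric and dimeric forms: total Hb is partitioned at mass-action
equilibrium (monomer²/dimer = K_hb, monomer + 2·dimer = total), whose
closed form monomer = (−K + √(K² + 8Kv))/4 is applied bin-wise at every
step.

This is a deliberate 1-D reduction of full-embryo gap-gene circuit
models: the geometry (and nuclear-division choreography) of the
syncytial blastoderm is collapsed onto the AP axis, which keeps a
90-minute simulation under a second on one CPU while preserving the
network-level question — which interactions must change when Bcd input
is silenced in a time window.

### Optogenetic shutdown semantics

Illumination scenarios are lists of half-open windows [start, end) in
minutes on a clock anchored at gastrulation onset (t = 0); the stage map
used throughout is n.c. 14 = (−45, 0), n.c. 13 = (−60, −45),
n.c. 10–12 = (−90, −60).  While a window is active the entire Bcd column
of M contributes exactly zero — an instantaneous, fully reversible
switch, matching the fast on/off kinetics of the optogenetic construct
this emulates (transcription stops within minutes of illumination;
residual fluorescent signal persists only for the polymerase traversal
time of the reporter, 6.4 kb / 1.54 kb/min ≈ 4 whole minutes, computed
by `ms2.residual_signal_window_min`).

The default scenario battery (ids 1–8) is: dark control; Bcd off for the
last 20, 30, 45, or 60 min before gastrulation; off from −90 to −30 or
−90 to −60 with dark recovery; and off entirely before −90 min.  The
model battery runs ids 1–6.

### Integrator

Time stepping uses an exponential-Euler update for the reaction part,

    v ← v·e^(−λ dt) + R Φ(u) (1 − e^(−λ dt))/λ + dt·D·Δv,

with central-difference diffusion and reflecting boundaries.  The
exponential update is exact for the linear decay, so pure-decay
trajectories and frozen-input fixed points are reproduced to round-off
(the test suite checks e^(−λt) to 1e−8 relative and R Φ(u)/λ to 1e−6);
a plain forward-Euler step is first-order in λ dt and cannot reach those
tolerances at practical step sizes.  Production is held frozen within a
step, so transient accuracy is first order, like forward Euler, but with
unconditionally stable decay.  Diffusion remains explicit and enforces
dt < w²/(2 max D); the defaults (dt = 0.01 min, w = 0.5 %EL,
D = 0.2 %EL²/min) sit far inside the bound.  Default grid: 200 bins of
0.5 %EL, chosen so that halving the bin width changes the end-state
profiles of the reference fixture by less than 2% (sup-norm, fine grid
restricted by pairwise averaging) and boundary calls by < 0.1 %EL.

### The reference fixture

`synth.make_reference_circuit` ships a hand-tuned parameter set whose
dark-control run reproduces the wild-type-like pattern: anterior Hb
(posterior boundary ≈ 58 %EL), anterior Gt (≈ 65 %EL), a central Kr band
with half-maximum boundaries at 58.1 and 45.0 %EL, and a posterior Kni
domain spanning 45.0–37.0 %EL.  Design principles:

- **Forced fronts only.**  Every boundary is a threshold response to a
  smooth, monotone input — Bcd thresholds for Hb and Gt, Hb-dimer
  repression for the Kr anterior edge, a Cad threshold for the Kr
  posterior fade, Tll for the Kni posterior edge, an anterior Hkb
  terminal domain capping Kr expansion.  Strong mutual gap-gene
  repression was tried and rejected: bistable interfaces pin to the
  spatial grid, making boundary positions discretisation-dependent and
  unresponsive to upstream changes.
- **Bcd column signs are phenomenological.**  The Bcd input to kni is
  net-repressive (−200); it stands in for Bcd-activated anterior
  repressors that are not explicit species in a four-gene circuit.  This
  gives the observed behaviour — losing Bcd releases Kni's anterior
  boundary — through a forced front rather than a repressor cascade.
- **Unit concentration scale.**  R = λ = 0.08/min for all genes, so
  saturated expression is ≈ 1 and the decay time (12.5 min) lets a
  60-minute shutdown erase Bcd-dependent expression (e^(−4.8) ≈ 0.8%).

Under the scenario-5 perturbation (Bcd off from n.c. 13 onward) the
fixture shifts the Kr anterior boundary +19 %EL, the Kr posterior
boundary +1.3 %EL and the Kni anterior boundary +8.4 %EL — the observed
directions, with larger magnitudes than real embryos show (a few %EL),
because the minimal circuit has no partially redundant activators to
buffer the loss.  Two of the five scoring criteria are not expressed by
this fixture: it forms no anterior Kni cap (criterion iii's target
domain), and its Hb domain decays multiplicatively so the Hb
half-maximum boundary barely moves (criterion v).  Both criteria are
fully implemented and tested against constructed profiles; the fixture
meets criteria i, ii and iv.

### Perturbation scoring and ensembles

`perturb.score_criteria` codifies five qualitative phenotype criteria as
thresholded measurements on end-state (t = 0) profiles, perturbed versus
dark: (i) anterior shift of the Kr anterior boundary; (ii) anterior
shift of the Kni posterior-domain anterior boundary; (iii) reduction of
anterior Kni expression; (iv) reduction of anterior Gt expression;
(v) anterior shift of the Hb anterior-domain posterior boundary AND
reduction of anterior Hb level (conjunctive).  Defaults: a shift counts
at ≥ 1 %EL anterior; a level reduction at ≥ 10% of the control
anterior-domain peak.  The original scoring of this kind of experiment
was done by eye; these numeric thresholds are this package's
codification, live in the shared config, and are reported alongside
results.  A domain that exists in the control but vanishes in the
perturbed profiles yields a NaN shift and a False criterion; a domain
missing from the control raises.

Parameter ensembles (default n = 21, sign-preserving lognormal jitter,
member 0 = reference) are scored per member; members meeting ≥ 3
criteria form the subset, and each scalar parameter gets

    z_i = (⟨p_i⟩_all − ⟨p_i⟩_subset) / (σ_i / √n)

with σ the sample standard deviation over the full ensemble and n the
full-ensemble size.  Positive z means the subset mean lies below the
ensemble mean.  The denominator is switchable to σ/n (the printed form
of this statistic is typographically ambiguous between the two);
parameters constant across the ensemble are flagged degenerate and get
z = 0.  `perturb.zscore_matrix` lays the interaction z-scores out as a
regulator-by-target-gene table.

## MS2 spot quantification

Detection operates on maximum-projected frames.  A pixel becomes a spot
candidate iff (a) its intensity is at least the absolute threshold,
(b) it lies inside the embryo mask, and (c) it exceeds the mean of its
surrounding background — the one-pixel ring of the (N+2)×(N+2) window
around it, excluding the central N×N block — by the contrast threshold.
Pixels whose window would leave the frame are skipped (count logged).
Adjacent selected pixels merge by 8-connectivity into one candidate with
intensity-weighted centroid and mean intensity; the AP position comes
from a linear pixel-to-%EL calibration.  The implementation is
vectorised (uniform filters + connected components) and is tested for
exact pixel-set equality against an exhaustive per-pixel oracle.

The embryo mask is the filled largest connected Otsu-bright region of
the time-max projection; if that region covers under 5% of the frame the
field of view is assumed to lie inside the embryo (cropped or synthetic
movies) and the whole frame is used.  Fixtures may pass a mask directly.

Linking is greedy one-to-one nearest-neighbour between consecutive
frames: candidate pairs within the maximum displacement are linked in
order of ascending distance (ties broken by the smaller (y, x) centroid,
earlier spot first); unlinked spots start new tracks; there is no gap
closing.  Track duration defaults to n_spots × frame interval — so
exactly 160 s (4 frames at 40 s) is *retained* by the persistence filter,
which excludes only tracks strictly shorter than the cut-off; the
(n−1)×Δt span convention is selectable.  Persistence statistics are
reported per AP region (anterior subdivisions 100–75, 75–70, 70–65,
65–60, 60–40 %EL; a region "high–low" covers (low, high]); spot density
is counts per 100×100 px² of domain area per frame.

## Profile quantification

Nuclei are binned into 5 µm steps along the AP axis ([k·w, (k+1)·w) by
distance from the posterior pole); bin value = mean background-subtracted
intensity; empty bins are missing (NaN), never zero.  An unbinned
per-nucleus profile is available for fits where spatial averaging is
unwanted.  Gradient fits use value(x) = A·exp(−d/ℓ) + c with d the
distance from the anterior pole in µm, least squares with deterministic
initialisation (A = max−min, c = min, ℓ = L/6); the offset term is on by
default and switchable.  Note that fitting a *binned* profile biases ℓ
by a few tenths of a µm (bin means are attributed to bin centres); the
unbinned profile recovers a noiseless exponential exactly.

Boundary calls: the domain peak is the maximum of the profile restricted
to a per-gene search window (defaults generous around the wild-type
domains so shifted boundaries stay in view); the boundary is the
linearly interpolated crossing of peak/2 on the requested flank,
anterior = nearer 100 %EL.  Calls are invariant to positive rescaling of
the profile.

ChIP-qPCR: percent input = 100·2^(adjusted input − Ct(IP)) with adjusted
input = Ct(input) − log2(100/input%), default 2% input aliquot; relative
percent input divides illuminated by dark.

## Synthetic data

The generators emulate the statistical structure the analyses assume,
with every random draw flowing through one integer seed (identical
config + seed ⇒ byte-identical output):

- **Maternal inputs** — Bcd exponential with 80 µm decay length; Cad
  posterior logistic ramp; Tll posterior terminal domain; Hkb anterior
  terminal domain plus posterior pole bump; all in [0, 1].
- **MS2 movies** — nuclei placed with a minimum separation (default
  16 px > 2× the tracking search radius, so recovery is unambiguous);
  per-nucleus on-durations from a truncated normal, default mean 7.1 and
  sd 3.2 min (control-embryo persistence), discretised to 40 s frames;
  spots are 2-D Gaussians with per-nucleus linear drift (0.3 px/frame);
  additive Gaussian noise (optional Poisson) applied after rendering.
  Frames default to 256×128 px mapped onto 100–40 %EL — desk-scale
  stand-ins for 1024×1024 acquisitions.
- **Gradient nuclei** — uniform AP positions, intensity = exponential
  model × (1 + Gaussian noise), truth parameters recorded.

What passing recovery tests does *not* show about real data: synthetic
spots never merge, blink, or move out of focus; nuclei neither divide
nor pack densely; the persistence distribution's true shape is unknown
(recovery tests therefore compare moments, not shapes); and embryo
autofluorescence, bleaching, and segmentation errors are absent.  The
pipeline's parameters (thresholds, displacement bound) still need manual
calibration per real dataset, exactly as the manual-measurement step
implies.

## Limitations

- The 1-D circuit omits 3-D geometry, nuclear divisions, and explicit
  Bcd protein dynamics; the upstream 21 published parameter sets are not
  bundled (the jittered ensemble generator stands in for tests, and
  `CircuitParams.from_json` imports externally obtained sets).
- Criterion scoring on the shipped fixture exhibits criteria i, ii, iv
  only (see above); conclusions about criteria iii and v on real
  parameter sets rest on the unit tests, not the fixture.
- The perturbed-boundary shift magnitudes of the fixture exceed
  biological ones; only directions are meaningful.
- No photobleaching correction, 3-D detection, or nuclear assignment of
  spots; the detection stage assumes maximum projection upstream.
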
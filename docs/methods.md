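# Methods

`asynsalt` models one phenomenon from two directions: the anomalous
retardation of seeded α-synuclein (α-syn) amyloid formation by added salt at
mildly acidic pH. A kinetic layer describes *what* is measured — sigmoidal
ThT fluorescence traces whose underlying rate product k₂k₊ falls with ionic
strength — and an electrostatic layer proposes *why* — a short-range
attraction between the positively charged N-terminal region of a free
monomer and the negatively charged C-terminal tails decorating a catalytic
surface, which salt screens away. This note records the models, the
defaults, and the choices made where the design was genuinely open.

## Sequence titration model

`sequences` implements the null model of protein titration: every
titratable group (D, E, H, Y, K, R, C side chains and free termini) titrates
independently with an intrinsic pKa, giving the mean charge
−1/(1+10^(pKa−pH)) for acids and +1/(1+10^(pH−pKa)) for bases. The default
intrinsic set is D 4.0, E 4.4, H 6.3, Y 9.6, K 10.4, R 12.0, C 10.8,
N-terminus 7.5, C-terminus 3.6 — common coarse-grained-model values; a
measured per-protein table can be loaded instead. The net charge is
strictly decreasing in pH, so the isoelectric point is the unique root of
the curve, found by bisection to |q| < 10⁻⁶ e. For the packaged 140-residue
human α-syn sequence this gives pI ≈ 4.6 and a net charge of about −6.5 e
at pH 5.5; the N-terminal region (1–60) is net positive, the C-terminal
tail (101–140) strongly negative, and the NAC core (61–95, holding only
E61, K80 and E83) close to neutral. Site–site coupling — the pKa shifts an
uneven charge distribution produces — is deliberately absent at this level;
it emerges in the constant-pH Monte Carlo model below.

## Seeded aggregation kinetics

The fibril population is described by its number concentration P and mass
concentration M (monomer equivalents), with free monomer m = m_tot − M:

    dP/dt = k_n m^{n_c} + k_2 m^{n_2} M        (primary + secondary nucleation)
    dM/dt = 2 k_+ m P                          (elongation at both ends)

Preformed sonicated seeds enter exactly through the initial conditions
(M(0), P(0)); with seeds present, primary nucleation is overruled and the
seeded family k_n = 0 is the one fitted to data. Reaction orders default to
n_2 = n_c = 2, the usual fitting convention when orders are not determined
independently.

Two solution routes are kept and cross-checked:

* **`moment_odes`** — stiff integration (LSODA, rtol 10⁻⁸) of the moment
  system; the ground truth. Monomer is eliminated through mass
  conservation, so m + M = m_tot holds identically.
* **`closed_form_mass`** — an analytic route. For the seeded family the
  system has an exact first integral: dividing the two equations gives
  P dP = (k_2/2k_+)(m_tot−M)^{n_2−1} M dM, so P is an elementary function
  of M and the mass curve reduces to a single quadrature t(M), inverted
  monotonically. The growth phase is integrated on a logarithmic grid in
  M−M(0), the plateau approach on a logarithmic grid in m_tot−M, and the
  first instants (M−M(0) quadratic in t) attached analytically; accuracy
  against the ODEs is ~3×10⁻⁶ in mass fraction at the default 600 nodes,
  at ~2 ms per evaluation.

The generalized-logistic integrated rate law used by global-fitting
protocols (with κ, λ, B±, C±, k∞, ǩ∞ as conventionally defined, extended to
seeds through the early-time linearization and the seed contribution
(2k₊P(0))² in k∞²) is retained as **`logistic_mass`**. Its mid-transition
accuracy against exact integration is 0.5–3% — a systematic shape deficit
of the first fixed-point iterate — which is documented rather than hidden:
the fitting layer uses the exact reduction, and a property test holds the
closed form to <10⁻³ of the ODE solution across the seeded parameter
region, which the logistic law cannot meet.

Half-times are the first upward crossing of baseline + amplitude/2, linearly
interpolated; flat traces return a distinct "no half-time" signal and are
reported as censored at the experiment horizon.

## Trace normalization and fitting

Each well is reduced to y = (F − baseline)/amplitude. The baseline is the
median of the pre-growth segment (points before the signal first exceeds 5%
of its robust range), the plateau the median of the final tenth; a
generalized-logistic (Richards) envelope refines both and is accepted only
when it reduces the residual *and* stays within the observed data range —
flat noisy wells otherwise let an unconstrained envelope fit run away.
A well whose amplitude is below 5 noise standard deviations, or below 5% of
the largest amplitude in its series, is non-aggregating: it carries no rate
estimate and its half-time is censored.

Seeded traces identify only the product k₂k₊ (through κ² = 2k₊k₂m(0)^{n₂+1})
and the seeding rate k₊P(0). The fit therefore pins k₊ = 1 in internal
units, derives P(0) from the seed mass via a mean seed length (default 500
monomers, configurable — sonicated seed lengths are not measured), and fits
log₁₀(k₂k₊) per salt level jointly across replicates, with per-well
amplitude and baseline free (plates start at t = 0, so no time offset).
Because the nuisance parameters enter linearly, they are profiled out by a
per-well linear solve, leaving a one-dimensional problem that is
multi-started on five log-spaced initializations and then polished; the 95%
confidence interval comes from the Jacobian at the joint optimum, on the
log scale. An identity check confirms that different k₊/k₂ splits with the
same two identifiable combinations produce identical curves.

## Synthetic plates

No deposited dataset accompanies the experiments, so the plate generator
defines the study conditions: 5 µM monomer, seeds at 0.005 and 0.05 µM
(monomer equivalents), NaCl at {0, 20, 40, 80, 120, 200, 500, 1200} mM,
three replicates, 64 h at 0.25 h resolution. The true rate product decays
log-linearly with salt — base 10¹⁷ M⁻³h⁻², 0.015 log₁₀ units per mM, so
half-times run from about an hour at no added salt to tens of hours at
120 mM — and conditions at or above 200 mM have the secondary-nucleation
rate zeroed, giving flat traces over the whole horizon. Fluorescence is
F = b_w + a_w·M_frac·(1+ε_mult) + ε_add with per-well baseline/amplitude
(100/900 a.u., 5% well-to-well variation), 1% multiplicative and 0.5%
additive Gaussian noise — chosen to resemble plate-reader traces. Every
plate ships its truth table; recovery tests compare against it, never
against hard-coded numbers. What the generator does *not* emulate —
drifting baselines, evaporation, well-to-well cross-talk, non-Gaussian
jumps — bounds what recovery tests show about real plates: they validate
the inference machinery, not robustness to instrumental pathology.

## Constant-pH Monte Carlo of the grafted-tail slit

The electrostatic layer is a bead-per-residue model of intrinsically
disordered chains in the canonical ensemble at T = 300 K. Nonbonded beads
interact through a Debye–Hückel screened Coulomb term plus a weak
Lennard-Jones term,

    u(r)/kT = l_B z_i z_j e^{−r/λ_D}/r + 4ε[(σ/r)¹² − (σ/r)⁶],

with l_B = 7.0 Å, ε = 0.05 kT, uniform σ = 4.0 Å; consecutive beads are
bonded harmonically (r_eq = 4.1 Å, k = 0.76 kT/Å²) and excluded from the
nonbonded sum. λ_D = (8π l_B N_A c_s)^(−1/2) for a 1:1 electrolyte. These
are the published constants of the coarse-grained IDP model family this
implementation follows; all are configurable and logged.

The default system is a cubic slit with hard walls at z = 0 and z = L,
periodic in x,y: 208 C-terminal tails (residues 101–140) anchored by their
N-terminal bead on a grid at exactly one tail per 1,200 Å² (so
L = √(208·1200) ≈ 500 Å), plus one free 140-mer. A desk preset keeps the
density and uses 32 tails (L ≈ 196 Å) — the grafting density, not the tail
count, controls the physics probed. The builder rejects slits shorter than
the tail contour. Grafting consumes the tail's N-terminus (anchor beads are
immobile and non-titratable); each remaining titratable residue carries one
swap site. A titratable residue at a free terminus would need two sites on
one bead, which the model declines rather than approximates — the packaged
sequences never need it.

Moves per sweep: one trial translation per movable bead (step ≤ 3 Å), one
rigid move per chain (translation+rotation for the free chain, rotation
about the anchor for grafted ones), one pivot per chain about a random
bond, and one titration swap per site with intrinsic cost
ln10·(pH − pKa) for protonation plus the electrostatic change. Step sizes
are tuned to 30–50% acceptance during equilibration, then frozen. A single
counter-seeded kernel makes runs bit-reproducible; two independent seeds
per condition estimate observable spread.

Numerical bookkeeping: the running energy is updated per accepted move and
compared against a from-scratch recomputation at the end (tolerance 10⁻⁶ kT
per 10⁴ moves; violations abort the run). One subtlety this check caught:
under the minimum-image convention a rigid rotation does *not* conserve
intra-chain nonbonded energy once a component separation exceeds L/2, so
rigid and pivot deltas include the moved-set internal energy.

Two range choices trade accuracy for speed and are documented rather than
silent: the LJ term is truncated at 3σ = 12 Å (|u| ≈ 3×10⁻⁴ kT there), and
the preset runs truncate electrostatics at min(6λ_D, L/2) — the discarded
tail is bounded by e⁻⁶ ≈ 0.25% of the contact interaction per pair (at
20 mM the cutoff is L/2 ≈ 98 Å, where the screened term is ≤ 8×10⁻⁴ kT).
Summation without any cutoff remains the default of `build_slit_system`.

## Observables

* **g(z)** — the free-chain mass-centre histogram normalized to the mean
  density in a bulk slab at z ∈ [0.7, 0.9]·L, chosen away from both the
  brush and the far wall. At low salt the chain can adsorb so strongly that
  the bulk slab is never visited within a desk-scale run; the profile is
  then normalized to the slit-average density instead and flagged as such.
  For a surface-peaked distribution this underestimates the bulk-normalized
  enhancement, so a peak read from such a profile is a lower bound.
* **Dipole orientation** — μ = Σq_i(r_i − r_cm) about the equal-mass centre;
  the profile is the per-z-bin mean of (μ·n̂)/|μ| with n̂ the unit normal
  pointing from solution toward the grafting surface, so +1 means the
  positive (N-terminal) end points at the surface. The mean of cosines is
  bounded by 1 by construction, which fixes the metric's theoretical
  maximum; samples with |μ| = 0 carry no orientation and are excluded.
  Reported profile maxima are read off the well-determined part of the
  curve — bins holding at least 10% of the samples — because rarely visited
  bins carry per-bin standard errors of ±0.1–0.3 and a maximum taken over
  them is upward-biased.
* **Net charges** — time averages per species with across-run spread.

Bin width defaults to 5 Å.

## Problem sizes and equilibration

Desk-scale production settings used by the acceptance script and the
end-to-end tests: 32 tails + 1 free chain (1,420 beads, ~650 titratable
sites), two independent seeds per condition, 1,600 equilibration and 2,400
production sweeps sampled every other sweep (1,200 samples per run). The
equilibration length was set by watching the free-chain z_cm: from a start
above the brush the chain takes roughly 1,000–1,500 sweeps at 20 mM to
finish burrowing to its equilibrium depth, and block means of z_cm are
stationary thereafter. Shorter runs leave a visible downward drift through
production and bias the orientation profile toward the transient
surface-skating configurations.

## Known limitations

* Implicit ions and unpolarized walls; no Ewald sums — minimum-image
  Debye–Hückel is the model, not an approximation to one.
* The desk preset's slit (196 Å) is closer to the adsorbed layer than the
  full 500 Å geometry, and confinement inflates near-surface statistics;
  directional salt comparisons are robust to this, absolute profile values
  at desk scale carry a scale systematic.
* The kinetic and simulation layers share the sequence and the titration
  model but are not coupled: no attempt is made to predict k₂k₊(salt) from
  the simulated adsorption free energy.
* Fits assume homogeneous, well-mixed wells and Gaussian noise; the
  synthetic generator states exactly which real-data features it omits.
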
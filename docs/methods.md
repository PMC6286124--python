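# Methods

## Model

The package implements a stochastic reaction–diffusion model of the
CaMKII/PP1 system in two synaptic micro-environments, the postsynaptic
density (PSD) and the spine cytosol. The computational unit is the CaMKII
*ring* of n = 6 or 7 subunits, a proxy for the two-ring holoenzyme in which
each "subunit" stands for a vertical dimer that phosphorylates and
dephosphorylates as a unit. Phosphorylated subunits are assumed to form one
contiguous block, so a ring state is fully described by (n, a) with a
unphosphorylated subunits — 15 states over both ring sizes, labelled
`x{a}y{n-a}`. A holoenzyme is *active* when at least two subunits are
phosphorylated.

### Reactions

* **Autophosphorylation** (Ca-driven). With H = [Ca]/K_H1 and Hill
  exponent 3, the propagation rate is v2 = k1·H³/(1+H³) and the initiation
  rate — which needs two simultaneous Ca/CaM bindings — is
  v1 = k1·(H³/(1+H³))² = v2²/k1. v1 applies only to the fully
  unphosphorylated ring; every other ring phosphorylates one subunit at v2.
  At 100 nM Ca, v1 = 1.27×10⁻⁵ s⁻¹ and v2 = 4.36×10⁻³ s⁻¹.
* **Dephosphorylation by PP1**, as explicit mass action: PP1 associates
  with any phospho-bearing ring at k+ (dissociation k− = 0), and the
  complex resolves productively at k2, returning PP1 and the ring with one
  more unphosphorylated subunit. Free phosphorylated subunits are
  dephosphorylated through the same two-step scheme.
* **Subunit exchange**: hexamers bind a free subunit (phosphorylated or
  not) to become heptamers; heptamers release one x (rate kx−) or one y
  (ky−). Hexamers never lose, heptamers never gain. The gain scale
  "1 s⁻¹ per N_CaMKII" is implemented volume-aware: the per-pair propensity
  is k_gain·n_vox/N_CaMKII, so one free subunit in a uniformly populated
  system is taken up at k_gain s⁻¹ in total regardless of voxelization.
* **PP1 regulation by inhibitor-1**: phosphorylated inhibitor-1 (I1P)
  sequesters PP1 (association k3·[I1P], dissociation k4). [I1P] is an
  algebraic function of Ca set by the PKA/calcineurin balance, not a
  counted species. Two monotone readings of the published expression are
  supported (see *Design choices*).
* **Turnover**: every phosphorylated ring reverts to the fresh,
  unphosphorylated ring of the same size at rate vt (default once per
  30 h).

Every reaction conserves total CaMKII subunits and total PP1; the network
constructor verifies this for each generated channel, and the scenario
driver re-checks both totals at every recorded state.

### Stimulus

Ca²⁺ is a global, piecewise-constant drive with no decay kinetics. The
basal profile (ε model) is a 4 s period at 50% duty cycle: 2 s at the
resting level and 2 s at an independent draw from a uniform distribution of
width 40 nM centred 40 nM above rest (Uniform[100, 140] nM for the standard
80 nM baseline). Strong stimuli are 3 s square pulses to a saturating
level (default 10 µM) every 1000 s, returning to the fixed baseline.

### Space

Geometry is a linear chain of equal well-mixed voxels with reflecting ends
(cylindrical arenas; 2D/3D is out of scope). Diffusion of a species with
coefficient D between neighbours h apart is the jump reaction with rate
k = D/h². Only free subunits and free PP1 diffuse by default; rings,
PP1–ring complexes, and PP1·I1P complexes are immobile (free-PP1 episodes
carry PP1 across the whole domain between captures, so complex mobility is
behaviorally redundant while dominating event counts ~100-fold; a config
flag restores it). The jump approximation with bimolecular chemistry is
validated for spacings above h_crit = (k+/N_A)/(D_PP1 + D_sub) ≈ 3.2 nm at
k+ = 1 µM⁻¹s⁻¹ and D = 0.5 µm²/s; the builder warns below h_crit and notes
spacings under the comfortable 10·h_crit.

### Solver

Gillespie's direct method, exact within each constant-Ca window. At every
Ca breakpoint the Ca-dependent propensities are refreshed and the pending
waiting time re-drawn, which is exact because exponential waiting times are
memoryless given refreshed propensities. Channel selection uses a binary
propensity sum-tree (O(log R) sampling and update, with periodic rebuilds
to cancel floating-point drift); the inner loop is numba-compiled and draws
from an inlined splitmix64 stream, so trajectories are bit-reproducible for
a given seed. Counts are sampled on a fixed grid (default 1 s) rather than
per event to bound output over multi-day simulated spans.

### Observables

Activity is the fraction of rings with ≥2 phosphorylated subunits
(PP1-complexed rings count with their current state). Switch ON/OFF
discretization is hysteretic (ON at ≥0.8, OFF at ≤0.2 of holoenzymes
active; the published work does not state its discretization, and the
symmetric 20/80 bands make the intermediate band explicit while suppressing
chatter). Residence times are flip-to-flip dwells; relaxation is the
intermediate-band crossing time. The PP1-tolerance curve fits ON-time
fraction against x = N_PP1/N_CaMKII with a/(1+e^{k(x−x0)}). Occupancy
histograms over the number of active holoenzymes are compared with
Kullback–Leibler divergence in bits, Laplace-smoothed with α = 1 count per
bin. Decay fitting starts at the ensemble-mean trace's peak, truncates
where the trace first reaches 2% of the peak (so the fully decayed tail
does not dominate the residuals), and uses single or fixed-weight double
exponentials. Pulse-aligned decays are averaged across all pulses of all
runs before fitting, as the published curves are.

### Exchange-rate assay

The two-color colocalization assay is modelled as rings R_aG_b with free R
and G subunits: heptamers shed a subunit at rl (color drawn in proportion
to composition), hexamers take up any free subunit at the second-order rate
rg. Initial populations are pure-color, with equal hexamer and heptamer
numbers per color. Colocalization — the percentage of rings carrying both
colors — is fit with 100·(1 − e^{−t/τ}) against the experimental
τ = 62.7 min at [CaMKII] = 8 µM (taken as a given constant). Because the
readout is a bulk fraction of µM-scale populations, the default backend
integrates the mass-action ODEs; the Gillespie backend runs the same
network for cross-checking. Admissible (rg, rl) pairs are ranked by the
agreement of dτ/d[CaMKII] over {1, 4, 8} µM with the experimental slope.
Diffusion, labelling efficiency and readout noise are not modelled.

## Parameters

Defaults (units: s⁻¹, µM, µm, µm²/s): k1 = 1.5, K_H1 = 0.7 (n = 3),
k2 = 1, K_M = 10, k+ = 1, k− = 0, k3 = 100, k4 = 0.1, I1 = 10,
vPKA/vCaN = 1, K_H2 = 0.3 (n = 3), gain 1 s⁻¹ per N_CaMKII, loss 0.1,
vt = 1/30 h⁻¹, D_PP1 = 0.5, D_sub scenario-dependent (10⁻⁵–10), voxel
spacing 30 nm. Bimolecular rates convert to per-pair propensities with
c = k/(N_A·V_voxel), N_A·1 µM·1 µm³ = 602.2.

## Design choices

* **I1P–Ca relation.** The published expression for [I1P] is typeset
  ambiguously; read one way it *decreases* with Ca (diverging at rest,
  ≈537 µM at 80 nM), read the other it *increases* toward I1·vPKA/vCaN.
  Under the decreasing reading the free-PP1 fraction k4/(k4+k3·I1P) never
  exceeds 10⁻⁴ at any Ca, which makes PP1 inert on every reported
  timescale (the spine decay would take hours instead of ~40 s, and no PP1
  level within the reported bistable bands could close the switch). The
  increasing reading — free PP1 partially available at rest, sequestered
  during strong Ca input — reproduces the reported dynamics to order of
  magnitude and is the default (`i1p_mode="increasing"`); the decreasing
  reading remains available as a config option.
* **Spine preset populations.** The spine experiment states only
  V = 0.02 µm³, Nv = 10, D_sub = 1, D_PP1 = 0.5, and a tenfold PP1 increase
  over the PSD setting. The preset uses N_CaMKII = 10 (one holoenzyme per
  voxel, as in the PSD spreading arena) and N_PP1 = 30×N_CaMKII — tenfold
  the 3×N_CaMKII lower edge of the no-exchange bistable PSD band, inside
  the parameter table's stated spine range of 10–100×.
* **Pulse amplitude** 10 µM (saturating both Hill functions; an
  uncaging-scale transient). At k1 = 1.5 s⁻¹ a 3 s pulse phosphorylates
  ~4–5 subunits per ring, so decays start from near-full activity.
* **Exchange while complexed.** Rings bound to PP1 neither gain nor lose
  subunits, and turnover does not act on complexed rings; the exchange and
  turnover reactions are written for free rings only.
* **Free subunits are never phosphorylated by Ca/CaM**; they are only
  dephosphorylated by PP1. No phosphorylation reaction exists for free
  subunits in the scheme.
* **Phosphorylation directionality** ("proceeds clockwise") has no
  observable consequence in the counts-only state representation and is
  not modelled.

## What the simulations show — and what they do not

The generator-driven scenarios reproduce the *structure* of the published
experiments (arena geometries, populations, stimuli). Three caveats bound
what agreement means:

* The published no-exchange spine decay constant (≈41.65 s) emerges from
  the preset within ~25–30%; its exact value depends on the unpublished
  spine PP1 count through the product k+·N_PP1.
* The published *exchange-dependent* effects — the ~5× slower spine decay
  and the rightward shift of the PP1-tolerance midpoint — do **not** emerge
  from the equations as printed, under any of the structural readings
  explored (per-ring vs per-site PP1 association, either k+ value, loss
  rates 0.1–1 s⁻¹, fixed or fluctuating inter-pulse baseline). The reason
  is structural: subunit exchange conserves phosphorylation and PP1 attack
  is concentration-based, so redistributing phospho-subunits cannot reduce
  the total dephosphorylation flux, and re-seeding through free subunits is
  rate-limited by v2 at basal Ca, which is an order of magnitude below the
  attack rate that the no-exchange decay constant itself implies. The
  package reports what the faithful equations produce.
* Scaled-down durations (minutes of simulated time instead of days) are
  used throughout the test suite and the acceptance script; residence-time
  magnitudes at full fidelity (hours to weeks) are therefore exercised only
  qualitatively.

The synthetic stimulus emulates square basal fluctuations and square
pulses only; real spine Ca transients have finite rise/decay kinetics and
NMDA-receptor stochasticity that the model deliberately omits, so passing
tests say nothing about those features.

## Numerical notes

Tolerances: SSA exactness is verified against a brute-force chemical master
equation solution on a closed A+B⇌C system (total variation < 0.02);
exponential waiting times against a KS test at α = 0.01; decay-fit
recovery to 5%; telegraph residence recovery to 10%. Degenerate inputs
(flat traces, capped colocalization, all-ON tolerance curves) are flagged
rather than fit. Curve fits use scipy's Levenberg–Marquardt/TRF with
bounded parameters; the sigmoid midpoint guess comes from linear
interpolation of the half-maximum crossing. Ensemble seeds are
`base_seed + i`; each run also derives an independent stimulus realization
seed, so ensembles are order-independent.
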
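# Methods

`tunnelfold` models how the geometry of the ribosome exit tunnel sets where
a nascent protein domain can fold, and how that folding is read out by an
arrest-peptide force assay. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic benchmarks do
and do not establish.

## The force-profile assay and its kinetic model

A domain is tethered L residues upstream of the critical proline of a
17-residue SecM arrest peptide (AP); the AP stalls translation, and force
on the nascent chain accelerates escape from the stalled state. The escape
rate follows the Bell model,

    ke(F) = k0 · exp(F · Δx‡ / kB·T),

with defaults k0 = 3.4e-4 s⁻¹ and Δx‡ = 4.5 Å (single-molecule estimates
for SecM; admissible ranges roughly 0.5–20 ×10⁻⁴ s⁻¹ and 1–8 Å). Assuming
folding equilibrates much faster than escape, the fraction of full-length
product after an exposure time t is

    f_FL(t) = 1 − exp(−t·[Pu·ke(Fu) + Pf·ke(Ff)]),

where Pu, Pf are the unfolded/folded populations at linker length L and
Fu, Ff the mean pulling forces in each state. `force_kinetics` implements
both formulas; `simulated_profile` applies them per L. Populations that do
not sum to 1 (discarded intermediate frames) are renormalized, since the
formula assumes two states. Temperature defaults to 310.15 K. The exposure
time t is a first-class parameter: the measured translation window is
20 min, but because the tethered chain carries an entropic background
tension of order kBT per bond length (~10–20 pN in the simulations), the
analysis drivers use t = 60 s so that the zero-extra-force baseline of the
predicted profiles stays small. The position of the profile peak is
unaffected by t (the Bell transform is monotone in force); only the
baseline and amplitude move.

## Coarse-grained model

Proteins are one bead per residue at the Cα position; RNA three beads per
nucleotide (P, C4′, N3). The nascent-chain domain carries a standard
structure-based (Gō-type) potential:

- harmonic bonds  V = k_b (r − r0)², k_b = 100 ε/Ų;
- harmonic angles V = k_a (θ − θ0)², k_a = 20 ε/rad²;
- dihedrals V = k1[1 − cos(φ − φ0)] + k3[1 − cos 3(φ − φ0)], k1 = 1 ε,
  k3 = 0.5 ε;
- native contacts: 12–10 well V = ε[5(σ/r)¹² − 6(σ/r)¹⁰], minimum −ε at
  the native Cα distance σ;
- excluded volume on non-native pairs (|i−j| ≥ 4): an r⁻¹² core truncated
  and force-shifted so energy and force vanish continuously at the
  excluded diameter (4 Å default).

The force-shifted truncation (rather than a bare r⁻¹² tail) makes native
conformations whose non-contact pairs all sit beyond the excluded diameter
exact stationary points: at the native state the energy is exactly
−ε·N_contacts and the gradient is zero, which the tests assert to machine
precision. Native contacts come from a heavy-atom cutoff (4.5 Å all-atom;
larger for Cα-only toy fixtures) with minimum sequence separation 4.
ε = 1 sets the reduced energy unit; temperature is in ε/kB.

The fraction of native contacts Q (a contact counts as formed within
1.2·σ) classifies frames: folded Q ≥ 0.7, unfolded Q ≤ 0.3, intermediate
frames discarded from force statistics but tracked as a diagnostic
fraction.

## Ribosome–nascent-chain simulations

The scaffold (real 50S bead model or toy tunnel) is static and purely
repulsive (the same force-shifted r⁻¹² with per-kind radii, protein 2.0 Å,
RNA/wall 2.5 Å), looked up through a precomputed cell grid. The chain =
domain + L linker residues; linker and AP beads carry bonds (3.8 Å), a
weak generic angle term (k = 1 ε/rad², θ0 = 2.0 rad) and excluded volume
only — they are a passive tether. The C-terminal bead is position-restrained
at the peptidyl-transfer-center anchor (k = 200 ε/Ų), and the pulling
force is measured on a harmonic pseudobond between the last and second-last
beads (k = 100 ε/Ų, r0 = 3.8 Å).

The recorded force observable is the pseudobond elongation projected on
the tunnel axis, F = k·⟨(r − r0)·cos θ⟩. A bare mean of (r − r0) carries a
radial-Jacobian offset of ~2kBT/r0 even at zero load; the projection
removes it while reproducing Hooke's law exactly for a bead held at a
fixed axial offset.

Dynamics are BAOAB Langevin steps in reduced units (bead mass 1, friction
1 τ⁻¹, dt = 0.005 τ for calibration runs, 0.01 τ for tunnel scans — stable
and passing the equipartition check at both values). A per-half-step
displacement above 2 Å aborts the run with a diagnostic. Conversion of
reduced forces to pN identifies the reduced thermal energy with kB·310.15 K
by default, so ε ≈ 0.6–0.7 kcal/mol at the simulation temperatures used
and entropic chain forces come out at the physical ~10–20 pN scale.

Simulation temperatures are ~0.9× each toy domain's folding midpoint,
determined once by a temperature scan of the isolated domain
(`calibrate_folding_temperature`): midpoint ≈ 1.2 ε/kB for the hairpin
(run at 0.85) and ≈ 1.13 for the three-helix bundle (run at 1.02).

### Mixed-start sampling

Folding/unfolding interconversion of a tethered, confined domain is slow
on desk-scale runs, and single unfolded-start trajectories produce noisy,
occasionally non-monotone Pf(L). Each linker length therefore pools frames
from three replicas: one threaded unfolded along the tunnel axis (coiled
loosely wherever the local free radius allows) and two started from a
constructed folded placement — the native domain at the deepest axial
position whose free-radius profile admits it, with the linker eased onto
the axis. Where no folded placement is geometrically and elastically
constructible (not enough space anywhere within linker reach), those
replicas fall back to unfolded starts, so below the geometric onset the
folded state is simply never seeded and Pf ≈ 0, while above it the
placement must also *survive* the dynamics (a taut linker or marginal fit
unfolds). Constructed starts are relaxed by a short capped-step steepest
descent before dynamics to remove construction clashes.

This protocol measures where a folded state is geometrically possible and
mechanically stable rather than a fully converged equilibrium constant:
with slow interconversion the pooled populations are start-biased near the
onset. The onset (smallest L with Pf > 0.5) is robust to this bias —
below the geometric onset no folded state can be seeded at all — and it is
the quantity the directional conclusions rest on. Near-threshold crossings
still wobble by one grid step between runs, so onset comparisons are read
at one-grid-step resolution: an obstruction "moves" an onset when the
shift exceeds one grid step and "leaves it unchanged" when the shift stays
within one.

## The toy tunnel

The synthetic scaffold is a surface of revolution ~110 Å long: a narrow
6 Å-radius section from the closed (PTC) end to ~66 Å, a wide 10.5 Å
section, and a funnel vestibule flaring to 22 Å at the exit, closed by an
annular plate (the ribosome surface). Two removable obstructions mimic the
tunnel-protein loops: a mid-tunnel protrusion (rings at 6 Å radius
extending the narrow section by ~12 Å; uL23-loop analogue, chain id `MID`)
and an exit-port obstruction (rings filling the funnel down to a 7 Å
opening; uL24-loop analogue, chain id `EXIT`). Deleting a chain's beads
yields the Δloop variant; the free-radius profile used for threading and
folded placement is re-measured from the remaining beads, so variants
never need hand-tuned profiles.

The two toy domains discriminate the two obstructions by size: the
12-residue hairpin (cross radius ~3 Å) folds in the wide section but not
the narrow one, so its onset is set by where the wide section becomes
reachable — the mid protrusion; the 28-residue three-helix bundle
(radius ~8 Å) fits only the funnel or the outside, so its onset is set by
the exit obstruction. Purely geometric placement predicts onsets
(hairpin 21/17/21, bundle 30/30/24 for wild-type/Δmid/Δexit at the default
geometry); the dynamics reproduce the same pattern with onsets shifted by
0–2 residues.

## Tunnel-volume calculation

The search space is a union of inclusion spheres; the published recipe
centres ten 20 Å spheres on alternating Cα atoms of the stalled SecM
peptide (D11…G28) plus one 40 Å sphere (E3) — the text says "eight" but
lists ten centres, so both presets ship. A cubic grid (2.0 Å spacing) is
anchored at integer multiples of the spacing in the structure frame; a
point counts iff it is inside ≥1 sphere and farther than 1.09 Å from every
occupant atom (atom centres, no van der Waals radii, as the recipe gives a
single cutoff). Volume = count × spacing³. Because the lattice phase is
anchored to the coordinate frame, comparisons are only meaningful on the
same region and spacing, which `volume_difference` enforces. A
26-connected largest-component filter is available (off by default; the
published use of pruning was cosmetic). Loop-deletion presets carry both
the strain ranges (uL23 65–74, uL24 43–57) and the volume-calculation
ranges (65–75, 42–57); which numbering is authoritative is not resolvable,
so the range is always an explicit parameter.

## Profile features

f_FL = I_FL/(I_A + I_FL) per gel lane. Features of a single-peaked
profile: L_max is the (first) interior maximum; the half-maximum level is
baseline + (peak − baseline)/2 with the baseline taken as the profile
minimum at L ≤ L_max (Δf_FL profiles are near zero before onset, and an
elevated tail after the peak should not distort the level); L_onset and
L_end are the rising/falling crossings of that level, linearly
interpolated between samples and rounded to integer L with ties rounded
down (published feature tables are integers). Replicates aggregate as mean
± sd/√n. Onset differences convert to folding depths at 3 Å per extended
linker residue.

## Synthetic data

All pipeline inputs can be generated with known ground truth: tunnel
variants (above); toy domains (procedural ideal geometries — generated
natives are verified to be exact local minima, and contact definitions are
per-class: hairpin 6.5 Å/sep ≥ 4; bundle 8.5 Å/sep ≥ 6 so that Q counts
tertiary assembly rather than helicity, keeping the fold two-state);
single-peaked profiles built piecewise-linearly so the noiseless curve
passes half-maximum exactly at the true onset/end (additive Gaussian
noise, clipped); and gel lanes I_FL = f·total, I_A = (1−f)·total with
optional additive band noise. All generators are pure functions of
(spec, seed).

What the synthetic benchmarks show: that the machinery — potential,
integrator, force readout, kinetic transform, feature extraction — behaves
quantitatively as specified, and that the geometric mechanism (folding
onset tracks available space) emerges from the dynamics with the correct
directionality. What they do not show: quantitative agreement with real
ribosomes, which would require the full 50S bead model (supported through
`structure_io.truncate_scaffold`) and far longer sampling; rRNA chemistry,
electrostatics and sequence-specific tunnel interactions are out of scope
by design.

## Problem sizes and determinism

Desk-scale defaults: tunnel scans use 3 replicas × 150–200k production
steps per linker length (≈10 min for the full two-domain, three-variant
comparison); the stochastic-oracle and recovery studies use 10⁵ trials and
500 replicates. All randomness flows from explicit seeds (per-(L, replica)
seeds derive from a master seed via `SeedSequence`), reruns are
bit-identical, and the simulation kernels avoid fast-math reassociation so
results do not depend on the host's SIMD width.

## Known limitations

- Mixed-start populations near the folding onset are sampling-protocol
  dependent (see above); only onset positions, not Pf values, should be
  compared across conditions.
- Force statistics treat recorded frames as independent; standard errors
  are optimistic unless the recording stride exceeds the correlation time.
- The toy tunnel's volume changes on loop deletion are much smaller than
  its total volume because sparse wall beads with a 1.09 Å cutoff block
  little of the grid; the sign and ordering of the differences are the
  meaningful output.
- The arrest peptide is a passive tether; sequence-dependent AP mechanics
  beyond (k0, Δx‡) are not modelled.
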
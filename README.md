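# tunnelfold

Where in the ribosome exit tunnel does a nascent protein start to fold,
and how does the tunnel's shape decide that? `tunnelfold` is a Python
toolkit for studying this question computationally, built around the
arrest-peptide force-profile assay: a domain is tethered L residues
upstream of a SecM arrest peptide, folding pulls on the nascent chain,
and the fraction of read-through (full-length) product f_FL, plotted
against L, reveals the linker length — hence the depth in the tunnel — at
which folding begins. The package targets researchers analysing such
profiles and running coarse-grained simulations of ribosome–nascent-chain
(RNC) complexes, in particular for comparing wild-type ribosomes with
variants whose tunnel-protruding loops (uL23, uL24) are deleted.

It provides, as composable modules:

- **structure_io** — PDB/mmCIF reading (via biotite), coarse-graining to
  Cα / three-bead-RNA models, loop deletions, scaffold truncation;
- **go_model** — a structure-based (Gō) potential: harmonic bonds/angles,
  1×/3× dihedrals, 12–10 native contacts (energy −ε per contact at the
  native state), force-shifted r⁻¹² excluded volume, and the fraction of
  native contacts Q;
- **rnc_sim** — BAOAB Langevin dynamics of a tethered chain inside a
  static repulsive tunnel scaffold (numba kernels), measuring per-L
  folded/unfolded populations and mean tether forces (Pu, Pf, Fu, Ff);
- **force_kinetics** — the Bell escape model,
  ke(F) = k0·exp(F·Δx‡/kB·T), and the two-state kinetic formula
  f_FL(t) = 1 − exp(−t·[Pu·ke(Fu) + Pf·ke(Ff)]);
- **tunnel_volume** — POVME-style grid cavity volumes over
  inclusion-sphere regions (2.0 Å grid, 1.09 Å cutoff, SecM-anchored
  presets) and volume differences between ribosome variants;
- **profile_analysis** — f_FL = I_FL/(I_A+I_FL) from gel intensities,
  Δf_FL profiles, half-maximal features (L_onset, L_max, L_end), and the
  conversion of onset shifts to folding depths at ~3 Å per residue;
- **synthetic_data** — toy tunnels with removable uL23/uL24-like
  obstructions, procedurally generated two-state toy domains, and
  synthetic profiles/gels with known ground truth;
- **pipeline / cli** — YAML-configured end-to-end runs and a `tunnelfold`
  command-line tool (`synth`, `scan`, `ffl-predict`, `ffl-features`,
  `tunnel-volume`, `run`).

The `analysis/` directory holds the numbered study drivers: build the toy
systems (01), scan linker lengths per tunnel variant (02), predict f_FL
profiles (03), extract features and depth shifts (04), and compute tunnel
volumes (05), each writing its tables under `results/`.

## Worked example

```python
from tunnelfold import BellParams, escape_rate, f_fl
from tunnelfold.synthetic_data import SyntheticProfileSpec, make_synthetic_profile
from tunnelfold.profile_analysis import (aggregate_replicates,
                                         extract_features, depth_shift)

# Bell model at the default SecM parameters (k0 = 3.4e-4 1/s, dx = 4.5 A)
print(escape_rate(0.0))                                  # 0.00034
print(f_fl(0.2, 0.8, 5.0, 20.0, BellParams(t=60.0)))     # 0.131...

# three replicate profiles shaped like a zinc-finger delta-f_FL
# measurement (true onset 17, peak 22, end 26), with measurement noise
spec = SyntheticProfileSpec(L_grid=tuple(range(13, 33)), onset=17, peak=22,
                            end=26, amplitude=0.6, baseline=0.02,
                            sigma=0.02, n_replicates=3)
mean = aggregate_replicates(make_synthetic_profile(spec, seed=0))
feats = extract_features(mean)
print(feats.to_dict())
# {'L_onset': 17, 'L_max': 22, 'L_end': 26, 'peak_height': 0.622...}

# a domain whose onset moves from L = 21 to L = 17 folds deeper by
print(depth_shift(21, feats.L_onset))                    # 12.0 (angstrom)
```

The last number is the headline arithmetic of this kind of study: an
onset shift of 4 residues, at ~3 Å per extended linker residue, means the
domain folds ~12 Å deeper in the mutant tunnel.

The toy end-to-end experiment (drivers 01–03) reproduces the directional
logic with simulations: deleting the mid-tunnel protrusion moves the
small hairpin's folding onset from L = 25 to L = 19 while deleting the
exit-port obstruction leaves it unchanged; the wide three-helix bundle
shows the converse (onset 32 → 24 on exit-loop deletion, unchanged within
one grid step on mid-loop deletion). See `docs/methods.md` for the
models, calibrations and sampling protocol behind these numbers, and
`results/scans/` for the tables they come from.

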
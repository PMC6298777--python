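#!/usr/bin/env python
"""Build the toy study systems: exit-tunnel scaffold variants and the two
structure-based toy domains.

Writes, under results/toy_systems/: the wild-type, mid-loop-deleted and
exit-loop-deleted tunnel bead models (TSV), the hairpin and three-helix
topologies (JSON), and a geometry report stating, per domain and tunnel
variant, the smallest linker length at which a folded placement is
geometrically and elastically constructible — the purely geometric onset
prediction that the dynamics in 02 refine.
"""

import json
from pathlib import Path

import numpy as np

from tunnelfold.rnc_sim import _place_folded  # geometric placement probe
from tunnelfold.structure_io import write_bead_model_tsv
from tunnelfold.synthetic_data import (ToyDomainSpec, make_toy_domain,
                                       make_toy_tunnel, remove_tunnel_loop)

OUT = Path("results/toy_systems")
OUT.mkdir(parents=True, exist_ok=True)

wt = make_toy_tunnel(seed=0)
variants = {
    "wt": wt,
    "mid_deleted": remove_tunnel_loop(wt, "mid"),
    "exit_deleted": remove_tunnel_loop(wt, "exit"),
}
for name, scaffold in variants.items():
    write_bead_model_tsv(scaffold.beads, OUT / f"tunnel_{name}.tsv")
    print(f"{name}: {scaffold.beads.n_beads} scaffold beads")

domains = {}
for fold_class, n in (("hairpin", 12), ("three-helix", 28)):
    structure, topology = make_toy_domain(ToyDomainSpec(fold_class, n), seed=1)
    topology.to_json(OUT / f"domain_{fold_class}.json")
    domains[fold_class] = topology
    print(f"{fold_class}: {n} residues, {topology.n_contacts} native contacts")

report = {}
for fold_class, topology in domains.items():
    for name, scaffold in variants.items():
        axis0 = scaffold.axis + (scaffold.anchor - scaffold.axis[0])
        first = next(
            (L for L in range(17, 45)
             if _place_folded(axis0, scaffold.init_radius, topology, L)
             is not None), None)
        report[f"{fold_class}/{name}"] = first
        print(f"geometric onset {fold_class:12s} {name:12s} L = {first}")

(OUT / "geometric_onsets.json").write_text(json.dumps(report, indent=1))
print(f"wrote {OUT}/geometric_onsets.json")
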
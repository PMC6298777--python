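"""End-to-end orchestration: simulate -> kinetics -> features, and
structure -> tunnel volumes, from a single YAML-able configuration.

A run configuration is a nested mapping with one block per stage (domain,
tunnel, scan, simulation, bell, volume) plus a master seed and an output
directory. Each stage writes its artifact into the output directory, every
file embeds the configuration hash, and a provenance manifest records seeds
and parameters, so a rerun with the same configuration is bit-identical for
the seeded stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tunnelfold import __version__ as _version
from tunnelfold.force_kinetics import BellParams, simulated_profile
from tunnelfold.profile_analysis import (NoPeakError, extract_features,
                                         write_profile_tsv)
from tunnelfold.rnc_sim import (SimulationParams, force_statistics_table,
                                scan_linker_lengths)
from tunnelfold.structure_io import (LoopDeletion, apply_loop_deletion,
                                     read_bead_model_tsv, read_structure)
from tunnelfold.synthetic_data import (ToyDomainSpec, ToyTunnelSpec,
                                       make_toy_domain, make_toy_tunnel,
                                       remove_tunnel_loop,
                                       suggested_temperature)
from tunnelfold.tunnel_volume import (InclusionRegion, compute_volume,
                                      inclusion_region_from_residues,
                                      volume_difference)

__all__ = ["RunConfig", "run_force_profile_pipeline", "run_volume_report"]


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected early."""

    seed: int = 0
    output_dir: str = "results"
    domain: dict = field(default_factory=dict)
    tunnel: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    bell: dict = field(default_factory=dict)
    volume: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Hash of the scientific parameters (the output location does not
        change what is computed)."""
        payload = {k: v for k, v in self.to_dict().items()
                   if k != "output_dir"}
        text = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _tunnel_from_config(cfg: RunConfig):
    block = dict(cfg.tunnel)
    variant = block.pop("variant", "wt")
    spec = ToyTunnelSpec(**block) if block else ToyTunnelSpec()
    scaffold = make_toy_tunnel(spec, seed=cfg.seed)
    if variant == "wt":
        return scaffold
    if variant in ("mid_deleted", "exit_deleted"):
        return remove_tunnel_loop(scaffold, variant.split("_")[0])
    raise ValueError(f"unknown tunnel variant {variant!r}")


def _domain_from_config(cfg: RunConfig):
    spec = ToyDomainSpec(**cfg.domain) if cfg.domain else ToyDomainSpec()
    _, topology = make_toy_domain(spec, seed=cfg.seed)
    return spec, topology


def _write_json(payload: dict, path: Path, cfg_hash: str) -> None:
    payload = {"config_hash": cfg_hash, **payload}
    path.write_text(json.dumps(payload, indent=1))


def run_force_profile_pipeline(cfg: RunConfig) -> dict:
    """Simulate a linker-length scan, predict the f_FL profile, extract its
    features; returns a summary dict and writes four artifacts.

    Artifacts: ``force_table.tsv`` (per-L Pu/Pf/Fu/Ff), ``profile.tsv``
    (L, f_FL), ``features.json`` and ``provenance.json``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.hash()

    dom_spec, topology = _domain_from_config(cfg)
    scaffold = _tunnel_from_config(cfg)

    sim_block = dict(cfg.simulation)
    if "temperature" not in sim_block:
        sim_block["temperature"] = suggested_temperature(dom_spec)
    params = SimulationParams(seed=cfg.seed, **sim_block)

    scan_block = dict(cfg.scan)
    L_values = scan_block.get("L_values", list(range(17, 34, 2)))
    ap_length = scan_block.get("ap_length", 17)
    stats = scan_linker_lengths(scaffold, topology, L_values, params,
                                ap_length=ap_length)
    if not stats:
        raise RuntimeError("stage 'scan' produced no force statistics")

    table = force_statistics_table(stats)
    table_path = out / "force_table.tsv"
    with open(table_path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    bell = BellParams(**cfg.bell) if cfg.bell else BellParams()
    profile = simulated_profile(stats, bell)
    write_profile_tsv(profile, out / "profile.tsv")

    features = None
    try:
        features = extract_features(profile)
        _write_json(features.to_dict(), out / "features.json", cfg_hash)
    except NoPeakError as exc:
        warnings.warn(f"stage 'features': {exc}")
        _write_json({"error": str(exc)}, out / "features.json", cfg_hash)

    provenance = {
        "version": _version,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "bell": dataclasses.asdict(bell),
        "simulation": {k: v for k, v in dataclasses.asdict(params).items()},
        "outputs": ["force_table.tsv", "profile.tsv", "features.json"],
    }
    _write_json(provenance, out / "provenance.json", cfg_hash)
    return {"stats": stats, "profile": profile, "features": features,
            "config_hash": cfg_hash}


def _load_occupant(source: str | Path):
    path = Path(source)
    if path.suffix == ".tsv":
        return read_bead_model_tsv(path)
    return read_structure(path)


def run_volume_report(cfg: RunConfig) -> dict:
    """Tunnel volumes for a set of structure variants plus pairwise
    differences; writes ``volumes.json``.

    The ``volume`` block lists variants as mappings with ``id``,
    ``structure`` (PDB/mmCIF path, or bead-model TSV), optional
    ``deletions`` ([chain, first, last] triplets) and ``exclude_chains``;
    the inclusion region comes from ``anchors`` ([chain, residue, radius]
    rows resolved on the first variant) or explicit ``spheres``
    ([x, y, z, radius] rows).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.hash()
    block = cfg.volume
    if not block.get("variants"):
        raise ValueError("volume config needs a non-empty 'variants' list")
    spacing = float(block.get("spacing", 2.0))
    cutoff = float(block.get("cutoff", 1.09))

    occupants = {}
    for var in block["variants"]:
        occ = _load_occupant(var["structure"])
        deletions = [LoopDeletion(c, int(a), int(b))
                     for c, a, b in var.get("deletions", [])]
        if deletions:
            occ = apply_loop_deletion(occ, deletions)
        occupants[var["id"]] = (occ, var.get("exclude_chains", []))

    if "spheres" in block:
        arr = np.asarray(block["spheres"], dtype=float)
        region = InclusionRegion(arr[:, :3], arr[:, 3])
    else:
        first = occupants[block["variants"][0]["id"]][0]
        region = inclusion_region_from_residues(
            first, [(c, int(r), float(rad)) for c, r, rad in block["anchors"]])

    results = {}
    for vid, (occ, excl) in occupants.items():
        results[vid] = compute_volume(occ, region, spacing=spacing,
                                      cutoff=cutoff, exclusions=excl,
                                      occupant_id=vid)
    ids = list(results)
    diffs = [{"a": a, "b": b,
              "difference_A3": volume_difference(results[a], results[b])}
             for i, a in enumerate(ids) for b in ids[i + 1:]]
    payload = {
        "spacing": spacing, "cutoff": cutoff,
        "volumes_A3": {vid: r.volume for vid, r in results.items()},
        "points": {vid: r.n_points for vid, r in results.items()},
        "differences": diffs,
    }
    _write_json(payload, out / "volumes.json", cfg_hash)
    return {"results": results, "differences": diffs, "config_hash": cfg_hash}
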
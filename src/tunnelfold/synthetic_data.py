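"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here at desk scale: a toy
exit tunnel (a ~100 A surface-of-revolution scaffold with removable
obstructions emulating the uL23 mid-tunnel loop and the uL24 exit-port
loop), small two-state-folding bead-chain domains, single-peaked f_FL
profiles with replicate noise, and gel band-intensity pairs consistent with
a given f_FL.

Toy geometry (defaults). The tunnel is narrow (6 A radius) for its first
~55 A, widens to 10.5 A, and flares into a funnel vestibule near the exit.
The mid-tunnel protrusion extends the narrow section by ~12 A; the exit
obstruction fills the funnel down to an 8 A opening. A small elongated
hairpin domain (cross radius ~3 A) can fold in the wide section but not the
narrow one, so its folding onset is set by the mid protrusion; a ~16 A-wide
three-helix bundle can fold only in the funnel or outside, so its onset is
set by the exit obstruction. This reproduces, in miniature, the geometric
logic of the loop-deletion experiments.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from tunnelfold.go_model import GoParams, NativeTopology, build_topology, \
    potential_gradient
from tunnelfold.profile_analysis import FflProfile, LaneQuantification
from tunnelfold.rnc_sim import RibosomeScaffold
from tunnelfold.structure_io import BeadModel, MolecularStructure

__all__ = [
    "ToyTunnelSpec",
    "ToyDomainSpec",
    "SyntheticProfileSpec",
    "make_toy_tunnel",
    "make_toy_domain",
    "make_synthetic_profile",
    "make_synthetic_gel",
    "remove_tunnel_loop",
    "suggested_temperature",
]


# ------------------------------------------------------------------- tunnel

@dataclass(frozen=True)
class ToyTunnelSpec:
    """Geometry of the toy exit tunnel (angstrom).

    ``radius_profile`` is a piecewise-linear free radius along the axis.
    ``constriction`` places the removable mid-tunnel protrusion (uL23-loop
    analogue); ``exit_opening`` is the radius left open by the removable
    exit-port obstruction (uL24-loop analogue).
    """

    length: float = 110.0
    radius_profile: tuple = ((0.0, 6.0), (66.0, 6.0), (73.0, 10.5),
                             (92.0, 10.5), (110.0, 22.0))
    wall_spacing: float = 4.0
    constriction: tuple | None = (73.0, 6.0)   # (axial position, radius)
    constriction_extent: float = 12.0
    vestibule_radius: float = 22.0
    exit_opening: float = 7.0
    obstruction_start: float = 102.0
    plate_radius: float = 30.0

    def radius_at(self, z: float) -> float:
        zs = np.array([p[0] for p in self.radius_profile])
        rs = np.array([p[1] for p in self.radius_profile])
        return float(np.interp(z, zs, rs))


def _ring(z: float, radius: float, spacing: float, phase: float = 0.0):
    if radius < 1e-6:
        return np.array([[0.0, 0.0, z]])
    n = max(int(np.ceil(2 * np.pi * radius / spacing)), 6)
    ang = 2 * np.pi * np.arange(n) / n + phase
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.full(n, z)], axis=1)


def make_toy_tunnel(spec: ToyTunnelSpec = ToyTunnelSpec(),
                    seed: int = 0) -> RibosomeScaffold:
    """Build the toy tunnel scaffold.

    Wall beads tile the surface of revolution of the radius profile; a cap
    closes the PTC end and an annular plate forms the ribosome surface
    around the exit. The two removable obstructions carry chain ids
    ``MID`` and ``EXIT`` so the delta-loop variants are obtained by deleting
    those bead sets (see :func:`remove_tunnel_loop`). The bead pattern is
    deterministic; ``seed`` only randomizes ring phases.
    """
    rng = np.random.default_rng(seed)
    s = spec.wall_spacing
    chunks: list[tuple[str, np.ndarray]] = []

    zs = np.arange(0.0, spec.length + 0.5 * s, s)
    wall = [_ring(z, spec.radius_at(z), s, rng.uniform(0, 2 * np.pi))
            for z in zs]
    chunks.append(("WALL", np.concatenate(wall)))

    r0 = spec.radius_at(0.0)
    cap = [_ring(0.0, r, s, rng.uniform(0, 2 * np.pi))
           for r in np.arange(0.0, r0, s)]
    chunks.append(("CAP", np.concatenate(cap)))

    r_exit = spec.radius_at(spec.length)
    plate = [_ring(spec.length, r, s, rng.uniform(0, 2 * np.pi))
             for r in np.arange(r_exit, spec.plate_radius + 0.5 * s, s)]
    chunks.append(("PLATE", np.concatenate(plate)))

    if spec.constriction is not None:
        cz, cr = spec.constriction
        rows = []
        for z in np.arange(cz - 4.0, cz - 4.0 + spec.constriction_extent + 0.1, s):
            if spec.radius_at(z) > cr + 0.5:
                rows.append(_ring(z, cr, s, rng.uniform(0, 2 * np.pi)))
        if rows:
            chunks.append(("MID", np.concatenate(rows)))

    rows = []
    for z in np.arange(spec.obstruction_start, spec.length + 0.1, s):
        for r in np.arange(spec.exit_opening, spec.radius_at(z), s):
            rows.append(_ring(z, r, s, rng.uniform(0, 2 * np.pi)))
    if rows:
        chunks.append(("EXIT", np.concatenate(rows)))

    kinds, chains, resids, coords = [], [], [], []
    for name, arr in chunks:
        kinds.extend(["CA"] * len(arr))
        chains.extend([name] * len(arr))
        resids.extend(range(1, len(arr) + 1))
        coords.append(arr)
    coords = np.concatenate(coords)
    beads = BeadModel(np.array(kinds), np.array(chains), np.array(resids),
                      coords, np.full(len(coords), 2.5))
    anchor = np.array([0.0, 0.0, 5.0])
    axis = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, spec.length]])
    init_radius = _free_radius_from_beads(beads, anchor_z=anchor[2])
    return RibosomeScaffold(beads=beads, anchor=anchor, axis=axis,
                            init_radius=init_radius)


def _free_radius_from_beads(beads: BeadModel, anchor_z: float,
                            window: float = 2.5) -> np.ndarray:
    """Free-radius profile measured directly off the scaffold beads: at each
    axial position, the smallest radial bead distance within an axial
    window. Removing obstruction beads therefore widens the profile
    automatically."""
    z = beads.coord[:, 2]
    r = np.linalg.norm(beads.coord[:, :2], axis=1)
    # ignore end caps/plates lying flat at the tunnel ends when probing the
    # interior: they enter only at their own axial position anyway
    s_grid = np.arange(0.0, z.max() - anchor_z + 1.0, 2.0)
    out = np.empty_like(s_grid)
    for k, s in enumerate(s_grid):
        sel = np.abs(z - (s + anchor_z)) <= window
        sel &= r > 1e-6  # skip on-axis cap beads
        out[k] = r[sel].min() if sel.any() else 1e6
    # guard band: the last ring's radius still binds for a few angstroms
    # beyond the scaffold before the profile opens up
    s_grid = np.append(s_grid, s_grid[-1] + 4.0)
    out = np.append(out, out[-1])
    return np.stack([s_grid, out], axis=1)


def remove_tunnel_loop(scaffold: RibosomeScaffold, which: str) -> RibosomeScaffold:
    """Delete one of the removable obstructions: ``"mid"`` (uL23-loop
    analogue) or ``"exit"`` (uL24-loop analogue)."""
    chain = {"mid": "MID", "exit": "EXIT"}[which]
    keep = scaffold.beads.chain_id != chain
    if keep.all():
        warnings.warn(f"scaffold has no {chain} beads to remove")
    beads = scaffold.beads.subset(keep)
    return RibosomeScaffold(beads=beads,
                            anchor=scaffold.anchor.copy(),
                            axis=scaffold.axis.copy(),
                            init_radius=_free_radius_from_beads(
                                beads, anchor_z=scaffold.anchor[2]))


# ------------------------------------------------------------------- domains

@dataclass(frozen=True)
class ToyDomainSpec:
    """Procedural two-state toy domain.

    ``hairpin``: an elongated two-strand beta-hairpin (small cross-section,
    folds in modest free radius). ``three-helix``: a wide bundle needing a
    large free radius. ``target_contacts``, when given, validates the
    generated contact count to within +/-2.
    """

    fold_class: str = "hairpin"
    n_residues: int = 12
    target_contacts: int | None = None
    epsilon: float = 1.0
    contact_cutoff: float | None = None   # CA-CA; per-class default if None
    min_separation: int | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("need at least 8 residues")
        if self.fold_class not in ("hairpin", "three-helix"):
            raise ValueError(f"unknown fold class {self.fold_class!r}")

    @property
    def effective_cutoff(self) -> float:
        if self.contact_cutoff is not None:
            return self.contact_cutoff
        # hairpin: cross-strand CA pairs sit at ~5-6 A. three-helix: count
        # only tertiary (inter-helix) pairs, which requires a larger reach,
        # and drop intra-helix i,i+4 pairs via the separation filter so that
        # Q reports bundle assembly, not helicity -- this keeps the fold
        # two-state.
        return 6.5 if self.fold_class == "hairpin" else 8.5

    @property
    def effective_min_separation(self) -> int:
        if self.min_separation is not None:
            return self.min_separation
        return 4 if self.fold_class == "hairpin" else 6


def _hairpin_coords(n: int) -> np.ndarray:
    half = n // 2
    pos = np.zeros((n, 3))
    for i in range(half):
        pos[i] = (0.4 * (-1) ** i, 0.0, 3.2 * i)
    for i in range(half, n):
        pos[i] = (4.8 + 0.4 * (-1) ** i, 0.0, 3.2 * (n - 1 - i))
    return pos


def _three_helix_coords(n: int) -> np.ndarray:
    """Three ideal helices at triangle vertices, alternating direction,
    joined by short straight loops."""
    n_loop = 2
    n_helix = (n - 2 * n_loop) // 3
    extra = (n - 2 * n_loop) - 3 * n_helix
    lengths = [n_helix + (1 if k < extra else 0) for k in range(3)]
    side = 9.5
    verts = [np.array([0.0, 0.0]), np.array([side, 0.0]),
             np.array([side / 2, side * np.sqrt(3) / 2])]
    centroid = np.mean(verts, axis=0)
    rise, radius, turn = 1.5, 2.3, np.deg2rad(100.0)
    pos = []
    for k in range(3):
        nh = lengths[k]
        up = k % 2 == 0
        # phase the helix so its residues face the bundle core
        toward = np.arctan2(*(centroid - verts[k])[::-1])
        for i in range(nh):
            ang = toward + turn * (i - nh / 2)
            z = rise * (i if up else nh - 1 - i)
            pos.append([verts[k][0] + radius * np.cos(ang),
                        verts[k][1] + radius * np.sin(ang), z])
        if k < 2:
            a = np.array(pos[-1])
            # loop beads filled in after computing next helix start
            nh2 = lengths[k + 1]
            up2 = (k + 1) % 2 == 0
            toward2 = np.arctan2(*(centroid - verts[k + 1])[::-1])
            ang2 = toward2 + turn * (0 - nh2 / 2)
            z2 = rise * (0 if up2 else nh2 - 1)
            b = np.array([verts[k + 1][0] + radius * np.cos(ang2),
                          verts[k + 1][1] + radius * np.sin(ang2), z2])
            for t in range(1, n_loop + 1):
                frac = t / (n_loop + 1)
                mid = a + frac * (b - a)
                # bow the loop outward so it does not clash with the core
                away = mid[:2] - centroid
                mid = mid + np.array([*(0.35 * away / max(np.linalg.norm(away), 1e-9)), 1.2])
                pos.append(list(mid))
    return np.asarray(pos)


def _as_structure(coords: np.ndarray) -> MolecularStructure:
    n = len(coords)
    return MolecularStructure(
        chain_id=np.full(n, "A"), res_id=np.arange(1, n + 1),
        res_name=np.full(n, "GLY"), atom_name=np.full(n, "CA"),
        element=np.full(n, "C"), coord=coords)


def make_toy_domain(spec: ToyDomainSpec = ToyDomainSpec(), seed: int = 0,
                    max_retries: int = 8):
    """Generate a toy domain: (native structure, topology).

    The native conformation is an exact local minimum of the generated
    potential (checked; gradient norm < 1e-6 per bead component in reduced
    units). A seeded sub-angstrom jitter decorrelates repeated draws without
    changing the topology statistics.
    """
    base = (_hairpin_coords(spec.n_residues) if spec.fold_class == "hairpin"
            else _three_helix_coords(spec.n_residues))
    params = GoParams(contact_cutoff=spec.effective_cutoff,
                      min_separation=spec.effective_min_separation,
                      epsilon=spec.epsilon)
    rng = np.random.default_rng(seed)
    last_err = None
    for _ in range(max_retries):
        coords = base + rng.normal(0.0, 0.03, size=base.shape)
        structure = _as_structure(coords)
        try:
            topology = build_topology(structure, params)
        except ValueError as exc:
            last_err = exc
            continue
        if topology.n_contacts == 0:
            last_err = ValueError("no native contacts generated")
            continue
        rep = topology.repulsive_pairs()
        if len(rep):
            d = np.linalg.norm(coords[rep[:, 1]] - coords[rep[:, 0]], axis=1)
            if d.min() <= params.ev_sigma + 0.05:
                last_err = ValueError("non-native pair inside excluded core")
                continue
        g = potential_gradient(topology, coords)
        if np.abs(g).max() >= 1e-6:
            last_err = ValueError("native not a local minimum")
            continue
        if (spec.target_contacts is not None
                and abs(topology.n_contacts - spec.target_contacts) > 2):
            raise ValueError(
                f"generated {topology.n_contacts} contacts, target "
                f"{spec.target_contacts} +/- 2")
        return structure, topology
    raise ValueError(f"domain generation failed: {last_err}")


#: simulation temperatures per fold class: ~0.9x the folding midpoint of the
#: default domains, determined once with calibrate_folding_temperature scans
#: (midpoints ~1.2 for the 12-residue hairpin, ~1.13 for the 28-residue
#: bundle); both folded and unfolded states are sampled at these values
_CALIBRATED_T = {"hairpin": 1.08, "three-helix": 1.02}


def suggested_temperature(spec: ToyDomainSpec) -> float:
    """Calibrated simulation temperature (~0.9x folding midpoint) for the
    default toy domains; both states are sampled at this temperature."""
    value = _CALIBRATED_T.get(spec.fold_class)
    if value is None:
        raise ValueError(f"no calibrated temperature for {spec.fold_class}")
    return value


# ------------------------------------------------------------------ profiles

@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Single-peaked profile with known half-maximal features."""

    L_grid: tuple = tuple(range(10, 41))
    onset: int = 20
    peak: int = 25
    end: int = 30
    amplitude: float = 0.6
    baseline: float = 0.05
    sigma: float = 0.02
    n_replicates: int = 3
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if not (self.onset < self.peak < self.end):
            raise ValueError("need onset < peak < end")
        grid = list(self.L_grid)
        if not (grid[0] <= self.onset and self.end <= grid[-1]):
            raise ValueError("features must lie within the L grid")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def _noiseless_profile(spec: SyntheticProfileSpec) -> np.ndarray:
    """Piecewise-linear peak passing through half-maximum exactly at the
    true onset and end and peaking at the true maximum."""
    L = np.asarray(spec.L_grid, dtype=float)
    start = 2.0 * spec.onset - spec.peak
    stop = 2.0 * spec.end - spec.peak
    top = spec.baseline + spec.amplitude
    f = np.full_like(L, spec.baseline)
    rising = (L > start) & (L <= spec.peak)
    f[rising] = spec.baseline + spec.amplitude * (L[rising] - start) / (spec.peak - start)
    falling = (L > spec.peak) & (L < stop)
    f[falling] = spec.baseline + spec.amplitude * (stop - L[falling]) / (stop - spec.peak)
    return np.clip(f, 0.0, 1.0)


def make_synthetic_profile(spec: SyntheticProfileSpec,
                           seed: int = 0) -> list[FflProfile]:
    """Replicate f_FL profiles: the noiseless shape plus independent
    Gaussian noise per replicate and point, clipped to [0, 1]."""
    mean = _noiseless_profile(spec)
    rng = np.random.default_rng(seed)
    out = []
    L = np.asarray(spec.L_grid, dtype=np.int64)
    for _ in range(spec.n_replicates):
        noisy = np.clip(mean + rng.normal(0.0, spec.sigma, size=mean.shape),
                        0.0, 1.0)
        out.append(FflProfile(L, noisy, condition=spec.condition))
    return out


def make_synthetic_gel(profile: FflProfile, total_intensity: float = 1000.0,
                       sigma: float = 0.0, seed: int = 0) -> list[LaneQuantification]:
    """Gel band-intensity pairs consistent with a profile: I_FL = f * total,
    I_A = (1 - f) * total, plus optional additive Gaussian noise of standard
    deviation ``sigma * total`` per band (clipped at a small positive
    floor). At sigma = 0 the intensity ratio reproduces f_FL exactly."""
    if total_intensity <= 0:
        raise ValueError("total intensity must be positive")
    rng = np.random.default_rng(seed)
    lanes = []
    for L, f in zip(profile.L.tolist(), profile.f_fl.tolist()):
        ifl = f * total_intensity
        ia = (1.0 - f) * total_intensity
        if sigma > 0:
            ifl += rng.normal(0.0, sigma * total_intensity)
            ia += rng.normal(0.0, sigma * total_intensity)
        floor = 1e-9 * total_intensity
        lanes.append(LaneQuantification(I_A=max(ia, floor),
                                        I_FL=max(ifl, floor),
                                        L=int(L), condition=profile.condition))
    return lanes
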
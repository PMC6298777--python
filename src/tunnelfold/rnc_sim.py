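"""Langevin simulation of a ribosome-nascent-chain (RNC) complex.

A nascent chain — a structure-based (Go) domain plus a passive linker that
includes the arrest peptide — is threaded through a static, purely repulsive
tunnel scaffold. The chain's C-terminal bead is position-restrained at the
peptidyl-transfer-center (PTC) anchor, and the pulling force that folding
exerts on the arrest peptide is read off the extension of a harmonic
pseudobond between the last and second-last chain beads. Frames are
classified folded/unfolded by the fraction of native contacts Q, yielding
per-linker-length force statistics (Pu, Pf, Fu, Ff) for the kinetic model.

Reduced units: bead mass 1, energy in epsilon, length in angstrom, time in
tau; temperature in epsilon/k_B. Forces convert to pN through the physical
value of epsilon in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from tunnelfold import _kernels
from tunnelfold.constants import KCAL_PER_MOL_PER_ANGSTROM_IN_PN
from tunnelfold.go_model import NativeTopology
from tunnelfold.structure_io import BeadModel

__all__ = [
    "RNCConstruct",
    "RibosomeScaffold",
    "SimulationParams",
    "ForceStatistics",
    "RNCSystem",
    "TrajectorySummary",
    "assemble_rnc",
    "run_langevin",
    "measure_force_statistics",
    "scan_linker_lengths",
    "domain_system",
    "single_bead_system",
    "calibrate_folding_temperature",
    "force_statistics_table",
]

BOND_LENGTH = 3.8          # A, virtual CA-CA bond in the linker
GENERIC_ANGLE = 2.0        # rad, resting angle of linker triples
GENERIC_ANGLE_K = 1.0      # epsilon/rad^2, weak linker bending stiffness
ARREST_PEPTIDE_LENGTH = 17


@dataclass
class RibosomeScaffold:
    """Static repulsive scaffold with a tether anchor and a tunnel axis.

    ``init_radius``, when present, is a piecewise-linear free-radius profile
    (axial position from the first axis point, radius) used only to thread
    the initial chain conformation compactly inside the tunnel; it has no
    effect on the dynamics.
    """

    beads: BeadModel
    anchor: np.ndarray          # PTC proxy, A
    axis: np.ndarray            # polyline (k, 3) from PTC to exit, A
    init_radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(-1, 3)
        if len(self.axis) < 2:
            raise ValueError("axis needs at least two points")
        if self.init_radius is not None:
            self.init_radius = np.asarray(self.init_radius,
                                          dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class RNCConstruct:
    """Domain topology plus linker length L.

    L counts the residues between the domain's C-terminal residue and the
    PTC anchor; the last ``ap_length`` of them represent the arrest peptide.
    Linker and arrest-peptide beads carry bonds, weak generic angles and
    excluded volume only — they are a passive tether.
    """

    domain: NativeTopology
    L: int
    ap_length: int = ARREST_PEPTIDE_LENGTH
    explicit_ap: bool = True

    def __post_init__(self) -> None:
        if self.explicit_ap and self.L < self.ap_length:
            raise ValueError(
                f"L = {self.L} shorter than the {self.ap_length}-residue "
                "arrest peptide")
        if self.L < 1:
            raise ValueError("L must be positive")

    @property
    def total_length(self) -> int:
        return self.domain.n_beads + self.L


@dataclass(frozen=True)
class SimulationParams:
    """Langevin run parameters (reduced units unless noted)."""

    temperature: float = 0.8        # epsilon/kB
    friction: float = 1.0           # 1/tau
    dt: float = 0.005               # tau
    equilibration_steps: int = 20_000
    production_steps: int = 200_000
    stride: int = 50                # record every `stride` steps
    seed: int = 0
    k_tether: float = 100.0         # epsilon/A^2 (F = k * extension offset)
    tether_r0: float = BOND_LENGTH  # A
    k_anchor: float = 200.0         # epsilon/A^2 position restraint
    q_folded: float = 0.7
    q_unfolded: float = 0.3
    q_tolerance: float = 1.2
    epsilon_kcal_per_mol: float | None = None
    physical_temperature: float = 310.15  # K, for the default epsilon map
    max_displacement: float = 2.0   # A per half-step; larger aborts the run

    def __post_init__(self) -> None:
        if not (0.0 < self.q_unfolded < self.q_folded < 1.0):
            raise ValueError("need 0 < q_unfolded < q_folded < 1")
        if self.production_steps <= 0 or self.equilibration_steps < 0:
            raise ValueError("step counts must be positive")

    @property
    def epsilon_physical(self) -> float:
        """epsilon in kcal/mol. By default the reduced thermal energy
        (temperature * epsilon) is identified with k_B * 310.15 K, so that
        entropic chain forces come out on the physical pN scale."""
        if self.epsilon_kcal_per_mol is not None:
            return self.epsilon_kcal_per_mol
        from tunnelfold.constants import KB_KCAL_PER_MOL_K
        return KB_KCAL_PER_MOL_K * self.physical_temperature / self.temperature

    @property
    def force_to_pN(self) -> float:
        return self.epsilon_physical * KCAL_PER_MOL_PER_ANGSTROM_IN_PN


@dataclass
class ForceStatistics:
    """Per-linker-length populations and mean tether forces.

    Pu and Pf are renormalized over classified (non-intermediate) frames and
    sum to 1; ``p_intermediate`` records the discarded mid-Q fraction of all
    frames. Forces are in pN; a state with no frames reports NaN force and
    zero population.
    """

    L: int
    Pu: float
    Pf: float
    Fu: float
    Ff: float
    se_Pu: float = 0.0
    se_Pf: float = 0.0
    se_Fu: float = float("nan")
    se_Ff: float = float("nan")
    n_unfolded: int = 0
    n_folded: int = 0
    p_intermediate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.Pu <= 1 and 0 <= self.Pf <= 1):
            raise ValueError("populations must lie in [0, 1]")


@dataclass
class RNCSystem:
    """Fully assembled kernel-ready system."""

    positions: np.ndarray
    radii: np.ndarray
    bonds: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray
    angle_theta0: np.ndarray
    angle_k: np.ndarray
    dihedrals: np.ndarray
    dihedral_phi0: np.ndarray
    kd1: float
    kd3: float
    contacts: np.ndarray
    contact_sigma: np.ndarray
    eps_contact: float
    rep_pairs: np.ndarray
    ev_sigma: float
    scaffold_pos: np.ndarray
    scaffold_rad: np.ndarray
    anchor_idx: int
    anchor_pos: np.ndarray
    tether: tuple[int, int]
    n_domain: int = 0
    L: int = 0
    double_well: tuple[float, float, float, float] | None = None  # a, b, c, kxy
    pull_dir: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def n_beads(self) -> int:
        return len(self.positions)


@dataclass
class TrajectorySummary:
    """Recorded time series of one Langevin run."""

    q: np.ndarray               # order parameter per frame (Q for RNC runs)
    tether_extension: np.ndarray  # pseudobond elongation projected on the pull axis, A
    bead0_positions: np.ndarray
    final_positions: np.ndarray
    frame_dt: float             # tau between recorded frames
    L: int = 0
    status: int = _kernels.STATUS_OK


# ------------------------------------------------------------------ assembly

def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _axis_point(axis: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length s along a polyline, extended past the last node."""
    seg = np.diff(axis, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = 0.0
    for k in range(len(seg)):
        if s <= total + seg_len[k]:
            t = (s - total) / seg_len[k]
            return axis[k] + t * seg[k]
        total += seg_len[k]
    direction = seg[-1] / seg_len[-1]
    return axis[-1] + (s - total) * direction


def _thread_chain(axis: np.ndarray, init_radius: np.ndarray | None,
                  n: int) -> np.ndarray:
    """Initial chain conformation threaded along the axis, C-terminus first.

    Without a free-radius profile the chain lies extended on the axis. With
    one, it winds a loose helix wherever the local free radius allows,
    which keeps even long chains inside the tunnel interior instead of
    poking through the exit obstructions.
    """
    clearance = 5.0  # chain-bead centre to wall-bead centre, plus margin
    pts = np.empty((n, 3))
    direction = _unit(axis[-1] - axis[-2])
    s = 0.0      # arc length along the axis
    phase = 0.0
    for k in range(n - 1, -1, -1):
        base = _axis_point(axis, s)
        a = 0.0
        if init_radius is not None:
            # minimum free radius over an axial window, so the coil backs
            # off before it reaches a constriction edge
            window = np.linspace(s - 4.0, s + 4.0, 5)
            free_r = float(np.interp(window, init_radius[:, 0],
                                     init_radius[:, 1]).min())
            a = min(max(free_r - clearance, 0.0), 4.0)
        if a >= 2.0:
            # helical packing: rise 1.0 A per bead, chord fits the bond
            chord = np.sqrt(BOND_LENGTH ** 2 - 1.0)
            phase += 2.0 * np.arcsin(min(chord / (2.0 * a), 1.0))
            # local frame perpendicular to the axis
            ref = np.array([1.0, 0.0, 0.0])
            if abs(direction @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = _unit(np.cross(direction, ref))
            e2 = np.cross(direction, e1)
            pts[k] = base + a * (np.cos(phase) * e1 + np.sin(phase) * e2)
            rise = 1.0
        else:
            pts[k] = base
            rise = BOND_LENGTH
        s += rise
    pts[n - 1] = _axis_point(axis, 0.0)
    return pts


def _aligned_native(topology: NativeTopology) -> np.ndarray:
    """Native coordinates centred and rotated so the longest principal axis
    lies along +z with the C-terminal bead at the low-z end."""
    x = topology.native_coord - topology.native_coord.mean(axis=0)
    _, _, vt = np.linalg.svd(x)
    R = vt  # rows: principal axes, first = longest
    aligned = x @ R.T
    aligned = aligned[:, [1, 2, 0]]  # longest axis -> z
    if aligned[-1, 2] > aligned[:, 2].mean():
        aligned[:, 2] *= -1.0  # flip so the C-terminus points to the PTC
        aligned[:, 0] *= -1.0  # keep the frame right-handed
    return aligned


def _place_folded(axis: np.ndarray, init_radius: np.ndarray | None,
                  topology: NativeTopology, L: int,
                  clearance: float = 4.6) -> np.ndarray | None:
    """Construct an initial state with the domain folded at the deepest
    axial position the free-radius profile admits, linker threaded straight
    to the anchor. Returns None when no such placement exists (not enough
    space anywhere in reach, or the linker cannot span the distance)."""
    if topology.native_coord is None or init_radius is None:
        return None
    dom = _aligned_native(topology)
    n_dom = len(dom)
    direction = _unit(axis[-1] - axis[-2])
    max_reach = L * BOND_LENGTH * 1.02
    bead_r = np.linalg.norm(dom[:, :2], axis=1)
    for z0 in np.arange(4.0, float(init_radius[-1, 0]) + 60.0, 1.0):
        zs = z0 + dom[:, 2] - dom[:, 2].min()
        free = np.interp(zs, init_radius[:, 0], init_radius[:, 1],
                         right=1e6)
        if np.any(bead_r > free - clearance):
            continue
        z_cterm = z0 + (dom[-1, 2] - dom[:, 2].min())
        if z_cterm > max_reach:
            return None  # deeper placements only get farther
        # build coordinates: domain plus a linker that eases from the
        # C-terminal bead onto the axis and runs down to the anchor
        pos = np.empty((n_dom + L, 3))
        ref = np.array([1.0, 0.0, 0.0])
        if abs(direction @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = _unit(np.cross(direction, ref))
        e2 = np.cross(direction, e1)
        for k in range(n_dom):
            base = _axis_point(axis, z0 + dom[k, 2] - dom[:, 2].min())
            pos[k] = base + dom[k, 0] * e1 + dom[k, 1] * e2
        spacing = z_cterm / L
        radial = dom[-1, 0] * e1 + dom[-1, 1] * e2
        for j in range(1, L + 1):
            s = z_cterm - j * spacing
            p = _axis_point(axis, max(s, 0.0))
            # radial offset of the C-terminus decays over the first beads
            decay = max(0.0, 1.0 - j / 3.0)
            p = p + decay * radial
            if spacing < 3.0 and 0 < j < L and decay == 0.0:
                # tuck slack off-axis so consecutive beads are not stacked
                p = p + 1.2 * ((-1.0) ** j) * e1
            pos[n_dom + j - 1] = p
        pos[-1] = _axis_point(axis, 0.0)
        return pos
    return None


def _chain_terms(construct: RNCConstruct, params: SimulationParams):
    dom = construct.domain
    p = dom.params
    n_dom = dom.n_beads
    n = construct.total_length
    bonds, bond_r0 = [], []
    for (i, j), r0 in zip(dom.bonds, dom.bond_r0):
        bonds.append((i, j))
        bond_r0.append(r0)
    for i in range(n_dom - 1, n - 2):  # junction + linker; last pair = tether
        bonds.append((i, i + 1))
        bond_r0.append(BOND_LENGTH)
    angles, theta0, ka = [], [], []
    for (i, j, k), t0 in zip(dom.angles, dom.angle_theta0):
        angles.append((i, j, k))
        theta0.append(t0)
        ka.append(p.k_angle)
    for j in range(n_dom - 1, n - 1):
        if j < 1 or j > n - 2:
            continue
        angles.append((j - 1, j, j + 1))
        theta0.append(GENERIC_ANGLE)
        ka.append(GENERIC_ANGLE_K)
    native = set(map(tuple, dom.contacts.tolist()))
    i_idx, j_idx = np.triu_indices(n, k=4)
    rep = [(a, b) for a, b in zip(i_idx.tolist(), j_idx.tolist())
           if (a, b) not in native]
    return (np.array(bonds, dtype=np.int64).reshape(-1, 2), np.array(bond_r0),
            np.array(angles, dtype=np.int64).reshape(-1, 3), np.array(theta0),
            np.array(ka),
            dom.dihedrals, dom.dihedral_phi0, p.k_dihedral_1, p.k_dihedral_3,
            dom.contacts, dom.contact_sigma,
            np.array(rep, dtype=np.int64).reshape(-1, 2), p.ev_sigma)


def assemble_rnc(scaffold: RibosomeScaffold, construct: RNCConstruct,
                 params: SimulationParams = SimulationParams(),
                 seed: int = 0,
                 threadable_margin: float = 250.0,
                 folding_competent: bool = True,
                 start: str = "unfolded") -> RNCSystem:
    """Assemble an RNC system at linker length L.

    ``start="unfolded"`` threads the chain along the tunnel axis (coiled
    where the free radius allows) with its C-terminus at the PTC anchor;
    ``start="folded"`` places the native domain at the deepest axial
    position the tunnel admits, raising ``ValueError`` when no geometrically
    and elastically consistent folded placement exists. A small
    deterministic transverse jitter (seeded) avoids exactly collinear
    triples. ``folding_competent=False`` zeroes the native-contact energy,
    the analogue of removing a folding ligand. Raises when the chain contour
    exceeds the threadable path (axis length plus ``threadable_margin``
    outside the exit).
    """
    (bonds, bond_r0, angles, theta0, ka, dihedrals, phi0, kd1, kd3,
     contacts, sigma, rep_pairs, ev_sigma) = _chain_terms(construct, params)
    n = construct.total_length
    axis_len = float(np.linalg.norm(np.diff(scaffold.axis, axis=0),
                                    axis=1).sum())
    contour = (n - 1) * BOND_LENGTH
    if contour > axis_len + threadable_margin:
        raise ValueError(
            f"chain contour {contour:.0f} A exceeds threadable path "
            f"{axis_len + threadable_margin:.0f} A")
    rng = np.random.default_rng(seed)
    axis0 = scaffold.axis + (scaffold.anchor - scaffold.axis[0])
    if start == "unfolded":
        pos = _thread_chain(axis0, scaffold.init_radius, n)
    elif start == "folded":
        pos = _place_folded(axis0, scaffold.init_radius, construct.domain,
                            construct.L)
        if pos is None:
            raise ValueError(
                f"folded start not constructible at L={construct.L}")
    else:
        raise ValueError("start must be 'unfolded' or 'folded'")
    jitter = rng.normal(0.0, 0.15, size=(n, 3))
    jitter[-1] = 0.0  # anchored bead exactly at the anchor
    pos += jitter
    eps = construct.domain.params.epsilon
    system = RNCSystem(
        positions=pos,
        radii=np.full(n, 2.0),
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, angle_theta0=theta0, angle_k=ka,
        dihedrals=dihedrals, dihedral_phi0=phi0, kd1=kd1, kd3=kd3,
        contacts=contacts, contact_sigma=sigma,
        eps_contact=(eps if folding_competent else 0.0),
        rep_pairs=rep_pairs, ev_sigma=ev_sigma,
        scaffold_pos=scaffold.beads.coord.copy(),
        scaffold_rad=scaffold.beads.radius.copy(),
        anchor_idx=n - 1, anchor_pos=scaffold.anchor.copy(),
        tether=(n - 2, n - 1),
        n_domain=construct.domain.n_beads, L=construct.L,
        pull_dir=_unit(scaffold.axis[1] - scaffold.axis[0]),
    )
    _relax_positions(system, params)
    return system


def domain_system(topology: NativeTopology, start: str = "native") -> RNCSystem:
    """Isolated domain (no scaffold, no tether): calibration runs and
    folded/unfolded reference simulations."""
    n = topology.n_beads
    if start == "native":
        if topology.native_coord is None:
            raise ValueError("topology lacks native coordinates")
        pos = topology.native_coord.copy()
    elif start == "extended":
        pos = np.zeros((n, 3))
        pos[:, 2] = np.arange(n) * BOND_LENGTH
        pos[:, 0] = 0.3 * (np.arange(n) % 2)
    else:
        raise ValueError("start must be 'native' or 'extended'")
    p = topology.params
    return RNCSystem(
        positions=pos, radii=np.full(n, 2.0),
        bonds=topology.bonds, bond_r0=topology.bond_r0,
        angles=topology.angles, angle_theta0=topology.angle_theta0,
        angle_k=np.full(len(topology.angles), p.k_angle),
        dihedrals=topology.dihedrals, dihedral_phi0=topology.dihedral_phi0,
        kd1=p.k_dihedral_1, kd3=p.k_dihedral_3,
        contacts=topology.contacts, contact_sigma=topology.contact_sigma,
        eps_contact=p.epsilon,
        rep_pairs=topology.repulsive_pairs(), ev_sigma=p.ev_sigma,
        scaffold_pos=np.zeros((0, 3)), scaffold_rad=np.zeros(0),
        anchor_idx=-1, anchor_pos=np.zeros(3), tether=(0, 0),
        n_domain=n,
    )


def single_bead_system(k_anchor: float = 0.0,
                       double_well: tuple | None = None) -> RNCSystem:
    """One free or restrained bead: equipartition / diffusion / double-well
    fixtures."""
    return RNCSystem(
        positions=np.zeros((1, 3)), radii=np.array([2.0]),
        bonds=np.zeros((0, 2), dtype=np.int64), bond_r0=np.zeros(0),
        angles=np.zeros((0, 3), dtype=np.int64), angle_theta0=np.zeros(0),
        angle_k=np.zeros(0),
        dihedrals=np.zeros((0, 4), dtype=np.int64), dihedral_phi0=np.zeros(0),
        kd1=0.0, kd3=0.0,
        contacts=np.zeros((0, 2), dtype=np.int64), contact_sigma=np.zeros(0),
        eps_contact=0.0,
        rep_pairs=np.zeros((0, 2), dtype=np.int64), ev_sigma=4.0,
        scaffold_pos=np.zeros((0, 3)), scaffold_rad=np.zeros(0),
        anchor_idx=(0 if k_anchor > 0 else -1), anchor_pos=np.zeros(3),
        tether=(0, 0), double_well=double_well,
    )


# ---------------------------------------------------------------- simulation

def _kernel_forces(system: RNCSystem, params: SimulationParams,
                   positions: np.ndarray, grid) -> np.ndarray:
    origin, csize, dims, cstart, citems = grid
    f = np.zeros_like(positions)
    dw = system.double_well
    _kernels._forces(
        positions, f,
        np.ascontiguousarray(system.radii, dtype=np.float64),
        np.ascontiguousarray(system.bonds, dtype=np.int64),
        np.ascontiguousarray(system.bond_r0, dtype=np.float64), 100.0,
        int(system.tether[0]), int(system.tether[1]),
        params.k_tether, params.tether_r0,
        np.ascontiguousarray(system.angles, dtype=np.int64),
        np.ascontiguousarray(system.angle_theta0, dtype=np.float64),
        np.ascontiguousarray(system.angle_k, dtype=np.float64),
        np.ascontiguousarray(system.dihedrals, dtype=np.int64),
        np.ascontiguousarray(system.dihedral_phi0, dtype=np.float64),
        float(system.kd1), float(system.kd3),
        np.ascontiguousarray(system.contacts, dtype=np.int64),
        np.ascontiguousarray(system.contact_sigma, dtype=np.float64),
        float(system.eps_contact),
        np.ascontiguousarray(system.rep_pairs, dtype=np.int64),
        float(system.ev_sigma), 1.0,
        np.ascontiguousarray(system.scaffold_pos, dtype=np.float64),
        np.ascontiguousarray(system.scaffold_rad, dtype=np.float64),
        np.ascontiguousarray(origin, dtype=np.float64), float(csize),
        np.ascontiguousarray(dims, dtype=np.int64),
        np.ascontiguousarray(cstart, dtype=np.int64),
        np.ascontiguousarray(citems, dtype=np.int64),
        int(system.anchor_idx),
        np.ascontiguousarray(system.anchor_pos, dtype=np.float64),
        params.k_anchor,
        dw is not None,
        float(dw[0]) if dw else 0.0, float(dw[1]) if dw else 0.0,
        float(dw[2]) if dw else 0.0, float(dw[3]) if dw else 0.0,
    )
    return f


def _relax_positions(system: RNCSystem, params: SimulationParams,
                     n_steps: int = 300, max_step: float = 0.2) -> None:
    """Capped-step steepest descent on the assembled state; removes the
    steric clashes that constructed initial geometries can carry without
    moving anything far from where it was placed."""
    grid = _kernels.build_cell_grid(system.scaffold_pos)
    pos = np.ascontiguousarray(system.positions, dtype=np.float64)
    for _ in range(n_steps):
        f = _kernel_forces(system, params, pos, grid)
        if system.anchor_idx >= 0:
            f[system.anchor_idx] = 0.0
        fmax = np.abs(f).max()
        if fmax < 50.0:
            break
        pos += f * (max_step / fmax)
    system.positions = pos


def run_langevin(system: RNCSystem, params: SimulationParams,
                 k_anchor: float | None = None) -> TrajectorySummary:
    """Run BAOAB Langevin dynamics; fixed seed gives identical output.

    Records Q (or, for contact-free fixtures, an indicator of bead 0 being at
    z > 0) and the tether extension every ``params.stride`` steps. Raises
    ``RuntimeError`` if any half-step displacement exceeds the safety bound.
    """
    origin, csize, dims, cstart, citems = _kernels.build_cell_grid(
        system.scaffold_pos)
    dw = system.double_well
    ka = params.k_anchor if k_anchor is None else k_anchor
    q, ext, pos0, final, status = _kernels.run_baoab(
        np.ascontiguousarray(system.positions, dtype=np.float64),
        np.ascontiguousarray(system.radii, dtype=np.float64),
        np.ascontiguousarray(system.bonds, dtype=np.int64),
        np.ascontiguousarray(system.bond_r0, dtype=np.float64),
        100.0,
        int(system.tether[0]), int(system.tether[1]),
        params.k_tether, params.tether_r0,
        np.ascontiguousarray(system.angles, dtype=np.int64),
        np.ascontiguousarray(system.angle_theta0, dtype=np.float64),
        np.ascontiguousarray(system.angle_k, dtype=np.float64),
        np.ascontiguousarray(system.dihedrals, dtype=np.int64),
        np.ascontiguousarray(system.dihedral_phi0, dtype=np.float64),
        float(system.kd1), float(system.kd3),
        np.ascontiguousarray(system.contacts, dtype=np.int64),
        np.ascontiguousarray(system.contact_sigma, dtype=np.float64),
        float(system.eps_contact), params.q_tolerance,
        np.ascontiguousarray(system.rep_pairs, dtype=np.int64),
        float(system.ev_sigma), 1.0,
        np.ascontiguousarray(system.scaffold_pos, dtype=np.float64),
        np.ascontiguousarray(system.scaffold_rad, dtype=np.float64),
        np.ascontiguousarray(origin, dtype=np.float64), float(csize),
        np.ascontiguousarray(dims, dtype=np.int64),
        np.ascontiguousarray(cstart, dtype=np.int64),
        np.ascontiguousarray(citems, dtype=np.int64),
        int(system.anchor_idx),
        np.ascontiguousarray(system.anchor_pos, dtype=np.float64),
        float(ka),
        dw is not None,
        float(dw[0]) if dw else 0.0, float(dw[1]) if dw else 0.0,
        float(dw[2]) if dw else 0.0, float(dw[3]) if dw else 0.0,
        np.ascontiguousarray(system.pull_dir, dtype=np.float64),
        params.temperature, params.friction, params.dt,
        params.production_steps, params.equilibration_steps, params.stride,
        int(params.seed) % (2 ** 31), params.max_displacement,
    )
    if status == _kernels.STATUS_BLOWUP:
        raise RuntimeError(
            "Langevin integration aborted: per-step displacement exceeded "
            f"{params.max_displacement} A (time step too large or bad "
            "initial geometry)")
    return TrajectorySummary(q=q, tether_extension=ext, bead0_positions=pos0,
                             final_positions=final,
                             frame_dt=params.dt * params.stride,
                             L=system.L, status=status)


def measure_force_statistics(summary: TrajectorySummary,
                             params: SimulationParams) -> ForceStatistics:
    """Classify frames by Q and average the tether force per state.

    Folded: Q >= q_folded; unfolded: Q <= q_unfolded; intermediate frames are
    discarded. The tether force is k_tether times the mean axis-projected
    elongation of the pseudobond, converted to pN through epsilon. Standard
    errors treat recorded frames as independent (choose the recording stride
    accordingly).
    """
    q = summary.q
    if len(q) == 0:
        raise ValueError("empty trajectory")
    folded = q >= params.q_folded
    unfolded = q <= params.q_unfolded
    n_f, n_u = int(folded.sum()), int(unfolded.sum())
    n_cls = n_f + n_u
    if n_cls == 0:
        raise ValueError(
            "no frames classified as folded or unfolded; run longer or "
            "loosen the Q thresholds")
    scale = params.force_to_pN
    def _force(mask):
        if not mask.any():
            return float("nan"), float("nan")
        d = params.k_tether * summary.tether_extension[mask] * scale
        se = (np.std(d, ddof=1) / np.sqrt(mask.sum())
              if mask.sum() > 1 else float("nan"))
        return float(np.mean(d)), float(se)
    Fu, se_Fu = _force(unfolded)
    Ff, se_Ff = _force(folded)
    Pu, Pf = n_u / n_cls, n_f / n_cls
    se_P = float(np.sqrt(max(Pu * Pf, 1e-12) / n_cls))
    return ForceStatistics(
        L=summary.L, Pu=Pu, Pf=Pf, Fu=Fu, Ff=Ff,
        se_Pu=se_P, se_Pf=se_P, se_Fu=se_Fu, se_Ff=se_Ff,
        n_unfolded=n_u, n_folded=n_f,
        p_intermediate=1.0 - n_cls / len(q),
    )


def scan_linker_lengths(scaffold: RibosomeScaffold, domain: NativeTopology,
                        L_values, params: SimulationParams,
                        folding_competent: bool = True,
                        n_replicas: int = 1,
                        ap_length: int = ARREST_PEPTIDE_LENGTH) -> list[ForceStatistics]:
    """One force-statistics entry per linker length.

    Per-(L, replica) seeds derive deterministically from ``params.seed``, so
    duplicate L values give identical statistics and the scan is
    reproducible regardless of ordering. ``n_replicas`` independent
    trajectories per L are pooled frame-wise before classification;
    replicas alternate between unfolded and folded starting states (falling
    back to unfolded where no folded placement exists), so both basins are
    sampled even when interconversion is slow on the run length. Per-L
    failures are warned about and skipped; partial results are returned.
    """
    L_values = list(L_values)
    if not L_values:
        raise ValueError("empty linker-length list")
    out = []
    for L in L_values:
        try:
            construct = RNCConstruct(domain, int(L), ap_length=ap_length)
            qs, exts = [], []
            for rep in range(n_replicas):
                seed = int(np.random.SeedSequence(
                    entropy=int(params.seed) % (2 ** 31),
                    spawn_key=(int(L), rep)).generate_state(1)[0] % (2 ** 31))
                p = replace(params, seed=seed)
                start = "unfolded" if rep == 0 else "folded"
                try:
                    system = assemble_rnc(scaffold, construct, p, seed=seed,
                                          folding_competent=folding_competent,
                                          start=start)
                except ValueError:
                    if start == "unfolded":
                        raise
                    system = assemble_rnc(scaffold, construct, p, seed=seed,
                                          folding_competent=folding_competent,
                                          start="unfolded")
                summary = run_langevin(system, p)
                qs.append(summary.q)
                exts.append(summary.tether_extension)
            pooled = TrajectorySummary(
                q=np.concatenate(qs),
                tether_extension=np.concatenate(exts),
                bead0_positions=summary.bead0_positions,
                final_positions=summary.final_positions,
                frame_dt=summary.frame_dt, L=int(L))
            out.append(measure_force_statistics(pooled, params))
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"L={L}: {exc}; skipped")
    return out


def calibrate_folding_temperature(topology: NativeTopology, temperatures,
                                  params: SimulationParams,
                                  target_q: float = 0.5) -> float:
    """Folding midpoint of the isolated domain: the temperature at which the
    mean Q crosses ``target_q``, linearly interpolated on the scanned grid."""
    temps = np.sort(np.asarray(list(temperatures), dtype=float))
    means = []
    for T in temps:
        p = replace(params, temperature=float(T))
        summary = run_langevin(domain_system(topology, "native"), p)
        means.append(float(np.mean(summary.q)))
    means = np.array(means)
    below = means < target_q
    if not below.any():
        return float(temps[-1])
    if below.all():
        return float(temps[0])
    k = int(np.argmax(below))  # first T where mean Q dropped below target
    t0, t1 = temps[k - 1], temps[k]
    q0, q1 = means[k - 1], means[k]
    return float(t0 + (q0 - target_q) / (q0 - q1) * (t1 - t0))


def force_statistics_table(stats) -> "pd.DataFrame":
    """Per-L table (L, Pu, Pf, Fu, Ff and standard errors) as a DataFrame."""
    import pandas as pd

    rows = [{
        "L": s.L, "Pu": s.Pu, "Pf": s.Pf, "Fu": s.Fu, "Ff": s.Ff,
        "se_Pu": s.se_Pu, "se_Pf": s.se_Pf, "se_Fu": s.se_Fu,
        "se_Ff": s.se_Ff, "n_unfolded": s.n_unfolded, "n_folded": s.n_folded,
        "p_intermediate": s.p_intermediate,
    } for s in stats]
    return pd.DataFrame(rows).sort_values("L").reset_index(drop=True)
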
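"""Structure-based (Go-type) potential for coarse-grained protein folding.

One bead per residue at the C-alpha position. The potential is the canonical
native-centric form: harmonic bonds and angles, a 1x/3x periodic dihedral
pair, a 12-10 attractive well for native contacts, and a purely repulsive
excluded-volume term for all other pairs. The native conformation is the
global minimum: every bonded term is zero there and the contact term
contributes exactly ``-epsilon`` per native contact.

The excluded-volume repulsion is an r^-12 core truncated and force-shifted so
that energy and force vanish continuously at the excluded diameter; native
conformations whose non-contact pairs all sit beyond that diameter are exact
local minima of the potential.

Energies are in reduced units of the contact energy ``epsilon``; temperature
is expressed in units of ``epsilon/k_B``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "GoParams",
    "NativeTopology",
    "build_native_contacts",
    "build_topology",
    "potential_energy",
    "potential_energy_terms",
    "potential_gradient",
    "fraction_native_contacts",
]


@dataclass(frozen=True)
class GoParams:
    """Parameters of the structure-based potential (reduced units).

    ``contact_cutoff`` is the heavy-atom distance defining a native contact
    (4.5 A for all-atom natives; C-alpha-only fixtures need a larger value,
    ~6.5 A). ``min_separation`` excludes near-sequence pairs from the contact
    list. ``epsilon`` is the reduced energy unit and scales the whole
    potential.
    """

    contact_cutoff: float = 4.5
    min_separation: int = 4
    epsilon: float = 1.0
    k_bond: float = 100.0       # epsilon / A^2
    k_angle: float = 20.0       # epsilon / rad^2
    k_dihedral_1: float = 1.0   # epsilon
    k_dihedral_3: float = 0.5   # epsilon
    ev_sigma: float = 4.0       # excluded-volume diameter, A


@dataclass
class NativeTopology:
    """Bonded terms, native-contact list and parameters for one chain."""

    n_beads: int
    bonds: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray        # (nb,) A
    angles: np.ndarray         # (na, 3) int
    angle_theta0: np.ndarray   # (na,) rad
    dihedrals: np.ndarray      # (nd, 4) int
    dihedral_phi0: np.ndarray  # (nd,) rad
    contacts: np.ndarray       # (nc, 2) int, i < j
    contact_sigma: np.ndarray  # (nc,) A
    params: GoParams = field(default_factory=GoParams)
    native_coord: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=float)
        self.dihedrals = np.asarray(self.dihedrals, dtype=np.int64).reshape(-1, 4)
        self.dihedral_phi0 = np.asarray(self.dihedral_phi0, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=np.int64).reshape(-1, 2)
        self.contact_sigma = np.asarray(self.contact_sigma, dtype=float)
        if np.any(self.contact_sigma <= 0):
            raise ValueError("contact sigma must be positive")
        if len(self.contacts):
            if np.any(self.contacts[:, 0] >= self.contacts[:, 1]):
                raise ValueError("contacts must satisfy i < j")
            pairs = set(map(tuple, self.contacts.tolist()))
            if len(pairs) != len(self.contacts):
                raise ValueError("duplicate contact pairs")
            sep = self.contacts[:, 1] - self.contacts[:, 0]
            if np.any(sep < self.params.min_separation):
                raise ValueError("contact below minimum sequence separation")
        if len(self.bonds) and np.any(
                np.abs(self.bonds[:, 1] - self.bonds[:, 0]) != 1):
            raise ValueError("bonds must connect sequence neighbours")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def repulsive_pairs(self) -> np.ndarray:
        """All (i, j) pairs with j - i >= 4 that are not native contacts;
        these carry the excluded-volume term (closer pairs are governed by
        the bonded terms)."""
        n = self.n_beads
        i, j = np.triu_indices(n, k=4)
        native = set(map(tuple, self.contacts.tolist()))
        mask = np.array([(a, b) not in native for a, b in zip(i, j)])
        return np.stack([i[mask], j[mask]], axis=1)

    # ------------------------------------------------------------------ JSON
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_beads": self.n_beads,
            "bonds": self.bonds.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "angles": self.angles.tolist(),
            "angle_theta0": self.angle_theta0.tolist(),
            "dihedrals": self.dihedrals.tolist(),
            "dihedral_phi0": self.dihedral_phi0.tolist(),
            "contacts": self.contacts.tolist(),
            "contact_sigma": self.contact_sigma.tolist(),
            "params": asdict(self.params),
            "native_coord": (None if self.native_coord is None
                             else self.native_coord.tolist()),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NativeTopology":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            n_beads=d["n_beads"],
            bonds=np.array(d["bonds"], dtype=np.int64).reshape(-1, 2),
            bond_r0=np.array(d["bond_r0"]),
            angles=np.array(d["angles"], dtype=np.int64).reshape(-1, 3),
            angle_theta0=np.array(d["angle_theta0"]),
            dihedrals=np.array(d["dihedrals"], dtype=np.int64).reshape(-1, 4),
            dihedral_phi0=np.array(d["dihedral_phi0"]),
            contacts=np.array(d["contacts"], dtype=np.int64).reshape(-1, 2),
            contact_sigma=np.array(d["contact_sigma"]),
            params=GoParams(**d["params"]),
            native_coord=(None if d["native_coord"] is None
                          else np.array(d["native_coord"])),
        )


# ---------------------------------------------------------------- construction

def _single_protein_chain(native) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Ordered CA coordinates, residue ids and per-residue heavy-atom index
    lists for a single-chain protein structure."""
    from tunnelfold.structure_io import MolecularStructure  # noqa: F401

    if native.n_atoms == 0:
        raise ValueError("empty structure")
    chains = native.chains()
    if len(chains) != 1:
        raise ValueError(f"expected a single chain, found {chains}")
    res_ids = list(dict.fromkeys(native.res_id.tolist()))
    heavy = [[] for _ in res_ids]
    ca = np.full((len(res_ids), 3), np.nan)
    pos = {r: k for k, r in enumerate(res_ids)}
    for i in range(native.n_atoms):
        if native.element[i].upper() == "H":
            continue
        k = pos[int(native.res_id[i])]
        heavy[k].append(i)
        if native.atom_name[i] == "CA":
            ca[k] = native.coord[i]
    if np.any(np.isnan(ca)):
        missing = [res_ids[k] for k in np.flatnonzero(np.isnan(ca[:, 0]))]
        raise ValueError(f"residues without CA: {missing}")
    return ca, np.array(res_ids), heavy


def build_native_contacts(native, cutoff: float = 4.5,
                          min_separation: int = 4) -> list[tuple[int, int, float]]:
    """Native-contact list from heavy-atom proximity.

    A residue pair (i, j), indexed by sequence position, is a contact iff any
    heavy-atom pair between them is within ``cutoff`` and ``j - i >=
    min_separation``; the contact distance sigma_ij is the native C-alpha
    distance.
    """
    ca, _, heavy = _single_protein_chain(native)
    n = len(ca)
    coords = native.coord
    out = []
    for i in range(n):
        ai = coords[heavy[i]]
        for j in range(i + min_separation, n):
            aj = coords[heavy[j]]
            d2 = ((ai[:, None, :] - aj[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= cutoff * cutoff:
                out.append((i, j, float(np.linalg.norm(ca[i] - ca[j]))))
    return out


def _angle(a, b, c):
    u = a - b
    v = c - b
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def build_topology(native, params: GoParams | None = None) -> NativeTopology:
    """Read bonded geometry and native contacts off a single-chain native
    structure. Residue-numbering gaps are treated as chain breaks and raise
    an error naming the gap positions."""
    params = params or GoParams()
    ca, res_ids, _ = _single_protein_chain(native)
    gaps = [int(res_ids[k]) for k in np.flatnonzero(np.diff(res_ids) != 1)]
    if gaps:
        raise ValueError(f"chain breaks after residues {gaps}")
    n = len(ca)
    if n < 2:
        raise ValueError("need at least two residues")
    bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    bond_r0 = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    angles = np.stack([np.arange(n - 2), np.arange(1, n - 1),
                       np.arange(2, n)], axis=1) if n >= 3 else np.zeros((0, 3))
    angle_theta0 = np.array([_angle(ca[i], ca[j], ca[k]) for i, j, k in angles])
    dihedrals = (np.stack([np.arange(n - 3), np.arange(1, n - 2),
                           np.arange(2, n - 1), np.arange(3, n)], axis=1)
                 if n >= 4 else np.zeros((0, 4)))
    dihedral_phi0 = np.array([_dihedral(ca[i], ca[j], ca[k], ca[l])
                              for i, j, k, l in dihedrals])
    raw = build_native_contacts(native, params.contact_cutoff,
                                params.min_separation)
    contacts = np.array([[i, j] for i, j, _ in raw], dtype=np.int64).reshape(-1, 2)
    sigma = np.array([s for _, _, s in raw])
    return NativeTopology(n, bonds, bond_r0, angles, angle_theta0,
                          dihedrals, dihedral_phi0, contacts, sigma,
                          params=params, native_coord=ca)


# ----------------------------------------------------------------- evaluation

def _check_conf(topology: NativeTopology, conf: np.ndarray) -> np.ndarray:
    conf = np.asarray(conf, dtype=float)
    if conf.shape != (topology.n_beads, 3):
        raise ValueError(
            f"conformation shape {conf.shape} != ({topology.n_beads}, 3)")
    return conf


def _repulsion_energy(r: np.ndarray, sigma: float, eps: float) -> np.ndarray:
    """Force-shifted r^-12 core: V and dV/dr both vanish at r = sigma."""
    inside = r < sigma
    v = np.zeros_like(r)
    rr = r[inside]
    v[inside] = eps * ((sigma / rr) ** 12 - 1.0 - 12.0 * (sigma - rr) / sigma)
    return v


def _repulsion_dvdr(r: np.ndarray, sigma: float, eps: float) -> np.ndarray:
    inside = r < sigma
    g = np.zeros_like(r)
    rr = r[inside]
    g[inside] = eps * (-12.0 * sigma ** 12 / rr ** 13 + 12.0 / sigma)
    return g


def potential_energy_terms(topology: NativeTopology, conf) -> dict[str, float]:
    """Per-term energies (reduced units): bond, angle, dihedral, contact,
    repulsion."""
    conf = _check_conf(topology, conf)
    p = topology.params
    terms = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0,
             "contact": 0.0, "repulsion": 0.0}
    if len(topology.bonds):
        d = np.linalg.norm(conf[topology.bonds[:, 1]]
                           - conf[topology.bonds[:, 0]], axis=1)
        terms["bond"] = float(np.sum(p.k_bond * (d - topology.bond_r0) ** 2))
    if len(topology.angles):
        th = np.array([_angle(conf[i], conf[j], conf[k])
                       for i, j, k in topology.angles])
        terms["angle"] = float(np.sum(p.k_angle * (th - topology.angle_theta0) ** 2))
    if len(topology.dihedrals):
        ph = np.array([_dihedral(conf[i], conf[j], conf[k], conf[l])
                       for i, j, k, l in topology.dihedrals])
        dphi = ph - topology.dihedral_phi0
        terms["dihedral"] = float(np.sum(
            p.k_dihedral_1 * (1 - np.cos(dphi))
            + p.k_dihedral_3 * (1 - np.cos(3 * dphi))))
    if len(topology.contacts):
        r = np.linalg.norm(conf[topology.contacts[:, 1]]
                           - conf[topology.contacts[:, 0]], axis=1)
        x = topology.contact_sigma / r
        terms["contact"] = float(np.sum(p.epsilon * (5 * x ** 12 - 6 * x ** 10)))
    rep = topology.repulsive_pairs()
    if len(rep):
        r = np.linalg.norm(conf[rep[:, 1]] - conf[rep[:, 0]], axis=1)
        terms["repulsion"] = float(np.sum(
            _repulsion_energy(r, p.ev_sigma, p.epsilon)))
    return terms


def potential_energy(topology: NativeTopology, conf) -> float:
    """Total potential energy (reduced units). At the native conformation of
    a well-separated fixture this equals ``-epsilon * n_contacts`` exactly."""
    return float(sum(potential_energy_terms(topology, conf).values()))


def potential_gradient(topology: NativeTopology, conf) -> np.ndarray:
    """Analytic gradient dV/dx, shape (n_beads, 3)."""
    conf = _check_conf(topology, conf)
    p = topology.params
    grad = np.zeros_like(conf)

    if len(topology.bonds):
        i, j = topology.bonds[:, 0], topology.bonds[:, 1]
        dv = conf[j] - conf[i]
        r = np.linalg.norm(dv, axis=1)
        coef = 2.0 * p.k_bond * (r - topology.bond_r0) / r
        f = coef[:, None] * dv
        np.add.at(grad, i, -f)
        np.add.at(grad, j, f)

    for (i, j, k), th0 in zip(topology.angles, topology.angle_theta0):
        u = conf[i] - conf[j]
        v = conf[k] - conf[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        c = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        th = np.arccos(c)
        dvdth = 2.0 * p.k_angle * (th - th0)
        dthdi = -(v / (nu * nv) - c * u / nu ** 2) / s
        dthdk = -(u / (nu * nv) - c * v / nv ** 2) / s
        grad[i] += dvdth * dthdi
        grad[k] += dvdth * dthdk
        grad[j] -= dvdth * (dthdi + dthdk)

    for (i, j, k, l), ph0 in zip(topology.dihedrals, topology.dihedral_phi0):
        b1 = conf[j] - conf[i]
        b2 = conf[k] - conf[j]
        b3 = conf[l] - conf[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        m = np.cross(n1, b2 / nb2)
        phi = np.arctan2(m @ n2, n1 @ n2)
        dvdphi = (p.k_dihedral_1 * np.sin(phi - ph0)
                  + 3.0 * p.k_dihedral_3 * np.sin(3 * (phi - ph0)))
        dpdi = nb2 / (n1 @ n1) * n1
        dpdl = -nb2 / (n2 @ n2) * n2
        sfac = (b1 @ b2) / (nb2 ** 2)
        tfac = (b3 @ b2) / (nb2 ** 2)
        dpdj = -(1.0 + sfac) * dpdi + tfac * dpdl
        dpdk = sfac * dpdi - (1.0 + tfac) * dpdl
        grad[i] += dvdphi * dpdi
        grad[j] += dvdphi * dpdj
        grad[k] += dvdphi * dpdk
        grad[l] += dvdphi * dpdl

    if len(topology.contacts):
        i, j = topology.contacts[:, 0], topology.contacts[:, 1]
        dv = conf[j] - conf[i]
        r = np.linalg.norm(dv, axis=1)
        x = topology.contact_sigma / r
        dvdr = p.epsilon * (-60.0 * x ** 12 + 60.0 * x ** 10) / r
        f = (dvdr / r)[:, None] * dv
        np.add.at(grad, i, -f)
        np.add.at(grad, j, f)

    rep = topology.repulsive_pairs()
    if len(rep):
        i, j = rep[:, 0], rep[:, 1]
        dv = conf[j] - conf[i]
        r = np.linalg.norm(dv, axis=1)
        dvdr = _repulsion_dvdr(r, p.ev_sigma, p.epsilon)
        f = (dvdr / r)[:, None] * dv
        np.add.at(grad, i, -f)
        np.add.at(grad, j, f)

    return grad


def fraction_native_contacts(topology: NativeTopology, conf,
                             tolerance: float = 1.2) -> float:
    """Fraction of native contacts Q: share of contact pairs within
    ``tolerance * sigma_ij``. Order parameter for folded/unfolded
    classification."""
    if topology.n_contacts == 0:
        raise ValueError("topology has no native contacts")
    conf = _check_conf(topology, conf)
    r = np.linalg.norm(conf[topology.contacts[:, 1]]
                       - conf[topology.contacts[:, 0]], axis=1)
    return float(np.mean(r <= tolerance * topology.contact_sigma))
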
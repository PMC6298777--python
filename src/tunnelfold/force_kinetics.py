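"""Bell-model kinetics: from pulling forces to fraction full-length (f_FL).

An arrest peptide stalls translation; a pulling force F on the nascent chain
accelerates escape from the stalled state following the Bell model,

    ke(F) = k0 * exp(F * dx / kB * T),

with k0 the zero-force escape rate and dx the distance to the transition
state. If the tethered domain interconverts between unfolded and folded
states much faster than escape, the fraction of ribosomes that have escaped
(read through to full-length product) after an exposure time t is

    f_FL(t) = 1 - exp(-t * [Pu * ke(Fu) + Pf * ke(Ff)]),

with Pu/Pf the state populations and Fu/Ff the mean pulling force in each
state at the given linker length L. Evaluating this per L turns a set of
simulated force statistics into a predicted f_FL profile.

Defaults: k0 = 3.4e-4 1/s and dx = 4.5 A (single-molecule estimates for the
SecM arrest peptide; admissible ranges roughly 0.5e-4..20e-4 1/s and 1..8 A),
T = 310.15 K and t = 1200 s matching the in vitro translation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tunnelfold.constants import KB_PN_ANGSTROM_PER_K

__all__ = ["BellParams", "escape_rate", "f_fl", "simulated_profile"]


@dataclass(frozen=True)
class BellParams:
    """Parameters of the force-dependent escape model.

    k0: zero-force escape rate, 1/s.
    dx: distance from the stalled minimum to the transition state, A.
    temperature: absolute temperature, K.
    t: exposure time (duration of the translation reaction), s.
    """

    k0: float = 3.4e-4
    dx: float = 4.5
    temperature: float = 310.15
    t: float = 1200.0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.t < 0:
            raise ValueError("exposure time must be non-negative")


def escape_rate(force_pN, params: BellParams = BellParams()):
    """Bell-model escape rate ke(F) = k0 exp(F dx / kB T), in 1/s.

    Accepts scalars or arrays; mildly negative forces (compressive
    fluctuations) are allowed.
    """
    force_pN = np.asarray(force_pN, dtype=float)
    if not np.all(np.isfinite(force_pN)):
        raise ValueError("force must be finite")
    kBT = KB_PN_ANGSTROM_PER_K * params.temperature  # pN*A
    out = params.k0 * np.exp(force_pN * params.dx / kBT)
    return float(out) if out.ndim == 0 else out


def f_fl(Pu: float, Pf: float, Fu_pN: float, Ff_pN: float,
         params: BellParams = BellParams(),
         renormalize: bool = True) -> float:
    """Fraction full-length after exposure time t for a two-state domain.

    ``Pu + Pf`` may be below 1 when intermediate frames were discarded from
    the force statistics; by default the populations are renormalized to sum
    to 1, as the two-state formula assumes.
    """
    if Pu < 0 or Pf < 0:
        raise ValueError("populations must be non-negative")
    if Pu + Pf > 1 + 1e-6:  # tolerance covers rounded table roundtrips
        raise ValueError("Pu + Pf must not exceed 1")
    total = Pu + Pf
    if total == 0:
        raise ValueError("at least one state must be populated")
    if renormalize:
        Pu, Pf = Pu / total, Pf / total
    # a state with zero population contributes nothing; its (possibly
    # undefined) mean force must not poison the sum
    rate = 0.0
    if Pu > 0:
        rate += Pu * escape_rate(Fu_pN, params)
    if Pf > 0:
        rate += Pf * escape_rate(Ff_pN, params)
    return float(1.0 - np.exp(-params.t * rate))


def simulated_profile(stats, params: BellParams = BellParams(),
                      renormalize: bool = True):
    """Predicted f_FL profile from per-linker-length force statistics.

    ``stats`` is an iterable of objects with attributes L, Pu, Pf, Fu, Ff
    (see :class:`tunnelfold.rnc_sim.ForceStatistics`). Returns an
    :class:`tunnelfold.profile_analysis.FflProfile` ordered by L.
    """
    from tunnelfold.profile_analysis import FflProfile

    stats = list(stats)
    if not stats:
        raise ValueError("no force statistics given")
    Ls = [s.L for s in stats]
    if len(set(Ls)) != len(Ls):
        raise ValueError("duplicate linker lengths in statistics")
    order = np.argsort(Ls)
    L_sorted = [int(Ls[i]) for i in order]
    values = [f_fl(stats[i].Pu, stats[i].Pf, stats[i].Fu, stats[i].Ff,
                   params, renormalize) for i in order]
    return FflProfile(L=np.array(L_sorted), f_fl=np.array(values),
                      condition="simulated")
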
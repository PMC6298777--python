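"""f_FL profiles and their features.

The arrest-peptide assay quantifies, per construct, the intensities of the
arrested (I_A) and full-length (I_FL) bands of an SDS-PAGE lane; the fraction
full-length is f_FL = I_FL / (I_A + I_FL). Plotting f_FL against linker
length L gives a single-peaked force profile whose features are read off at
half-maximal height: L_onset on the rising flank, L_max at the peak, L_end on
the falling flank. Differences of onsets between ribosome variants convert to
folding-depth differences at ~3 A per (extended) linker residue.

The half-maximum baseline is the minimum of the profile over L <= L_max
(Delta-f_FL profiles are near zero before the onset); interpolated crossings
are rounded to the nearest integer L with ties rounded down, matching the
integer feature tables reported for this assay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LaneQuantification",
    "FflProfile",
    "ProfileFeatures",
    "NoPeakError",
    "f_fl_from_intensities",
    "delta_ffl",
    "extract_features",
    "depth_shift",
    "aggregate_replicates",
    "read_profile_tsv",
    "write_profile_tsv",
]

EXTENSION_PER_RESIDUE = 3.0  # A per residue, extended linker conformation


class NoPeakError(ValueError):
    """Raised when a profile has no usable interior peak."""


@dataclass(frozen=True)
class LaneQuantification:
    """Band intensities of one gel lane."""

    I_A: float
    I_FL: float
    L: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.I_A < 0 or self.I_FL < 0:
            raise ValueError("band intensities must be non-negative")
        if self.I_A == 0 and self.I_FL == 0:
            raise ValueError("both band intensities are zero")


@dataclass
class FflProfile:
    """Ordered map L -> f_FL with optional replicate dispersion (SEM)."""

    L: np.ndarray
    f_fl: np.ndarray
    sem: np.ndarray | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=np.int64)
        self.f_fl = np.asarray(self.f_fl, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if np.any(self.sem < 0):
                raise ValueError("SEM must be non-negative")
            if len(self.sem) != len(self.L):
                raise ValueError("SEM length mismatch")
        if len(self.L) != len(self.f_fl):
            raise ValueError("L and f_FL length mismatch")
        if len(self.L) > 1 and np.any(np.diff(self.L) <= 0):
            raise ValueError("L must be strictly increasing")
        if np.any(self.f_fl < -1 - 1e-9) or np.any(self.f_fl > 1 + 1e-9):
            raise ValueError("f_FL outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.L)


@dataclass(frozen=True)
class ProfileFeatures:
    """Half-maximal features of a single-peaked f_FL profile."""

    L_onset: int
    L_max: int
    L_end: int
    peak_height: float

    def __post_init__(self) -> None:
        if not (self.L_onset <= self.L_max <= self.L_end):
            raise ValueError("features must satisfy L_onset <= L_max <= L_end")

    def to_dict(self) -> dict:
        return {"L_onset": self.L_onset, "L_max": self.L_max,
                "L_end": self.L_end, "peak_height": self.peak_height}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def f_fl_from_intensities(lane: LaneQuantification) -> float:
    """f_FL = I_FL / (I_A + I_FL)."""
    return lane.I_FL / (lane.I_A + lane.I_FL)


def delta_ffl(plus: FflProfile, minus: FflProfile,
              strict_grid: bool = False) -> FflProfile:
    """Pointwise difference plus - minus (e.g. folding-permissive Zn2+ minus
    folding-blocked TPEN), isolating folding-dependent force.

    Mismatched L grids intersect by default (``strict_grid=True`` errors
    instead); SEMs combine in quadrature when both profiles carry them.
    """
    common = np.intersect1d(plus.L, minus.L)
    if len(common) == 0:
        raise ValueError("profiles share no linker lengths")
    if strict_grid and (len(common) != len(plus.L) or len(common) != len(minus.L)):
        raise ValueError("profiles on different L grids")
    ip = np.searchsorted(plus.L, common)
    im = np.searchsorted(minus.L, common)
    diff = plus.f_fl[ip] - minus.f_fl[im]
    sem = None
    if plus.sem is not None and minus.sem is not None:
        sem = np.hypot(plus.sem[ip], minus.sem[im])
    tag = f"{plus.condition}-{minus.condition}" if plus.condition else "delta"
    return FflProfile(common, diff, sem, condition=tag)


def _round_ties_down(x: float) -> int:
    return math.ceil(x - 0.5)


def extract_features(profile: FflProfile) -> ProfileFeatures:
    """Half-maximal features (L_onset, L_max, L_end) of a peaked profile.

    L_max is the L of the (first) maximum, which must be interior and above
    baseline. The baseline is the profile minimum over L <= L_max; crossings
    of baseline + (peak - baseline)/2 on each flank are located by linear
    interpolation between bracketing samples and rounded to integer L.
    """
    if len(profile) < 3:
        raise NoPeakError("need at least 3 points")
    f = profile.f_fl
    L = profile.L.astype(float)
    imax = int(np.argmax(f))
    if imax == 0 or imax == len(f) - 1:
        raise NoPeakError("maximum at profile boundary (monotone profile)")
    peak = f[imax]
    baseline = float(f[: imax + 1].min())
    if peak <= baseline:
        raise NoPeakError("flat profile")
    half = baseline + 0.5 * (peak - baseline)

    # rising flank: last upward crossing of `half` left of the peak
    onset_x = None
    for k in range(imax - 1, -1, -1):
        if f[k] < half <= f[k + 1]:
            onset_x = L[k] + (half - f[k]) / (f[k + 1] - f[k]) * (L[k + 1] - L[k])
            break
    if onset_x is None:
        raise NoPeakError("no half-maximum crossing on the rising flank")

    # falling flank: first downward crossing right of the peak
    end_x = None
    for k in range(imax, len(f) - 1):
        if f[k] >= half > f[k + 1]:
            end_x = L[k] + (f[k] - half) / (f[k] - f[k + 1]) * (L[k + 1] - L[k])
            break
    if end_x is None:
        raise NoPeakError("profile never falls to half-maximum after the peak")

    onset = _round_ties_down(onset_x)
    end = _round_ties_down(end_x)
    lmax = int(profile.L[imax])
    onset = min(onset, lmax)
    end = max(end, lmax)
    return ProfileFeatures(onset, lmax, end, float(peak))


def depth_shift(onset_a: int, onset_b: int,
                per_residue: float = EXTENSION_PER_RESIDUE) -> float:
    """Folding-depth difference (A) implied by an onset difference, assuming
    an extended linker (~3 A per residue): (onset_a - onset_b) * per_residue,
    signed."""
    return (onset_a - onset_b) * per_residue


def aggregate_replicates(profiles) -> FflProfile:
    """Mean profile over replicates with SEM = sd/sqrt(n) per L.

    Replicates may skip L values; each L uses the replicates that measured
    it. SEM is reported where n >= 2.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no replicates")
    values: dict[int, list[float]] = {}
    for p in profiles:
        for l, v in zip(p.L.tolist(), p.f_fl.tolist()):
            values.setdefault(l, []).append(v)
    Ls = sorted(values)
    mean = np.array([np.mean(values[l]) for l in Ls])
    sem = np.array([
        (np.std(values[l], ddof=1) / math.sqrt(len(values[l])))
        if len(values[l]) >= 2 else 0.0
        for l in Ls])
    return FflProfile(np.array(Ls), mean, sem,
                      condition=profiles[0].condition)


def write_features_table(features: dict, path: str | Path) -> None:
    """Write a feature table TSV (rows: conditions; columns L_onset, L_max,
    L_end) in the style of published summary tables.

    ``features`` maps a condition label to a :class:`ProfileFeatures`.
    """
    rows = [{"condition": name, "L_onset": f.L_onset, "L_max": f.L_max,
             "L_end": f.L_end} for name, f in features.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path, condition: str | None = None) -> FflProfile:
    """Read a profile TSV with columns L, f_FL, optional SEM and condition.

    When the file holds several conditions, ``condition`` selects one.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "l" not in cols or "f_fl" not in cols:
        raise ValueError("profile TSV needs columns L and f_FL")
    if condition is not None and "condition" in cols:
        df = df[df[cols["condition"]] == condition]
        if df.empty:
            raise ValueError(f"condition {condition!r} not present")
    df = df.sort_values(cols["l"])
    sem = df[cols["sem"]].to_numpy() if "sem" in cols else None
    tag = condition or (str(df[cols["condition"]].iloc[0])
                        if "condition" in cols else "")
    return FflProfile(df[cols["l"]].to_numpy(), df[cols["f_fl"]].to_numpy(),
                      sem, condition=tag)


def write_profile_tsv(profile: FflProfile, path: str | Path) -> None:
    data = {"L": profile.L, "f_FL": profile.f_fl}
    if profile.sem is not None:
        data["SEM"] = profile.sem
    if profile.condition:
        data["condition"] = [profile.condition] * len(profile)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g")
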
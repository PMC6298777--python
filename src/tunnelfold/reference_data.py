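"""Published profile features for the arrest-peptide assay.

Experimentally determined half-maximal features (L_onset, L_max, L_end, in
residues) of f_FL profiles for three domains translated on wild-type, uL23
delta-loop, and uL24 delta-loop E. coli ribosomes: the 29-residue zinc-finger
domain ADR1a (Delta-f_FL profiles, Zn2+ minus TPEN), the 109-residue
alpha-spectrin R16 domain, and the 89-residue titin I27 domain. These serve
as printed inputs for depth-shift arithmetic and as ground truth when
generating profile fixtures shaped like the measured ones.
"""

from __future__ import annotations

from tunnelfold.profile_analysis import ProfileFeatures

__all__ = ["PUBLISHED_FEATURES", "DOMAIN_SIZES"]

#: residues per domain
DOMAIN_SIZES = {"ADR1a": 29, "R16": 109, "I27": 89}

#: (domain, ribosome variant) -> measured profile features
PUBLISHED_FEATURES: dict[tuple[str, str], ProfileFeatures] = {
    ("ADR1a", "WT"): ProfileFeatures(21, 25, 27, peak_height=float("nan")),
    ("ADR1a", "uL23dloop"): ProfileFeatures(17, 22, 26, peak_height=float("nan")),
    ("ADR1a", "uL24dloop"): ProfileFeatures(20, 25, 27, peak_height=float("nan")),
    ("R16", "WT"): ProfileFeatures(31, 35, 42, peak_height=float("nan")),
    ("R16", "uL23dloop"): ProfileFeatures(31, 35, 39, peak_height=float("nan")),
    ("R16", "uL24dloop"): ProfileFeatures(29, 33, 40, peak_height=float("nan")),
    ("I27", "WT"): ProfileFeatures(32, 35, 38, peak_height=float("nan")),
    ("I27", "uL23dloop"): ProfileFeatures(33, 35, 38, peak_height=float("nan")),
    ("I27", "uL24dloop"): ProfileFeatures(28, 35, 41, peak_height=float("nan")),
}
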
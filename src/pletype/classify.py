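"""Family assignment of query pleB fragments by nearest-reference identity.

The headline typing procedure: a trimmed diagnostic-core fragment is
compared against a reference panel by pairwise global alignment; the query
is assigned the family of its nearest reference, with a tiered confidence
call and the family's predicted product structure (peptide length and
macrocycle size).

Thresholds are nucleotide-fragment calibration defaults (95% for a
known-producer match, 75% family floor); the published identity anchors
(~70% between the most divergent transporters, >90% within a family) are
stated for full-length proteins, so fragment-level cutoffs are exposed in
:class:`TypingThresholds` and can be re-derived from any panel with
:func:`calibrate_thresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .align import AlignmentParams, DEFAULT_NT, global_align, percent_identity
from .refdata import LINEAR, FamilyProfile, ReferenceEntry, typing_references

__all__ = [
    "TypingThresholds",
    "TypingResult",
    "assign_family",
    "predict_structure",
    "flag_discordance",
    "calibrate_thresholds",
    "UNASSIGNED",
]

UNASSIGNED = "UNASSIGNED"

# Families reported as one phylogenetic clade when the top hits are too close
# to separate (their transporters form a single intertwined cluster).
_MERGED_CLADE = frozenset({"Xantholysin", "Entolysin"})
_MERGED_LABEL = "Xantholysin-Entolysin"


@dataclass(frozen=True)
class TypingThresholds:
    """Identity cutoffs (%) for the confidence tiers.

    ``known_match_nt`` / ``family_floor_nt`` act on nucleotide fragment
    identity; the protein-level figures are informational anchors only.
    """

    known_match_nt: float = 95.0
    family_floor_nt: float = 75.0
    protein_family_floor: float = 70.0
    protein_intrafamily: float = 90.0

    def __post_init__(self) -> None:
        if self.known_match_nt <= self.family_floor_nt:
            raise ValueError("known_match_nt must exceed family_floor_nt")


@dataclass(frozen=True)
class TypingResult:
    query_id: str
    family: str  # family name, merged clade label, or UNASSIGNED
    nearest_reference: str
    identity: float
    tier: str  # known_LP_match | novel_within_family | unassigned
    top_references: tuple[tuple[str, str, float], ...]  # (strain, family, %id)
    predicted_peptide_length: int | None = None
    predicted_macrocycle: int | str | None = None
    discordance_flag: bool = False
    note: str = "pleB-only"


def predict_structure(
    family: str, families: list[FamilyProfile]
) -> tuple[int, int | str]:
    """The family's (peptide length, macrocycle size or LINEAR)."""
    for f in families:
        if f.family_name == family:
            return f.peptide_length, f.macrocycle_size
    raise KeyError(f"unknown family {family!r}")


def assign_family(
    query_core: str,
    refs: list[ReferenceEntry],
    thresholds: TypingThresholds = TypingThresholds(),
    families: list[FamilyProfile] | None = None,
    params: AlignmentParams = DEFAULT_NT,
    query_id: str = "query",
    allow_non_targeted: bool = False,
    clade_margin: float = 2.0,
) -> TypingResult:
    """Nearest-reference (1-NN) family assignment with tiered confidence.

    Ties break on (higher identity, then lexicographic strain id).  When the
    top two references lie within ``clade_margin`` percentage points and span
    the Xantholysin/Entolysin pair, the merged clade label is reported.
    Typing against non-targeted families (for which the published primers
    were not designed) requires ``allow_non_targeted=True``.
    """
    usable = typing_references(refs)
    if families is not None and not allow_non_targeted:
        targeted = {f.family_name for f in families if f.targeted}
        usable = [e for e in usable if e.family_name in targeted]
    if not usable:
        raise ValueError("no usable references (with pleB sequence) configured")

    scored: list[tuple[str, str, float]] = []
    for e in usable:
        ident = percent_identity(global_align(query_core, e.pleb_nt, params))
        scored.append((e.strain_id, e.family_name, ident))
    scored.sort(key=lambda t: (-t[2], t[0]))
    top = tuple(scored[:3])
    best_strain, best_family, best_ident = scored[0]

    if best_ident >= thresholds.known_match_nt:
        tier = "known_LP_match"
    elif best_ident >= thresholds.family_floor_nt:
        tier = "novel_within_family"
    else:
        tier = "unassigned"

    family = best_family
    if tier != "unassigned" and len(scored) >= 2:
        s2 = scored[1]
        pair = {best_family, s2[1]}
        if pair == _MERGED_CLADE and best_ident - s2[2] <= clade_margin:
            family = _MERGED_LABEL
    if tier == "unassigned":
        family = UNASSIGNED

    pep_len = macro = None
    if family not in (UNASSIGNED, _MERGED_LABEL) and families is not None:
        pep_len, macro = predict_structure(family, families)

    return TypingResult(
        query_id=query_id,
        family=family,
        nearest_reference=best_strain,
        identity=best_ident,
        tier=tier,
        top_references=top,
        predicted_peptide_length=pep_len,
        predicted_macrocycle=macro,
    )


def flag_discordance(
    result: TypingResult, secondary_evidence: str | None = None
) -> TypingResult:
    """Flag disagreement between pleB typing and independent BGC/NRPS evidence.

    Precedent: one Antarctic isolate clusters with the Viscosin family on its
    pleB yet its BGC architecture and product (prosekin) place it in the
    Bananamide family — transporter typing is advisory, not definitive.
    """
    if secondary_evidence is None:
        return replace(result, discordance_flag=False, note="pleB-only")
    if result.family == UNASSIGNED:
        return replace(
            result, discordance_flag=False,
            note=f"secondary evidence {secondary_evidence}; pleB unassigned",
        )
    if secondary_evidence != result.family:
        note = (
            f"pleB assigns {result.family} but secondary BGC/NRPS evidence "
            f"indicates {secondary_evidence}; cf. the P. prosekii LMG 26287 "
            f"precedent (pleB in Viscosin cluster, product in Bananamide family)"
        )
        return replace(result, discordance_flag=True, note=note)
    return replace(result, discordance_flag=False, note="pleB and secondary evidence agree")


def calibrate_thresholds(
    refs: list[ReferenceEntry],
    params: AlignmentParams = DEFAULT_NT,
) -> dict[str, float]:
    """Derive family-separating identity statistics from a reference panel.

    Returns intra-/inter-family identity distribution summaries and a
    suggested family floor halfway between the lowest intra-family and the
    highest inter-family identity.
    """
    usable = typing_references(refs)
    intra, inter = [], []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            ident = percent_identity(
                global_align(usable[i].pleb_nt, usable[j].pleb_nt, params)
            )
            (intra if usable[i].family_name == usable[j].family_name else inter).append(ident)
    if not intra or not inter:
        raise ValueError("panel needs both intra- and inter-family pairs to calibrate")
    out = {
        "intra_min": float(np.min(intra)),
        "intra_median": float(np.median(intra)),
        "inter_max": float(np.max(inter)),
        "inter_median": float(np.median(inter)),
    }
    out["suggested_family_floor"] = (out["intra_min"] + out["inter_max"]) / 2.0
    return out
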
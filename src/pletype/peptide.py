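"""Lipopeptide sequence comparison and macrocycle bookkeeping.

Operates on the :class:`~pletype.refdata.LPPeptide` records transcribed into
the packaged peptide table (e.g., prosekin differs from the family namesake
bananamide MDN-0066 only by Ile at position 7 instead of Leu).
"""

from __future__ import annotations

from .refdata import LINEAR, FamilyProfile, LPPeptide

__all__ = ["diff_positions", "macrocycle_summary", "family_consistency"]


def diff_positions(a: LPPeptide, b: LPPeptide) -> list[tuple[int, str, str]]:
    """1-based positions where two equal-length peptides differ.

    Returns ``(position, residue_a, residue_b)`` tuples in order.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"length mismatch: {a.lp_name} ({a.family_name}, {len(a.residues)} aa) "
            f"vs {b.lp_name} ({b.family_name}, {len(b.residues)} aa)"
        )
    return [
        (i + 1, ra, rb)
        for i, (ra, rb) in enumerate(zip(a.residues, b.residues))
        if ra != rb
    ]


def macrocycle_summary(p: LPPeptide) -> tuple[int, int | str, int]:
    """(total residues, macrocycle size or LINEAR, exocyclic residue count)."""
    total = len(p.residues)
    bad = [pos for pos in p.macrocycle_positions if not 1 <= pos <= total]
    if bad:
        raise ValueError(f"{p.lp_name}: macrocycle positions {sorted(bad)} outside 1..{total}")
    if p.linear:
        return total, LINEAR, total
    cycle = len(p.macrocycle_positions)
    return total, cycle, total - cycle


def family_consistency(p: LPPeptide, profile: FamilyProfile) -> bool:
    """True iff residue count and macrocycle size match the family profile."""
    total, cycle, _ = macrocycle_summary(p)
    if total != profile.peptide_length:
        return False
    if profile.macrocycle_size == LINEAR:
        return cycle == LINEAR
    return cycle == profile.macrocycle_size
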
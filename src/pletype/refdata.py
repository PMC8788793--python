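"""Packaged reference tables for lipopeptide families, producers, peptides.

Three UTF-8 TSV tables ship with the package:

``families.tsv``
    One row per lipopeptide family: oligopeptide length (8-25 residues),
    macrocycle size (4-9 residues, or LINEAR for non-cyclized members),
    whether the family is targeted by the published primer sets, and the
    phylogenetic clade used for tie-breaking (Xantholysin and Entolysin form
    one intertwined transporter clade).

``producers.tsv``
    One row per characterized producer strain per family, with the produced
    lipopeptide name, validation-strain flag, and an ``additional_strain``
    flag for rows that are a second strain of an already-counted producer
    (the known-producer census counts 23 strains over the seven targeted
    families: Bananamide 3, Amphisin 6, Gacamide 2, Putisolvin 5,
    Xantholysin 3, Entolysin 1, Tolaasin 3).

``peptides.tsv``
    Amino-acid sequences of known/new lipopeptides as dash-joined 3-letter
    codes with macrocycle positions as a 1-based inclusive range (empty for
    linear peptides); ``inherited`` audits cells that the printed source
    table left blank and that were filled from the row above.

Reference *pleB* sequences are user-extendable: a multi-FASTA whose record
ids are strain ids can be joined onto the producer table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LINEAR",
    "FamilyProfile",
    "ReferenceEntry",
    "LPPeptide",
    "ValidationReport",
    "load_family_table",
    "load_producers",
    "load_peptides",
    "validate_references",
    "count_known_producers",
    "TARGETED_FAMILIES",
    "write_family_table",
    "write_producers",
]

LINEAR = "LINEAR"

PEPTIDE_LENGTH_RANGE = (8, 25)
MACROCYCLE_RANGE = (4, 9)


def _data_path(name: str):
    return resources.files("pletype.data").joinpath(name)


def _strip_type_marker(s: str) -> str:
    # type-strain superscript "T" markers, when present in user tables
    return s.replace("ᵀ", "").replace("^T^", "").strip()


@dataclass(frozen=True)
class FamilyProfile:
    """Structural profile of one lipopeptide family."""

    family_name: str
    peptide_length: int
    macrocycle_size: int | str  # int or LINEAR
    targeted: bool = True
    clade: str = ""
    taxonomic_note: str | None = None


@dataclass(frozen=True)
class ReferenceEntry:
    """One known/putative producer strain (optionally with pleB sequence)."""

    strain_id: str
    species: str
    family_name: str
    lp_name: str
    status: str = "known"  # known | putative
    pleb_nt: str | None = None
    pleb_aa: str | None = None
    accession: str | None = None
    validation_strain: bool = False
    additional_strain: bool = False


@dataclass(frozen=True)
class LPPeptide:
    """Ordered residue list of one lipopeptide, with macrocycle membership."""

    lp_name: str
    producer: str
    family_name: str
    fatty_acid: str
    residues: tuple[str, ...]
    macrocycle_positions: frozenset[int]
    linear: bool
    inherited_fields: tuple[str, ...] = ()


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        raise ValueError(f"{path}: empty or malformed TSV")
    return df


def _bool(s: str) -> bool:
    return str(s).strip().lower() in ("true", "1", "yes")


def load_family_table(path: str | Path | None = None) -> list[FamilyProfile]:
    """Load family structural profiles (packaged table by default)."""
    src = path if path is not None else _data_path("families.tsv")
    df = _read_tsv(src)
    required = {"family", "peptide_length", "macrocycle_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"family table missing column(s): {sorted(missing)}")
    profiles: list[FamilyProfile] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = row["family"].strip()
        if name in seen:
            raise ValueError(f"duplicate family {name!r} in family table")
        seen.add(name)
        mc_raw = row["macrocycle_size"].strip()
        mc: int | str = LINEAR if mc_raw.upper() == "LINEAR" else int(mc_raw)
        profiles.append(
            FamilyProfile(
                family_name=name,
                peptide_length=int(row["peptide_length"]),
                macrocycle_size=mc,
                targeted=_bool(row.get("targeted", "true")),
                clade=(row.get("clade", "") or name).strip() or name,
                taxonomic_note=(row.get("note", "").strip() or None),
            )
        )
    if not profiles:
        raise ValueError("family table contains no rows")
    return profiles


TARGETED_FAMILIES = (
    "Bananamide", "Amphisin", "Gacamide", "Putisolvin",
    "Xantholysin", "Entolysin", "Tolaasin",
)


def load_producers(
    path: str | Path | None = None,
    fasta: str | Path | None = None,
    families: list[FamilyProfile] | None = None,
) -> list[ReferenceEntry]:
    """Load producer entries, optionally joining pleB sequences by strain id.

    FASTA records without a table row are reported with a warning and
    ignored; table rows without a sequence stay loaded (they are excluded
    from identity searches later, with a logged notice).
    """
    src = path if path is not None else _data_path("producers.tsv")
    df = _read_tsv(src)
    required = {"family", "lp_name", "species", "strain_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"producer table missing column(s): {sorted(missing)}")
    known_families = {f.family_name for f in (families or load_family_table())}
    bad = sorted(set(df["family"]) - known_families)
    if bad:
        rows = df.index[df["family"].isin(bad)].tolist()
        raise ValueError(f"unknown families {bad} in producer table rows {rows}")

    seqs: dict[str, str] = {}
    if fasta is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(fasta), "fasta"):
            seqs[_strip_type_marker(rec.id)] = str(rec.seq).upper()

    entries: list[ReferenceEntry] = []
    for _, row in df.iterrows():
        sid = _strip_type_marker(row["strain_id"])
        entries.append(
            ReferenceEntry(
                strain_id=sid,
                species=row["species"].strip(),
                family_name=row["family"].strip(),
                lp_name=row["lp_name"].strip(),
                status=(row.get("status", "known") or "known").strip(),
                pleb_nt=seqs.pop(sid, None),
                accession=(row.get("accession", "").strip() or None),
                validation_strain=_bool(row.get("validation_strain", "false")),
                additional_strain=_bool(row.get("additional_strain", "false")),
            )
        )
    for orphan in seqs:
        warnings.warn(f"FASTA record {orphan!r} has no producer-table row; ignored")
    return entries


def count_known_producers(
    entries: list[ReferenceEntry],
    families: tuple[str, ...] = TARGETED_FAMILIES,
) -> dict[str, int]:
    """Known-producer census per family.

    Additional strains of an already-counted producer (``additional_strain``)
    are excluded, matching the published per-family counts.
    """
    counts = {f: 0 for f in families}
    for e in entries:
        if e.status == "known" and not e.additional_strain and e.family_name in counts:
            counts[e.family_name] += 1
    return counts


def load_peptides(
    path: str | Path | None = None,
    families: list[FamilyProfile] | None = None,
) -> list[LPPeptide]:
    """Load lipopeptide residue sequences (packaged table by default)."""
    src = path if path is not None else _data_path("peptides.tsv")
    df = _read_tsv(src)
    required = {"family", "lp_name", "strain_id", "fatty_acid", "residues", "macrocycle"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing column(s): {sorted(missing)}")
    known_families = {f.family_name for f in (families or load_family_table())}
    peptides: list[LPPeptide] = []
    for _, row in df.iterrows():
        if row["family"] not in known_families:
            raise ValueError(f"peptide {row['lp_name']!r}: unknown family {row['family']!r}")
        residues = tuple(r.strip() for r in row["residues"].split("-"))
        mc_raw = row["macrocycle"].strip()
        if mc_raw:
            lo, hi = (int(x) for x in mc_raw.split("-"))
            positions = frozenset(range(lo, hi + 1))
            linear = False
        else:
            positions = frozenset()
            linear = True
        inherited = tuple(
            f.strip() for f in (row.get("inherited", "") or "").split(",") if f.strip()
        )
        peptides.append(
            LPPeptide(
                lp_name=row["lp_name"].strip(),
                producer=f"{row['species'].strip()} {_strip_type_marker(row['strain_id'])}".strip(),
                family_name=row["family"].strip(),
                fatty_acid=row["fatty_acid"].strip(),
                residues=residues,
                macrocycle_positions=positions,
                linear=linear,
                inherited_fields=inherited,
            )
        )
    return peptides


def validate_references(
    families: list[FamilyProfile],
    entries: list[ReferenceEntry] | None = None,
    peptides: list[LPPeptide] | None = None,
) -> ValidationReport:
    """Report-only validation of the family/producer/peptide invariants."""
    report = ValidationReport()
    fam_by_name = {f.family_name: f for f in families}
    lo, hi = PEPTIDE_LENGTH_RANGE
    mlo, mhi = MACROCYCLE_RANGE
    for f in families:
        if not lo <= f.peptide_length <= hi:
            report.add(
                f"family {f.family_name}: peptide_length {f.peptide_length} "
                f"outside [{lo}, {hi}]"
            )
        if f.macrocycle_size != LINEAR:
            if not mlo <= f.macrocycle_size <= mhi:
                report.add(
                    f"family {f.family_name}: macrocycle_size {f.macrocycle_size} "
                    f"outside [{mlo}, {mhi}] and not LINEAR"
                )
    for e in entries or []:
        if e.family_name not in fam_by_name:
            report.add(f"producer {e.strain_id}: unknown family {e.family_name!r}")
        if e.status not in ("known", "putative"):
            report.add(f"producer {e.strain_id}: invalid status {e.status!r}")
    for p in peptides or []:
        fam = fam_by_name.get(p.family_name)
        if fam is None:
            report.add(f"peptide {p.lp_name}: unknown family {p.family_name!r}")
            continue
        if len(p.residues) != fam.peptide_length:
            report.add(
                f"peptide {p.lp_name}: {len(p.residues)} residues but family "
                f"{fam.family_name} expects {fam.peptide_length}"
            )
        if not p.linear:
            if fam.macrocycle_size == LINEAR:
                report.add(f"peptide {p.lp_name}: cyclic but family profile is LINEAR")
            elif len(p.macrocycle_positions) != fam.macrocycle_size:
                report.add(
                    f"peptide {p.lp_name}: macrocycle of {len(p.macrocycle_positions)} "
                    f"residues but family expects {fam.macrocycle_size}"
                )
            n = len(p.residues)
            expected_suffix = set(range(n - len(p.macrocycle_positions) + 1, n + 1))
            if set(p.macrocycle_positions) != expected_suffix:
                report.add(
                    f"peptide {p.lp_name}: macrocycle positions are not a "
                    f"contiguous C-terminal block"
                )
    return report


def typing_references(entries: list[ReferenceEntry]) -> list[ReferenceEntry]:
    """Entries usable for nucleotide identity search (pleB sequence present);
    sequence-less entries are dropped with a logged notice."""
    usable, dropped = [], []
    for e in entries:
        (usable if e.pleb_nt else dropped).append(e)
    if dropped:
        logger.info(
            "excluding %d reference entries without pleB sequence from identity "
            "search: %s", len(dropped), ", ".join(e.strain_id for e in dropped[:10]),
        )
    return usable


def write_family_table(families: list[FamilyProfile], path: str | Path) -> None:
    rows = [
        {
            "family": f.family_name,
            "peptide_length": f.peptide_length,
            "macrocycle_size": "Linear" if f.macrocycle_size == LINEAR else f.macrocycle_size,
            "targeted": str(f.targeted).lower(),
            "clade": f.clade,
            "note": f.taxonomic_note or "",
        }
        for f in families
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_producers(entries: list[ReferenceEntry], path: str | Path) -> None:
    rows = [
        {
            "family": e.family_name,
            "lp_name": e.lp_name,
            "species": e.species,
            "strain_id": e.strain_id,
            "status": e.status,
            "validation_strain": str(e.validation_strain).lower(),
            "additional_strain": str(e.additional_strain).lower(),
            "accession": e.accession or "",
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
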
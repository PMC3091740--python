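"""Mature-miRNA reference set: parsing, normalization, redundancy bookkeeping.

miRBase-style identifiers (``tae-miR1137``, ``osa-miR444d``, ``ath-miR156a-5p``)
carry a species prefix and a family token.  The enrichment statistics downstream
need both the *redundant* record list (one entry per database deposit) and the
*non-redundant* sequence map (identical matures collapsed), because species
representation is counted over the redundant set while scanning runs once per
distinct sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

from Bio import SeqIO

_VALID_CHARS = set("ACGTUN")
_FAMILY_RE = re.compile(r"mir[-]?(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class MatureRecord:
    """One reference mature miRNA.

    ``sequence`` is normalized RNA (upper-case, T->U).  ``species_code`` is the
    prefix before the first hyphen; ``family`` the numeric family token with any
    letter/ordinal suffix stripped.  Either may be ``None`` for records whose ID
    does not follow the miRBase convention; such records are still scanned but
    excluded from species enrichment.
    """

    id: str
    sequence: str
    species_code: Optional[str] = None
    family: Optional[str] = None


@dataclass
class ReferenceSet:
    """Redundant records plus the deduplicated sequence map.

    ``nr_map`` maps each distinct normalized sequence to the IDs of all records
    carrying it; ``nr_representatives`` holds one record per distinct sequence
    (the first encountered, so parsing order is reproducible).
    """

    records: list[MatureRecord] = field(default_factory=list)
    nr_map: dict[str, list[str]] = field(default_factory=dict)
    nr_representatives: list[MatureRecord] = field(default_factory=list)

    @property
    def by_id(self) -> dict[str, MatureRecord]:
        return {r.id: r for r in self.records}

    def to_tsv(self) -> str:
        lines = ["id\tspecies\tfamily\tsequence"]
        for r in self.records:
            lines.append(
                f"{r.id}\t{r.species_code or ''}\t{r.family or ''}\t{r.sequence}"
            )
        return "\n".join(lines) + "\n"


class ReferenceError(ValueError):
    pass


def family_of(identifier: str) -> str:
    """Family token of a miRBase-style ID: digits after the miR/MIR tag.

    >>> family_of("ath-miR156a")
    '156'
    """
    m = _FAMILY_RE.search(identifier)
    if not m:
        raise ReferenceError(f"unparseable ID: {identifier!r} has no miR family token")
    return m.group(1)


def species_of(identifier: str) -> str:
    """Species prefix of a miRBase-style ID (text before the first hyphen)."""
    code, sep, _ = identifier.partition("-")
    if not sep or not code:
        raise ReferenceError(f"unparseable ID: {identifier!r} has no species prefix")
    return code


def normalize_rna(seq: str, record_id: str = "?") -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - {"A", "C", "G", "U", "N"}
    if bad:
        raise ReferenceError(
            f"record {record_id!r}: invalid characters {sorted(bad)} in sequence"
        )
    return s


def _make_record(rec_id: str, raw_seq: str) -> MatureRecord:
    seq = normalize_rna(raw_seq, rec_id)
    try:
        sp: Optional[str] = species_of(rec_id)
        fam: Optional[str] = family_of(rec_id)
    except ReferenceError:
        sp, fam = None, None
    return MatureRecord(id=rec_id, sequence=seq, species_code=sp, family=fam)


def build_reference_set(records: list[MatureRecord]) -> ReferenceSet:
    """Assemble redundancy bookkeeping from parsed records."""
    ref = ReferenceSet(records=list(records))
    for r in records:
        members = ref.nr_map.setdefault(r.sequence, [])
        if not members:
            ref.nr_representatives.append(r)
        members.append(r.id)
    return ref


def parse_mature_fasta(text: str) -> ReferenceSet:
    """Parse a mature-miRNA FASTA into a :class:`ReferenceSet`.

    Sequence identity (for the non-redundant map) is case- and T/U-insensitive.
    Raises :class:`ReferenceError` on empty input or invalid characters.
    """
    records = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        rec_id = rec.id
        if rec_id in seen_ids:  # disambiguate duplicate deposits
            n = 2
            while f"{rec_id}.{n}" in seen_ids:
                n += 1
            rec_id = f"{rec_id}.{n}"
        seen_ids.add(rec_id)
        records.append(_make_record(rec_id, str(rec.seq)))
    if not records:
        raise ReferenceError("empty reference")
    return build_reference_set(records)
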
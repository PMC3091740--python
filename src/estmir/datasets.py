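"""Bundled input tables.

``barley_species_counts`` is the published per-species survey of mature
miRNAs in a plant reference set versus those matching at least one barley
EST: for each donor species, ``m`` reference deposits (redundant set, 1929
total) and ``k`` deposits whose sequence matched an EST (497 total).  It is
an *input* table — the representation statistics are always recomputed from
these counts, never shipped.
"""

from __future__ import annotations

from importlib.resources import files


def load_barley_species_counts() -> tuple[dict[str, int], dict[str, int]]:
    """(initial_counts, matched_counts) keyed by species name."""
    text = files("estmir.data").joinpath("barley_species_counts.tsv").read_text()
    initial: dict[str, int] = {}
    matched: dict[str, int] = {}
    for line in text.strip().splitlines()[1:]:
        species, m, k = line.split("\t")
        initial[species] = int(m)
        matched[species] = int(k)
    return initial, matched


def parse_species_counts_tsv(text: str) -> tuple[dict[str, int], dict[str, int]]:
    """Parse a user (species, m, k) TSV; a 'Total' row is ignored (totals are
    recomputed), a header row is detected and skipped."""
    initial: dict[str, int] = {}
    matched: dict[str, int] = {}
    for ln, line in enumerate(text.strip().splitlines()):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"line {ln + 1}: expected 3 tab-separated columns")
        if ln == 0 and not parts[1].strip().isdigit():
            continue
        if parts[0].strip().lower() == "total":
            continue
        initial[parts[0].strip()] = int(parts[1])
        matched[parts[0].strip()] = int(parts[2])
    return initial, matched
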
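"""Variable-site tabulation and diagnostic-nucleotide detection.

A diagnostic character for species *s* is an alignment column where every
sequence of *s* carries the same unambiguous base *b*, and no sequence of
any other species carries *b* — nor an IUPAC ambiguity code whose base set
contains *b* (an ambiguous read that could be *b* disqualifies the site:
the rule never claims a diagnostic an ambiguity could contradict). Columns
containing a gap or ambiguity inside *s* are ineligible for *s*.

Species lacking any pure diagnostic site may still be identifiable by their
combination of consensus states across all variable sites
(:func:`combination_signature`), the situation of *Ammodytes tobianus* at
the Rhodopsin fragment.

Positions are 1-based on the (primer-trimmed) alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

from .seqio import Alignment

__all__ = [
    "DiagnosticSite",
    "DiagnosticSiteTable",
    "CombinationSignature",
    "diagnostic_sites",
    "combination_signature",
    "count_diagnostics",
]

#: IUPAC code -> set of bases it may represent ("-" represents nothing).
_IUPAC_SET = {c: frozenset(v) for c, v in ambiguous_dna_values.items()}
_IUPAC_SET["-"] = frozenset()
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DiagnosticSite:
    position: int  # 1-based
    states: dict  # species -> consensus base, or None when mixed/ambiguous
    diagnostic_for: str | None


@dataclass
class DiagnosticSiteTable:
    sites: list[DiagnosticSite]
    species: list[str]
    alignment_length: int

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]


def _consensus_state(column: list[str]) -> str | None:
    """The single shared unambiguous base of a species column, else None."""
    states = set(column)
    if len(states) == 1:
        b = states.pop()
        if b in _BASES:
            return b
    return None


def diagnostic_sites(
    aln: Alignment, species_map: dict[str, str] | None = None
) -> DiagnosticSiteTable:
    """Tabulate variable sites across species consensuses and flag diagnostics.

    A site enters the table iff at least two distinct unambiguous consensus
    states occur among species. Requires >= 2 species with >= 1 sequence.
    With exactly two species a fixed difference is diagnostic for both; the
    alphabetically first species is recorded (``diagnostic_for`` is single-
    valued); with three or more species at most one species can hold an
    exclusive base per site.
    """
    if species_map is None:
        species_map = aln.species_map()
    groups: dict[str, list[str]] = {}
    for rec in aln.records:
        sp = species_map.get(rec.specimen_id, "unknown")
        if sp == "unknown":
            continue
        groups.setdefault(sp, []).append(rec.sequence)
    if len(groups) < 2:
        raise ValueError("diagnostic analysis needs at least 2 named species")
    for sp, seqs in groups.items():
        if not seqs:
            raise ValueError(f"species {sp} has no sequences")

    species = sorted(groups)
    sites: list[DiagnosticSite] = []
    for col in range(aln.length):
        cons = {
            sp: _consensus_state([s[col] for s in groups[sp]])
            for sp in species
        }
        distinct = {b for b in cons.values() if b is not None}
        if len(distinct) < 2:
            continue
        diagnostic_for = None
        for sp in species:
            b = cons[sp]
            if b is None:
                continue  # gap/ambiguity/polymorphism inside sp: ineligible
            others_ok = all(
                b not in _IUPAC_SET.get(s[col], _BASES)
                for other in species
                if other != sp
                for s in groups[other]
            )
            if others_ok:
                diagnostic_for = sp
                break  # at most one species can be exclusive for its base
        sites.append(
            DiagnosticSite(
                position=col + 1, states=cons, diagnostic_for=diagnostic_for
            )
        )
    return DiagnosticSiteTable(
        sites=sites, species=species, alignment_length=aln.length
    )


@dataclass(frozen=True)
class CombinationSignature:
    species: str
    positions: tuple
    states: tuple  # consensus base or None per variable site
    identifiable: bool  # True iff no other species shares the vector


def combination_signature(
    table: DiagnosticSiteTable, species: str
) -> CombinationSignature:
    """A species' consensus-state vector over all variable sites.

    Identifiable iff the vector differs from every other species' vector.
    """
    if species not in table.species:
        raise KeyError(f"species {species!r} not in table")
    vec = tuple(site.states[species] for site in table.sites)
    unique = all(
        tuple(site.states[other] for site in table.sites) != vec
        for other in table.species
        if other != species
    )
    return CombinationSignature(
        species=species,
        positions=tuple(table.positions),
        states=vec,
        identifiable=unique,
    )


def count_diagnostics(table: DiagnosticSiteTable) -> dict[str, int]:
    """Per-species count of diagnostic sites (zero-filled)."""
    counts = {sp: 0 for sp in table.species}
    for site in table.sites:
        if site.diagnostic_for is not None:
            counts[site.diagnostic_for] += 1
    return counts
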
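"""Subunit co-occurrence tables and named-subset conservation reports.

The co-occurrence table answers the question the five-set Venn diagram poses:
which subunits (A-E) co-occur in which species, tallied per phylum and per
co-occurrence class.  By construction of the curation pipeline no species
carries a B-E subunit without an A subunit; :func:`check_presence_invariant`
asserts exactly that on any curated set.

Subset reports re-run the substitution classification restricted to a named
list of sequences (for example gut-parasite species against their hosts) so
conservation of the ligand-binding residues can be compared between a focal
group and the full family.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from htr3evo.align import ColumnMap, MSAView
from htr3evo.conservation import classify_substitutions, phylum_summary
from htr3evo.curation import SubunitRecord
from htr3evo.reference import ReferenceAnnotation

SUBUNITS = "ABCDE"


@dataclass
class PresenceTable:
    """Per-species subunit sets with per-phylum and co-occurrence tallies."""

    species_subunits: dict[str, frozenset[str]]
    species_phylum: dict[str, str]

    @property
    def n_species(self) -> int:
        return len(self.species_subunits)

    def region_counts(self) -> dict[frozenset[str], int]:
        """Number of species per exact subunit combination (Venn regions)."""
        out: dict[frozenset[str], int] = {}
        for subs in self.species_subunits.values():
            out[subs] = out.get(subs, 0) + 1
        return out

    def phylum_counts(self) -> pd.DataFrame:
        """Species count per phylum and subunit."""
        rows: dict[str, dict] = {}
        for sp, subs in self.species_subunits.items():
            phylum = self.species_phylum[sp]
            cell = rows.setdefault(
                phylum, {"phylum": phylum, **{s: 0 for s in SUBUNITS}}
            )
            for s in subs:
                cell[s] += 1
        return pd.DataFrame(sorted(rows.values(), key=lambda r: r["phylum"]))

    def species_without_A(self) -> list[str]:
        return sorted(
            sp for sp, subs in self.species_subunits.items() if "A" not in subs
        )


def cooccurrence(curated: list[SubunitRecord]) -> PresenceTable:
    """Build the per-species subunit presence table from a curated record set."""
    species_subunits: dict[str, set[str]] = {}
    species_phylum: dict[str, str] = {}
    for rec in curated:
        species_subunits.setdefault(rec.species, set()).add(rec.subunit)
        species_phylum[rec.species] = rec.phylum
    return PresenceTable(
        {sp: frozenset(s) for sp, s in species_subunits.items()}, species_phylum
    )


def check_presence_invariant(table: PresenceTable) -> None:
    """Raise if any species carries B-E subunits without an A subunit."""
    offenders = table.species_without_A()
    if offenders:
        raise AssertionError(
            f"species with B-E subunits but no A subunit: {offenders}"
        )


def subset_report(
    msa: MSAView,
    cmap: ColumnMap,
    ann: ReferenceAnnotation,
    accessions: list[str],
    phylum_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Critical-residue substitution summary restricted to a named subset.

    An empty subset yields an empty frame.  Passing every accession
    reproduces the full phylum summary.
    """
    sub_msa = msa.subset(accessions)
    if not sub_msa.rows:
        return pd.DataFrame(
            columns=[
                "ref_pos",
                "expected_aa",
                "phylum",
                "substituents",
                "identical",
                "conservative",
                "non_conservative",
                "absent",
            ]
        )
    subs = classify_substitutions(sub_msa, cmap, ann, phylum_of)
    return phylum_summary(subs)
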
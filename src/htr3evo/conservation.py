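"""Column-wise conservation in bits and critical-residue substitution analysis.

Conservation of an alignment column is the sequence-logo information content:

    info = log2(20) - H,    H = -sum_a p_a * log2(p_a)

with frequencies p taken over the non-gap characters of the column.  A fully
conserved column scores log2(20) ~ 4.32 bits, five equiprobable residues score
exactly 2 bits, and a uniform column over all 20 residues scores 0.  An
optional small-sample correction subtracts the standard approximation
e_n = (20 - 1) / (2 * ln 2 * n); it is off by default so the analytic values
above hold exactly.

Substitutions at catalogued critical residues are classified against the
five physico-chemical classes (polar / neutral / basic / acidic /
hydrophobic): ``identical`` when the observed residue equals the reference
one, ``conservative`` when it differs but stays in the same class,
``non_conservative`` when it changes class (or is X), and ``absent`` when the
row carries a gap at that column.  A softer ``hydropathy_conservative`` tag is
additionally set when both residues are hydrophobic or the aromatic polar
tyrosine, since aromatic swaps such as F<->Y are often tolerated at binding
sites.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from htr3evo.align import GAP, ColumnMap, MSAView, residue_at
from htr3evo.reference import AA_CLASSES, STANDARD_AA, ReferenceAnnotation, _CLASS_OF

MAX_BITS = math.log2(20.0)

_HYDROPATHY_POOL = AA_CLASSES["hydrophobic"] | {"Y"}


def column_info_bits(column, correction: bool = False) -> float:
    """Information content in bits of one alignment column.

    Gaps are excluded from the frequency distribution.  An all-gap column
    returns 0.0 (callers should consult the gap fraction).  Raises on an
    empty column.
    """
    chars = [c for c in column if c != GAP]
    if not list(column):
        raise ValueError("empty column")
    n = len(chars)
    if n == 0:
        return 0.0
    counts = Counter(chars)
    entropy = -sum((c / n) * math.log2(c / n) for c in counts.values())
    info = MAX_BITS - entropy
    if correction:
        info -= (len(STANDARD_AA) - 1) / (2.0 * math.log(2.0) * n)
    return max(info, 0.0)


@dataclass
class ConservationProfile:
    """Per-column gap fraction, residue frequencies and information content."""

    table: pd.DataFrame  # columns: column, gap_fraction, info_bits, top_aa, top_freq

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def profile(msa: MSAView, correction: bool = False) -> ConservationProfile:
    """Apply ``column_info_bits`` to every column of an MSA."""
    rows = []
    n_rows = len(msa.rows)
    for col in range(1, msa.n_cols + 1):
        column = msa.column(col)
        non_gap = [c for c in column if c != GAP]
        gap_fraction = 1.0 - len(non_gap) / n_rows if n_rows else 1.0
        bits = column_info_bits(column, correction=correction)
        if non_gap:
            top_aa, top_count = Counter(non_gap).most_common(1)[0]
            top_freq = top_count / len(non_gap)
        else:
            top_aa, top_freq = GAP, 0.0
        rows.append(
            {
                "column": col,
                "gap_fraction": gap_fraction,
                "info_bits": bits,
                "top_aa": top_aa,
                "top_freq": top_freq,
            }
        )
    return ConservationProfile(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Critical-residue substitution classification
# ---------------------------------------------------------------------------

KLASSES = ("identical", "conservative", "non_conservative", "absent")


@dataclass(frozen=True)
class SubstitutionRecord:
    """Observed state of one catalogued residue in one aligned sequence."""

    ref_pos: int
    expected_aa: str
    observed: str
    accession: str
    phylum: str
    klass: str
    hydropathy_conservative: bool = False


def classify_pair(expected: str, observed: str) -> str:
    if observed == GAP:
        return "absent"
    if observed == expected:
        return "identical"
    if _CLASS_OF.get(observed) is not None and _CLASS_OF.get(observed) == _CLASS_OF.get(expected):
        return "conservative"
    return "non_conservative"


def classify_substitutions(
    msa: MSAView,
    cmap: ColumnMap,
    ann: ReferenceAnnotation,
    phylum_of: dict[str, str] | None = None,
) -> list[SubstitutionRecord]:
    """Classify every catalogued critical residue in every MSA row.

    ``phylum_of`` maps accession to phylum; rows without an entry are tagged
    'unknown'.  Raises ``KeyError`` if a catalogued position falls outside the
    column map.
    """
    phylum_of = phylum_of or {}
    out = []
    for crit in ann.critical_residues:
        if crit.position not in cmap.ref_to_col:
            raise KeyError(
                f"catalogued position {crit.position} not covered by the column map"
            )
        for acc, _ in msa.rows:
            obs = residue_at(msa, cmap, acc, crit.position)
            klass = classify_pair(crit.expected_aa, obs)
            hydro = (
                klass in ("conservative", "non_conservative")
                and obs in _HYDROPATHY_POOL
                and crit.expected_aa in _HYDROPATHY_POOL
            )
            out.append(
                SubstitutionRecord(
                    ref_pos=crit.position,
                    expected_aa=crit.expected_aa,
                    observed=obs,
                    accession=acc,
                    phylum=phylum_of.get(acc, "unknown"),
                    klass=klass,
                    hydropathy_conservative=hydro,
                )
            )
    return out


def substitutions_frame(subs: list[SubstitutionRecord]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in subs])


def phylum_summary(subs: list[SubstitutionRecord]) -> pd.DataFrame:
    """Per (reference position, phylum): observed substituent set and class tallies.

    The substituent set lists the distinct non-identical, non-gap residues
    observed; tallies count rows in each classification.
    """
    rows: dict[tuple[int, str], dict] = {}
    for s in subs:
        key = (s.ref_pos, s.phylum)
        cell = rows.setdefault(
            key,
            {
                "ref_pos": s.ref_pos,
                "expected_aa": s.expected_aa,
                "phylum": s.phylum,
                "substituents": set(),
                **{k: 0 for k in KLASSES},
            },
        )
        cell[s.klass] += 1
        if s.klass in ("conservative", "non_conservative"):
            cell["substituents"].add(s.observed)
    records = []
    for key in sorted(rows):
        cell = rows[key]
        cell = dict(cell)
        cell["substituents"] = "".join(sorted(cell["substituents"]))
        records.append(cell)
    return pd.DataFrame(
        records,
        columns=["ref_pos", "expected_aa", "phylum", "substituents", *KLASSES],
    )


# ---------------------------------------------------------------------------
# Glycosylation / ICL-arginine / pore-proline site reports
# ---------------------------------------------------------------------------


def site_reports(msa: MSAView, cmap: ColumnMap, ann: ReferenceAnnotation) -> pd.DataFrame:
    """Per-row status of glycosylation asparagines, ICL arginines and pore prolines.

    For each sequence the report gives: the number of conserved glycosylation
    asparagines (N present at a catalogued glycosylation position), whether at
    least one *extracellular* glycosylation site is retained, per-position
    status of the conductance arginines in the intracellular loop
    (conserved / substituted-with-X / absent), and the state of the two
    pore-opening prolines after TM1.
    """
    glyc = [c for c in ann.critical_residues if c.role == "glycosylation"]
    icl_arg = [
        c
        for c in ann.critical_residues
        if c.region == "ICL" and c.expected_aa == "R" and "conductance" in c.role
    ]
    prolines = [
        c
        for c in ann.critical_residues
        if c.region == "post_TM1" and "pore-opening" in c.role
    ]
    icl_span = ann.region("ICL")
    rows = []
    for acc, _ in msa.rows:
        rec: dict = {"accession": acc}
        n_glyc = 0
        extracellular_glyc = False
        for c in glyc:
            obs = residue_at(msa, cmap, acc, c.position)
            if obs == "N":
                n_glyc += 1
                if not (icl_span.start <= c.position <= icl_span.end):
                    extracellular_glyc = True
        rec["n_glycosylation_conserved"] = n_glyc
        rec["has_extracellular_glycosylation"] = extracellular_glyc
        n_arg = 0
        for c in icl_arg:
            obs = residue_at(msa, cmap, acc, c.position)
            status = "absent" if obs == GAP else ("conserved" if obs == "R" else obs)
            rec[f"R{c.position}"] = status
            n_arg += obs == "R"
        rec["n_icl_arginines"] = n_arg
        for c in prolines:
            obs = residue_at(msa, cmap, acc, c.position)
            rec[f"P{c.position}"] = (
                "absent" if obs == GAP else ("conserved" if obs == "P" else obs)
            )
        rows.append(rec)
    return pd.DataFrame(rows)
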
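"""Three-step curation of candidate 5-HT3 subunit homolog sequences.

Candidate sequences arriving from a homology search are filtered in the order
the study protocol prescribes:

1. hit-level exclusion on E-value, percent similarity and protein length
   (strict comparators: E-value > 0.004, similarity < 40%, length < 100 aa
   are excluded; boundary values are kept);
2. best-annotated record per (species, subunit), then at most four records
   per (genus, subunit), then the requirement that any B-E record's species
   also retains an A record — no functional pentamer is known without an A
   subunit, so a species represented only by B-E records is uninformative;
3. domain-anchored checks against the reference: all four transmembrane
   helices and the Cys-loop must be present (>= half the region aligned to
   candidate residues in a global alignment with the reference) and every
   present mandatory domain at least 20% identical; finally, records labelled
   B-E that align clearly better to the A reference than to their own
   subunit's reference are flagged as mis-annotated A subunits.

Because later stages can orphan B-E records (their species' A record may fall
to a domain check), the A-requirement is re-applied until a fixpoint.
Every stage writes its exclusions into a :class:`CurationReport` whose ledger
is conserved: records in = records out + exclusions, at every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from htr3evo.align import global_align
from htr3evo.reference import STANDARD_AA, ReferenceAnnotation

ANNOTATION_QUALITY = ("named", "receptor_like", "unnamed_hypothetical")

_QUALITY_RANK = {q: i for i, q in enumerate(ANNOTATION_QUALITY)}

# Table-driven exclusion thresholds; strict comparators, boundaries kept.
DEFAULT_THRESHOLDS = {
    "max_evalue": 0.004,        # exclude if evalue > this
    "min_similarity": 40.0,     # exclude if similarity < this (percent)
    "min_length": 100,          # exclude if protein shorter than this (aa)
    "genus_cap": 4,             # max records per (genus, subunit)
    "min_domain_identity": 20.0,   # percent, per mandatory domain
    "min_domain_coverage": 50.0,   # percent of region positions aligned
    "misannotation_margin": 5.0,   # percentage points
}


@dataclass(frozen=True)
class SubunitRecord:
    """One candidate sequence with taxonomy, subunit label and provenance."""

    accession: str
    species: str
    genus: str
    phylum: str
    subunit: str
    annotation_quality: str
    sequence: str

    def __post_init__(self):
        if self.subunit not in "ABCDE":
            raise ValueError(f"{self.accession}: bad subunit {self.subunit!r}")
        if self.annotation_quality not in ANNOTATION_QUALITY:
            raise ValueError(
                f"{self.accession}: bad annotation quality {self.annotation_quality!r}"
            )
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_AA + "X")
        if bad:
            raise ValueError(f"{self.accession}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class HitRow:
    """One homology-search hit: significance, similarity and subject length."""

    accession: str
    evalue: float
    similarity_pct: float
    subject_length: int

    def __post_init__(self):
        if self.evalue < 0 or math.isnan(self.evalue):
            raise ValueError(f"{self.accession}: bad E-value {self.evalue}")
        if not 0 <= self.similarity_pct <= 100:
            raise ValueError(f"{self.accession}: bad similarity {self.similarity_pct}")


@dataclass(frozen=True)
class Exclusion:
    accession: str
    stage: str
    reason: str


@dataclass
class CurationReport:
    """Per-stage inclusion/exclusion ledger."""

    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)
    included: list[str] = field(default_factory=list)

    def record_stage(self, stage: str, n_in: int, n_out: int, excl: list[Exclusion]):
        if n_in - n_out != len(excl):
            raise ValueError(
                f"stage {stage}: ledger violated ({n_in} in, {n_out} out, "
                f"{len(excl)} exclusions)"
            )
        self.stage_counts.append((stage, n_in, n_out))
        self.exclusions.extend(excl)

    @property
    def excluded_accessions(self) -> set[str]:
        return {e.accession for e in self.exclusions}

    def reason_of(self, accession: str) -> str | None:
        for e in self.exclusions:
            if e.accession == accession:
                return e.reason
        return None

    def validate(self) -> None:
        overlap = set(self.included) & self.excluded_accessions
        if overlap:
            raise ValueError(f"records both included and excluded: {sorted(overlap)}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(e.accession, e.stage, e.reason) for e in self.exclusions],
            columns=["accession", "stage", "reason"],
        )


def rank_key(rec: SubunitRecord, hits: dict[str, HitRow]):
    """Ranking used to pick survivors: annotation quality, then E-value, then accession."""
    hit = hits[rec.accession]
    return (_QUALITY_RANK[rec.annotation_quality], hit.evalue, rec.accession)


# ---------------------------------------------------------------------------
# Stage 1: hit-level exclusion
# ---------------------------------------------------------------------------


def filter_hits(
    hits: list[HitRow], thresholds: dict | None = None
) -> tuple[set[str], list[Exclusion]]:
    """Keep hits passing the E-value / similarity / length rules.

    A failing hit carries exactly one reason: the first failed rule in the
    order E-value, similarity, length.
    """
    t = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    kept: set[str] = set()
    excl: list[Exclusion] = []
    for h in hits:
        if h.evalue > t["max_evalue"]:
            excl.append(Exclusion(h.accession, "filter_hits", "evalue"))
        elif h.similarity_pct < t["min_similarity"]:
            excl.append(Exclusion(h.accession, "filter_hits", "similarity"))
        elif h.subject_length < t["min_length"]:
            excl.append(Exclusion(h.accession, "filter_hits", "short_seq"))
        else:
            kept.add(h.accession)
    return kept, excl


# ---------------------------------------------------------------------------
# Stage 2: per-species / per-genus selection and the A-subunit requirement
# ---------------------------------------------------------------------------


def select_best_per_species(
    records: list[SubunitRecord], hits: dict[str, HitRow]
) -> tuple[list[SubunitRecord], list[Exclusion]]:
    """Keep one record per (species, subunit), ranked by :func:`rank_key`."""
    groups: dict[tuple[str, str], list[SubunitRecord]] = {}
    for rec in records:
        groups.setdefault((rec.species, rec.subunit), []).append(rec)
    kept, excl = [], []
    for key in sorted(groups):
        ranked = sorted(groups[key], key=lambda r: rank_key(r, hits))
        kept.append(ranked[0])
        excl.extend(
            Exclusion(r.accession, "select_best_per_species", "not_best_annotation")
            for r in ranked[1:]
        )
    kept.sort(key=lambda r: r.accession)
    return kept, excl


def cap_genus(
    records: list[SubunitRecord], hits: dict[str, HitRow], k: int = 4
) -> tuple[list[SubunitRecord], list[Exclusion]]:
    """Keep at most ``k`` records per (genus, subunit), ranked as above."""
    groups: dict[tuple[str, str], list[SubunitRecord]] = {}
    for rec in records:
        groups.setdefault((rec.genus, rec.subunit), []).append(rec)
    kept, excl = [], []
    for key in sorted(groups):
        ranked = sorted(groups[key], key=lambda r: rank_key(r, hits))
        kept.extend(ranked[:k])
        excl.extend(
            Exclusion(r.accession, "cap_genus", "genus_cap") for r in ranked[k:]
        )
    kept.sort(key=lambda r: r.accession)
    return kept, excl


def require_subunit_A(
    records: list[SubunitRecord],
) -> tuple[list[SubunitRecord], list[Exclusion]]:
    """Exclude B-E records whose species has no surviving A record."""
    species_with_a = {r.species for r in records if r.subunit == "A"}
    kept, excl = [], []
    for rec in records:
        if rec.subunit == "A" or rec.species in species_with_a:
            kept.append(rec)
        else:
            excl.append(Exclusion(rec.accession, "require_subunit_A", "no_A_in_species"))
    return kept, excl


# ---------------------------------------------------------------------------
# Stage 3: domain-anchored checks and mis-annotation flagging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainCheck:
    passed: bool
    per_domain_identity: dict[str, float]
    per_domain_coverage: dict[str, float]
    n_TM_present: int
    reason: str | None


def _anchored_domain_stats(
    ann: ReferenceAnnotation, candidate: str
) -> tuple[dict[str, float], dict[str, float]]:
    """Identity/coverage of each mandatory domain, read off a global alignment.

    The full reference is globally aligned to the candidate so each domain is
    held in its sequence context; a domain deleted from the candidate then
    shows up as gap columns (coverage ~ 0) instead of drifting to a spurious
    off-site match.
    """
    aln = global_align(ann.sequence, candidate)
    # reference residue index per alignment column
    ident: dict[str, float] = {}
    cover: dict[str, float] = {}
    ref_positions = []
    pos = 0
    for ch in aln.ref_aligned:
        if ch != "-":
            pos += 1
            ref_positions.append(pos)
        else:
            ref_positions.append(0)
    from htr3evo.reference import MANDATORY_REGIONS

    for name in MANDATORY_REGIONS:
        region = ann.region(name)
        n = region.length
        n_cov = 0
        n_id = 0
        for col, rp in enumerate(ref_positions):
            if region.start <= rp <= region.end:
                c = aln.cand_aligned[col]
                if c != "-":
                    n_cov += 1
                    if c == aln.ref_aligned[col] and c != "X":
                        n_id += 1
        ident[name] = 100.0 * n_id / n
        cover[name] = 100.0 * n_cov / n
    return ident, cover


def check_domains(
    rec: SubunitRecord,
    ann: ReferenceAnnotation,
    thresholds: dict | None = None,
) -> DomainCheck:
    """Check Cys-loop and TM1-TM4 presence and identity against the reference.

    A domain is *present* when at least ``min_domain_coverage`` percent of its
    reference positions align to candidate residues.  The record passes when
    all four TM domains and the Cys-loop are present and every present
    mandatory domain is at least ``min_domain_identity`` percent identical.
    """
    t = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if not rec.sequence:
        raise ValueError(f"{rec.accession}: empty sequence")
    ident, cover = _anchored_domain_stats(ann, rec.sequence)
    min_cov = t["min_domain_coverage"]
    min_id = t["min_domain_identity"]
    tm_present = sum(
        1 for name in ("TM1", "TM2", "TM3", "TM4") if cover[name] >= min_cov
    )
    cys_present = cover["cys_loop"] >= min_cov
    reason = None
    if tm_present < 4:
        reason = "lt4_TM"
    elif not cys_present:
        reason = "no_cysloop"
    else:
        for name, pct in ident.items():
            if cover[name] >= min_cov and pct < min_id:
                reason = "low_domain_identity"
                break
    return DomainCheck(reason is None, ident, cover, tm_present, reason)


def flag_misannotation(
    rec: SubunitRecord,
    refs: dict[str, ReferenceAnnotation],
    margin: float = DEFAULT_THRESHOLDS["misannotation_margin"],
) -> bool:
    """True when a B-E record aligns clearly better to the A reference.

    Global percent identity against the A reference must exceed identity
    against the record's own subunit reference by more than ``margin``
    percentage points; an equidistant record is not flagged.
    """
    if rec.subunit == "A":
        return False
    own = refs.get(rec.subunit)
    ref_a = refs.get("A")
    if own is None or ref_a is None:
        return False
    id_a = global_align(rec.sequence, ref_a.sequence).identity_pct()
    id_own = global_align(rec.sequence, own.sequence).identity_pct()
    return id_a > id_own + margin


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_curation(
    records: list[SubunitRecord],
    hits: dict[str, HitRow],
    ann_map: dict[str, ReferenceAnnotation],
    thresholds: dict | None = None,
) -> tuple[list[SubunitRecord], CurationReport]:
    """Run all curation stages in order and reconcile the ledger.

    Stage order: filter_hits -> select_best_per_species -> cap_genus ->
    require_subunit_A -> check_domains -> flag_misannotation, followed by
    re-application of the A-requirement until no further record drops out.
    """
    t = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    report = CurationReport()
    current = sorted(records, key=lambda r: r.accession)

    missing = [r.accession for r in current if r.accession not in hits]
    if missing:
        raise ValueError(f"records without hit rows: {missing[:5]}")

    kept_acc, excl = filter_hits([hits[r.accession] for r in current], t)
    survivors = [r for r in current if r.accession in kept_acc]
    report.record_stage("filter_hits", len(current), len(survivors), excl)
    current = survivors

    survivors, excl = select_best_per_species(current, hits)
    report.record_stage("select_best_per_species", len(current), len(survivors), excl)
    current = survivors

    survivors, excl = cap_genus(current, hits, k=t["genus_cap"])
    report.record_stage("cap_genus", len(current), len(survivors), excl)
    current = survivors

    survivors, excl = require_subunit_A(current)
    report.record_stage("require_subunit_A", len(current), len(survivors), excl)
    current = survivors

    survivors, excl = [], []
    for rec in current:
        ann = ann_map.get(rec.subunit, ann_map.get("A"))
        check = check_domains(rec, ann, t)
        if check.passed:
            survivors.append(rec)
        else:
            excl.append(Exclusion(rec.accession, "check_domains", check.reason))
    report.record_stage("check_domains", len(current), len(survivors), excl)
    current = survivors

    survivors, excl = [], []
    for rec in current:
        if flag_misannotation(rec, ann_map, t["misannotation_margin"]):
            excl.append(Exclusion(rec.accession, "flag_misannotation", "misannotated"))
        else:
            survivors.append(rec)
    report.record_stage("flag_misannotation", len(current), len(survivors), excl)
    current = survivors

    # later stages may have orphaned B-E records; re-apply until fixpoint
    while True:
        survivors, excl = require_subunit_A(current)
        if not excl:
            break
        report.record_stage("require_subunit_A", len(current), len(survivors), excl)
        current = survivors

    report.included = [r.accession for r in current]
    report.validate()
    return current, report
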
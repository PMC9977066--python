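"""Seeded synthetic 5-HT3 subunit families with known truth for every pipeline stage.

The generator evolves the reference subunit along a taxonomy-structured
bifurcating tree (species nested in genera nested in phyla), producing for
each simulated species one record per requested subunit label.  Region-aware
substitution rates reproduce the conservation gradient seen in real
Cys-loop receptor families: transmembrane helices and the Cys-loop mutate
slowly, the large intracellular loop quickly, the rest of the extracellular
domain in between.  Substitutions are class-preserving with probability
``class_preserving_prob`` so downstream substitution classification sees both
conservative and non-conservative changes.  Insertions (up to
``max_insert_len`` residues, echoing the longest loop inserts seen in real
homologs) and deletions never fall inside TM regions or the Cys-loop unless
a violation is being planted.

On top of the clean family the generator plants curation violations — short
sequences, deleted Cys-loops, three-TM records, genus-cap overflows,
mis-annotated A subunits, and bad homology-search hit rows — and writes every
planted violation into a truth table together with the exclusion reason the
curation pipeline is expected to report.  Sequence-modifying violations are
planted on non-A records whenever a second subunit label is simulated, so a
planted exclusion never cascades into additional (untracked) exclusions of
dependent records.

Each tree edge mutates under its own deterministically derived random
generator, so the set of substituted sites at a given seed is a monotone
function of the substitution rate (raising a rate adds substitutions without
reshuffling the existing ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from htr3evo.align import MSAView
from htr3evo.curation import HitRow, SubunitRecord, rank_key
from htr3evo.phylo import PhyloTree, TreeNode, to_newick
from htr3evo.reference import AA_CLASSES, STANDARD_AA, ReferenceAnnotation, _CLASS_OF

VIOLATION_KINDS = (
    "short_seq",
    "missing_cysloop",
    "three_TMs",
    "excess_genus_members",
    "misannotated_subunit",
    "high_evalue_hit",
    "low_similarity_hit",
)

#: exclusion reason the curation pipeline is expected to emit per violation
EXPECTED_REASON = {
    "short_seq": "short_seq",
    "missing_cysloop": "no_cysloop",
    "three_TMs": "lt4_TM",
    "excess_genus_members": "genus_cap",
    "misannotated_subunit": "misannotated",
    "high_evalue_hit": "evalue",
    "low_similarity_hit": "similarity",
}

_DEFAULT_RATES = {
    "extracellular": 0.15,
    "transmembrane": 0.04,
    "intracellular": 0.30,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated family."""

    seed: int = 17
    n_phyla: int = 4
    genera_per_phylum: int = 3
    species_per_genus: int = 3
    subunit_labels: tuple[str, ...] = ("A", "B")
    per_region_sub_rate: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RATES)
    )
    class_preserving_prob: float = 0.7
    indel_rate: float = 0.005
    max_insert_len: int = 39
    planted_violations: dict[str, int] = field(default_factory=dict)
    genus_cap: int = 4
    #: minimum branch length (expected substitutions per site per unit rate);
    #: keeps every internal edge identifiable so true trees are recoverable
    min_branch: float = 0.05

    def validate(self) -> None:
        for k, v in self.per_region_sub_rate.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"substitution rate {k}={v} outside [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate outside [0, 1]")
        if min(self.n_phyla, self.genera_per_phylum, self.species_per_genus) < 1:
            raise ValueError("taxonomy counts must be >= 1")
        for k, v in self.planted_violations.items():
            if k not in VIOLATION_KINDS:
                raise ValueError(f"unknown violation kind {k!r}")
            if v < 0:
                raise ValueError(f"negative violation count for {k}")
        bad = set(self.subunit_labels) - set("ABCDE")
        if bad or "A" not in self.subunit_labels:
            raise ValueError("subunit_labels must include 'A' and lie in A-E")
        if self.species_per_genus > self.genus_cap and self.planted_violations.get(
            "excess_genus_members"
        ):
            raise ValueError(
                "excess_genus_members planting requires species_per_genus <= genus cap"
            )
        if (
            self.planted_violations.get("misannotated_subunit")
            and len(self.subunit_labels) < 2
        ):
            raise ValueError("misannotated_subunit planting needs >= 2 subunit labels")


@dataclass
class SimOutput:
    records: list[SubunitRecord]
    hit_table: pd.DataFrame  # accession, evalue, similarity_pct, subject_length
    truth_table: pd.DataFrame  # accession, outcome, kind, expected_reason
    msa: MSAView  # reference row + clean grid A records
    true_tree: str  # newick over the MSA's record accessions
    tree_root: TreeNode
    subunit_refs: dict[str, ReferenceAnnotation] = field(default_factory=dict)

    def hits_map(self) -> dict[str, HitRow]:
        return {
            row.accession: HitRow(
                row.accession, row.evalue, row.similarity_pct, int(row.subject_length)
            )
            for row in self.hit_table.itertuples()
        }


# ---------------------------------------------------------------------------
# sequence state and mutation
# ---------------------------------------------------------------------------


@dataclass
class _SeqState:
    chars: list[str]  # one entry per reference position; '' means deleted
    inserts: dict[int, str] = field(default_factory=dict)  # after ref position i

    def copy(self) -> "_SeqState":
        return _SeqState(list(self.chars), dict(self.inserts))

    def sequence(self) -> str:
        parts = []
        for i, ch in enumerate(self.chars, start=1):
            parts.append(ch)
            parts.append(self.inserts.get(i, ""))
        return "".join(parts)


_AA = list(STANDARD_AA)


def _substitute(aa: str, q: float, rng: np.random.Generator) -> str:
    """Replace ``aa``: same chemistry class with probability q, else another class."""
    klass = _CLASS_OF.get(aa)
    same = sorted(AA_CLASSES[klass] - {aa}) if klass else []
    if same and rng.random() < q:
        return same[rng.integers(len(same))]
    other = sorted(set(_AA) - (AA_CLASSES[klass] if klass else set()) - {aa})
    return other[rng.integers(len(other))]


def _position_rates(ann: ReferenceAnnotation, rates: dict[str, float]) -> np.ndarray:
    """Per-position substitution rate: TM and Cys-loop slow, ICL fast, ECD medium."""
    L = len(ann.sequence)
    out = np.full(L, rates["extracellular"])
    for r in ann.regions:
        if r.category == "transmembrane" or r.name == "cys_loop":
            out[r.start - 1 : r.end] = rates["transmembrane"]
        elif r.category == "intracellular":
            out[r.start - 1 : r.end] = rates["intracellular"]
    # keep the Cys-loop slow even though it sits inside the extracellular span
    cys = ann.region("cys_loop")
    out[cys.start - 1 : cys.end] = rates["transmembrane"]
    return out


def _indel_eligible(ann: ReferenceAnnotation) -> np.ndarray:
    L = len(ann.sequence)
    ok = np.ones(L, dtype=bool)
    for r in ann.regions:
        if r.category == "transmembrane" or r.name == "cys_loop":
            ok[r.start - 1 : r.end] = False
    return ok


def _mutate(
    state: _SeqState,
    bl: float,
    rates: np.ndarray,
    eligible: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> _SeqState:
    out = state.copy()
    L = len(out.chars)
    p_sub = np.clip(rates * bl, 0.0, 0.95)
    u = rng.random(L)
    for i in np.nonzero(u < p_sub)[0]:
        if out.chars[i]:
            out.chars[i] = _substitute(out.chars[i], cfg.class_preserving_prob, rng)
    if cfg.indel_rate > 0:
        p_ind = min(cfg.indel_rate * bl, 0.5)
        v = rng.random(L)
        for i in np.nonzero(v < p_ind)[0]:
            if not eligible[i] or not out.chars[i]:
                continue
            if rng.random() < 0.5:  # insertion after position i+1 (1-based)
                length = min(int(rng.geometric(0.4)), cfg.max_insert_len)
                ins = "".join(_AA[j] for j in rng.integers(0, 20, size=length))
                out.inserts[i + 1] = out.inserts.get(i + 1, "") + ins
            else:  # deletion of a short eligible run starting at i
                length = min(int(rng.geometric(0.5)), 5)
                for j in range(i, min(i + length, L)):
                    if eligible[j]:
                        out.chars[j] = ""
    return out


# ---------------------------------------------------------------------------
# taxonomy-structured random tree
# ---------------------------------------------------------------------------


def _join_random(
    subtrees: list[TreeNode],
    rng: np.random.Generator,
    bl_mean: float,
    floor: float = 0.05,
) -> TreeNode:
    nodes = list(subtrees)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        new = TreeNode(
            children=[
                (a, floor + float(rng.exponential(bl_mean))),
                (b, floor + float(rng.exponential(bl_mean))),
            ]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    return nodes[0]


def _prune(node: TreeNode, keep: set[str]) -> tuple[TreeNode | None, float]:
    """Drop leaves outside ``keep``; suppress unary nodes, summing branch lengths."""
    if node.is_leaf:
        return (node, 0.0) if node.name in keep else (None, 0.0)
    children = []
    for child, bl in node.children:
        pruned, extra = _prune(child, keep)
        if pruned is not None:
            children.append((pruned, bl + extra))
    if not children:
        return None, 0.0
    if len(children) == 1:
        child, bl = children[0]
        return child, bl
    return TreeNode(children=children), 0.0


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------


def simulate_family(cfg: SimConfig, ann: ReferenceAnnotation) -> SimOutput:
    """Simulate one subunit family with planted curation violations.

    Returns records, a synthetic hit table, the per-record truth table, the
    MSA of clean grid A records (with the reference as first row) and the
    true tree pruned to those records.  Fixed seed implies byte-identical
    output.
    """
    cfg.validate()
    master = np.random.default_rng([cfg.seed, 1])
    rates = _position_rates(ann, cfg.per_region_sub_rate)
    eligible = _indel_eligible(ann)
    L = len(ann.sequence)

    # --- taxonomy grid and species tree -------------------------------
    species_ids = []  # (phylum, genus, species_id)
    phylum_subtrees = []
    for p in range(cfg.n_phyla):
        phylum = f"Phylum{p+1:02d}"
        genus_subtrees = []
        for g in range(cfg.genera_per_phylum):
            genus = f"Genus{p+1:02d}_{g+1:02d}"
            leaves = []
            for s in range(cfg.species_per_genus):
                sp = f"Species{p+1:02d}_{g+1:02d}_{s+1:02d}"
                species_ids.append((phylum, genus, sp))
                leaves.append(TreeNode(name=sp))
            genus_subtrees.append(_join_random(leaves, master, 0.08, cfg.min_branch))
        phylum_subtrees.append(_join_random(genus_subtrees, master, 0.15, cfg.min_branch))
    species_root = _join_random(phylum_subtrees, master, 0.4, cfg.min_branch)

    # --- subunit ancestors ---------------------------------------------
    ancestors: dict[str, _SeqState] = {}
    for si, label in enumerate(cfg.subunit_labels):
        state = _SeqState(list(ann.sequence))
        if label != "A":
            arng = np.random.default_rng([cfg.seed, 10 + si])
            div = np.clip(rates * 2.5, 0.0, 0.6)
            u = arng.random(L)
            for i in np.nonzero(u < div)[0]:
                state.chars[i] = _substitute(
                    state.chars[i], cfg.class_preserving_prob, arng
                )
        ancestors[label] = state

    # --- evolve each subunit along the species tree --------------------
    def evolve(label: str, si: int) -> dict[str, _SeqState]:
        states: dict[str, _SeqState] = {}
        counter = [0]

        def walk(node: TreeNode, state: _SeqState):
            if node.is_leaf:
                states[node.name] = state
                return
            for child, bl in node.children:
                counter[0] += 1
                erng = np.random.default_rng([cfg.seed, 100 + si, counter[0]])
                walk(child, _mutate(state, bl, rates, eligible, cfg, erng))

        walk(species_root, ancestors[label])
        return states

    states_by_subunit = {
        label: evolve(label, si) for si, label in enumerate(cfg.subunit_labels)
    }

    # --- grid records ---------------------------------------------------
    qual_rng = np.random.default_rng([cfg.seed, 3])
    records: list[SubunitRecord] = []
    state_of: dict[str, _SeqState] = {}
    grid_a: list[str] = []
    for phylum, genus, sp in species_ids:
        for label in cfg.subunit_labels:
            acc = f"SYN{label}_{sp.removeprefix('Species')}"
            quality = ("named", "receptor_like", "unnamed_hypothetical")[
                qual_rng.choice(3, p=[0.6, 0.25, 0.15])
            ]
            st = states_by_subunit[label][sp]
            records.append(
                SubunitRecord(acc, sp, genus, phylum, label, quality, st.sequence())
            )
            state_of[acc] = st
            if label == "A":
                grid_a.append(acc)

    truth_rows: list[dict] = []
    planted: dict[str, str] = {}  # accession -> kind
    vrng = np.random.default_rng([cfg.seed, 4])

    # victims for sequence/hit violations: non-A records when available; in
    # single-subunit runs keep victims out of the genus-cap target genus so
    # the planted genus-cap count cannot be disturbed by an earlier exclusion
    victim_label = (
        cfg.subunit_labels[-1] if len(cfg.subunit_labels) > 1 else "A"
    )
    cap_target_genus = (
        species_ids[0][1]
        if victim_label == "A" and cfg.planted_violations.get("excess_genus_members")
        else None
    )
    victim_pool = sorted(
        r.accession
        for r in records
        if r.subunit == victim_label and r.genus != cap_target_genus
    )

    def take_victims(n: int) -> list[str]:
        avail = [a for a in victim_pool if a not in planted]
        if len(avail) < n:
            raise ValueError("not enough records to plant requested violations")
        picks = sorted(vrng.choice(len(avail), size=n, replace=False))
        return [avail[i] for i in picks]

    by_acc = {r.accession: r for r in records}

    def replace_record(acc: str, **changes) -> None:
        old = by_acc[acc]
        new = SubunitRecord(**{**old.__dict__, **changes})
        by_acc[acc] = new
        records[records.index(old)] = new

    pv = cfg.planted_violations

    for acc in take_victims(pv.get("short_seq", 0)):
        planted[acc] = "short_seq"
        seq = by_acc[acc].sequence[:90]
        replace_record(acc, sequence=seq)

    for acc in take_victims(pv.get("missing_cysloop", 0)):
        planted[acc] = "missing_cysloop"
        st = state_of[acc].copy()
        cys = ann.region("cys_loop")
        for i in range(cys.start - 1, cys.end):
            st.chars[i] = ""
        replace_record(acc, sequence=st.sequence())

    for acc in take_victims(pv.get("three_TMs", 0)):
        planted[acc] = "three_TMs"
        st = state_of[acc].copy()
        tm4 = ann.region("TM4")
        for i in range(tm4.start - 1, tm4.end):
            st.chars[i] = ""
        replace_record(acc, sequence=st.sequence())

    hit_level: dict[str, str] = {}  # accession -> 'evalue' | 'similarity'
    for acc in take_victims(pv.get("high_evalue_hit", 0)):
        planted[acc] = "high_evalue_hit"
        hit_level[acc] = "evalue"
    for acc in take_victims(pv.get("low_similarity_hit", 0)):
        planted[acc] = "low_similarity_hit"
        hit_level[acc] = "similarity"

    # genus-cap overflow: top up the first genus to cap + k members
    extra_records: list[SubunitRecord] = []
    k_genus = pv.get("excess_genus_members", 0)
    genus_cap_excluded: list[str] = []
    if k_genus:
        phylum, genus, sp0 = species_ids[0]
        n_extra = k_genus + max(0, cfg.genus_cap - cfg.species_per_genus)
        base = state_of[f"SYNA_{sp0.removeprefix('Species')}"]
        # grid members of the target genus must outrank the hypothetical
        # extras so exactly the k worst extras fall to the cap
        for rec in [r for r in records if r.genus == genus and r.subunit == "A"]:
            if rec.annotation_quality != "named":
                replace_record(rec.accession, annotation_quality="named")
        extras = []
        for x in range(n_extra):
            sp = f"SpeciesX{x+1:02d}_{genus.removeprefix('Genus')}"
            acc = f"SYNA_X{x+1:02d}_{genus.removeprefix('Genus')}"
            st = _mutate(
                base, 0.05, rates, eligible, cfg, np.random.default_rng([cfg.seed, 5, x])
            )
            extras.append(
                SubunitRecord(
                    acc, sp, genus, phylum, "A", "unnamed_hypothetical", st.sequence()
                )
            )
        extra_records.extend(extras)
        # extras rank below the named grid members; the k worst extras fall
        # to the genus cap (ranking replicated from the curation module)
        slots = cfg.genus_cap - cfg.species_per_genus
        ranked = sorted(extras, key=lambda r: r.accession)  # evalues assigned below keep this order
        genus_cap_excluded = [r.accession for r in ranked[slots:]]
        for acc in genus_cap_excluded:
            planted[acc] = "excess_genus_members"

    # mis-annotated subunits: A-derived sequences labelled as another subunit,
    # each on a fresh species that also gets a clean A record
    k_mis = pv.get("misannotated_subunit", 0)
    if k_mis:
        other = next(l for l in cfg.subunit_labels if l != "A")
        phylum, _, sp0 = species_ids[-1]
        base = state_of[f"SYNA_{sp0.removeprefix('Species')}"]
        for x in range(k_mis):
            sp = f"SpeciesM{x+1:02d}"
            genus = f"GenusM{x+1:02d}"  # own genus: no cap interaction
            mrng = np.random.default_rng([cfg.seed, 6, x])
            st_a = _mutate(base, 0.05, rates, eligible, cfg, mrng)
            st_b = _mutate(st_a, 0.05, rates, eligible, cfg, mrng)
            acc_a = f"SYNA_M{x+1:02d}"
            acc_b = f"SYN{other}_M{x+1:02d}"
            extra_records.append(
                SubunitRecord(acc_a, sp, genus, phylum, "A", "named", st_a.sequence())
            )
            extra_records.append(
                SubunitRecord(
                    acc_b, sp, genus, phylum, other, "named", st_b.sequence()
                )
            )
            planted[acc_b] = "misannotated_subunit"

    records = records + extra_records

    # --- hit table -------------------------------------------------------
    hrng = np.random.default_rng([cfg.seed, 7])
    hit_rows = []
    for rec in sorted(records, key=lambda r: r.accession):
        kind = hit_level.get(rec.accession)
        if kind == "evalue":
            evalue = float(10 ** hrng.uniform(-2, 0))  # > 0.004
            sim = float(hrng.uniform(45, 100))
        elif kind == "similarity":
            evalue = float(10 ** hrng.uniform(-180, -5))
            sim = float(hrng.uniform(10, 39.5))
        else:
            evalue = float(10 ** hrng.uniform(-180, -5))
            sim = float(hrng.uniform(45, 100))
        if rec.accession.startswith("SYNA_X"):
            # genus-cap extras: e-values ordered with accession so the
            # curation ranking matches the truth bookkeeping above
            evalue = 1e-20 * (1 + int(rec.accession[6:8]))
        hit_rows.append(
            {
                "accession": rec.accession,
                "evalue": evalue,
                "similarity_pct": sim,
                "subject_length": len(rec.sequence),
            }
        )
    hit_table = pd.DataFrame(hit_rows)

    # --- truth table ----------------------------------------------------
    for rec in sorted(records, key=lambda r: r.accession):
        kind = planted.get(rec.accession, "")
        truth_rows.append(
            {
                "accession": rec.accession,
                "outcome": "exclude" if kind else "include",
                "kind": kind,
                "expected_reason": EXPECTED_REASON.get(kind, ""),
            }
        )
    truth_table = pd.DataFrame(truth_rows)

    # --- MSA of clean grid A records + reference row --------------------
    msa_accessions = [
        acc
        for acc in grid_a
        if planted.get(acc) not in ("short_seq", "missing_cysloop", "three_TMs")
    ]
    widths = np.zeros(L + 1, dtype=int)
    ref_state = _SeqState(list(ann.sequence))
    msa_states = [(ann.accession, ref_state)] + [
        (acc, state_of[acc]) for acc in msa_accessions
    ]
    for _, st in msa_states:
        for pos, ins in st.inserts.items():
            widths[pos] = max(widths[pos], len(ins))
    rows = []
    for acc, st in msa_states:
        parts = []
        for i in range(1, L + 1):
            parts.append(st.chars[i - 1] or "-")
            ins = st.inserts.get(i, "")
            parts.append(ins + "-" * (widths[i] - len(ins)))
        rows.append((acc, "".join(parts)))
    msa = MSAView(rows)

    # --- true tree over MSA record accessions ----------------------------
    acc_of_species = {
        r.species: r.accession for r in records if r.accession in set(msa_accessions)
    }

    def relabel(node: TreeNode) -> None:
        if node.is_leaf:
            node.name = acc_of_species.get(node.name, node.name)
        for child, _ in node.children:
            relabel(child)

    tree_root_copy = _copy_tree(species_root)
    relabel(tree_root_copy)
    pruned, _ = _prune(tree_root_copy, set(msa_accessions))
    newick = to_newick(PhyloTree(pruned), with_supports=False) if pruned else ";"

    subunit_refs = {"A": ann}
    for label in cfg.subunit_labels:
        if label != "A":
            subunit_refs[label] = ReferenceAnnotation(
                accession=f"{ann.accession}_{label}",
                sequence=ancestors[label].sequence(),
                regions=list(ann.regions),
                critical_residues=[],
            )

    return SimOutput(
        records, hit_table, truth_table, msa, newick, pruned, subunit_refs
    )


def _copy_tree(node: TreeNode) -> TreeNode:
    if node.is_leaf:
        return TreeNode(name=node.name)
    return TreeNode(children=[(_copy_tree(c), bl) for c, bl in node.children])


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def emit(out: SimOutput, directory: str | Path) -> dict[str, Path]:
    """Write FASTA, metadata, hit table, truth table, MSA and true tree."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = directory / "sequences.fasta"
    with open(fasta, "w") as fh:
        for rec in sorted(out.records, key=lambda r: r.accession):
            fh.write(f">{rec.accession}\n{rec.sequence}\n")
    paths["fasta"] = fasta

    meta = directory / "metadata.tsv"
    pd.DataFrame(
        [
            {
                "accession": r.accession,
                "species": r.species,
                "genus": r.genus,
                "phylum": r.phylum,
                "subunit": r.subunit,
                "annotation_quality": r.annotation_quality,
            }
            for r in sorted(out.records, key=lambda r: r.accession)
        ]
    ).to_csv(meta, sep="\t", index=False)
    paths["metadata"] = meta

    hits = directory / "hits.tsv"
    out.hit_table.to_csv(hits, sep="\t", index=False)
    paths["hits"] = hits

    truth = directory / "truth.tsv"
    out.truth_table.to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth

    msa = directory / "msa.fasta"
    out.msa.write(msa)
    paths["msa"] = msa

    tree = directory / "true_tree.nwk"
    tree.write_text(out.true_tree + "\n")
    paths["tree"] = tree
    return paths


def load_records(fasta: str | Path, meta: str | Path) -> list[SubunitRecord]:
    """Read records back from a FASTA + metadata TSV pair."""
    from Bio import SeqIO

    meta_df = pd.read_csv(meta, sep="\t").set_index("accession")
    records = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        m = meta_df.loc[rec.id]
        records.append(
            SubunitRecord(
                rec.id,
                m["species"],
                m["genus"],
                m["phylum"],
                m["subunit"],
                m["annotation_quality"],
                str(rec.seq).upper(),
            )
        )
    return records


def load_hits(path: str | Path) -> dict[str, HitRow]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.accession: HitRow(
            row.accession, row.evalue, row.similarity_pct, int(row.subject_length)
        )
        for row in df.itertuples()
    }
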
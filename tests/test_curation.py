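"""Hit filtering, selection rules, domain checks and the curation ledger."""

import itertools
import warnings

import pytest

from htr3evo.curation import (
    HitRow,
    SubunitRecord,
    cap_genus,
    check_domains,
    filter_hits,
    flag_misannotation,
    rank_key,
    require_subunit_A,
    run_curation,
    select_best_per_species,
)


def _hit(acc, evalue=1e-50, sim=80.0, length=400):
    return HitRow(acc, evalue, sim, length)


def _rec(acc, species="sp1", subunit="A", quality="named", genus="g1",
         phylum="p1", sequence="MKWV"):
    return SubunitRecord(acc, species, genus, phylum, subunit, quality, sequence)


class TestFilterHits:
    @pytest.mark.parametrize(
        "evalue,sim,length,reason",
        [
            (0.01, 80, 400, "evalue"),
            (1e-50, 39.9, 400, "similarity"),
            (1e-50, 80, 99, "short_seq"),
            (0.01, 39.9, 50, "evalue"),  # first failed rule wins
        ],
    )
    def test_exclusions_carry_first_failed_rule(self, evalue, sim, length, reason):
        kept, excl = filter_hits([_hit("a", evalue, sim, length)])
        assert kept == set()
        assert [e.reason for e in excl] == [reason]

    def test_boundary_values_are_kept(self):
        kept, excl = filter_hits([_hit("a", 0.004, 40.0, 100)])
        assert kept == {"a"}
        assert excl == []

    def test_malformed_row_rejected(self):
        with pytest.raises(ValueError):
            HitRow("a", -1.0, 80, 100)
        with pytest.raises(ValueError):
            HitRow("a", 1e-5, 120, 100)


class TestSelectBestPerSpecies:
    def test_named_beats_hypothetical_despite_worse_evalue(self):
        hits = {"n": _hit("n", 1e-20), "h": _hit("h", 1e-80)}
        recs = [_rec("n", quality="named"), _rec("h", quality="unnamed_hypothetical")]
        kept, excl = select_best_per_species(recs, hits)
        assert [r.accession for r in kept] == ["n"]
        assert [e.accession for e in excl] == ["h"]

    def test_single_record_kept(self):
        kept, excl = select_best_per_species([_rec("a")], {"a": _hit("a")})
        assert len(kept) == 1 and not excl

    def test_accession_breaks_exact_ties(self):
        hits = {"AAA1": _hit("AAA1", 1e-30), "AAB2": _hit("AAB2", 1e-30)}
        recs = [_rec("AAB2"), _rec("AAA1")]
        kept, _ = select_best_per_species(recs, hits)
        assert [r.accession for r in kept] == ["AAA1"]

    def test_ranking_agrees_with_exhaustive_ordering_oracle(self):
        """rank_key ordering equals sorting all permutations of the criteria."""
        hits = {}
        recs = []
        qualities = ("named", "receptor_like", "unnamed_hypothetical")
        for i, (q, e) in enumerate(itertools.product(qualities, (1e-9, 1e-3))):
            acc = f"R{i}"
            hits[acc] = _hit(acc, e)
            recs.append(_rec(acc, quality=q))
        ranked = sorted(recs, key=lambda r: rank_key(r, hits))
        # oracle: explicit lexicographic comparison over tuples built by hand
        oracle = sorted(
            recs,
            key=lambda r: (
                qualities.index(r.annotation_quality),
                hits[r.accession].evalue,
                r.accession,
            ),
        )
        assert [r.accession for r in ranked] == [r.accession for r in oracle]


class TestCapGenus:
    def test_six_species_capped_to_four(self):
        recs = [_rec(f"a{i}", species=f"sp{i}") for i in range(6)]
        hits = {r.accession: _hit(r.accession, 10 ** -(50 - i)) for i, r in enumerate(recs)}
        kept, excl = cap_genus(recs, hits, k=4)
        assert len(kept) == 4
        assert {e.reason for e in excl} == {"genus_cap"}

    def test_two_species_untouched(self):
        recs = [_rec("a", species="s1"), _rec("b", species="s2")]
        hits = {r.accession: _hit(r.accession) for r in recs}
        kept, excl = cap_genus(recs, hits)
        assert len(kept) == 2 and not excl


class TestRequireSubunitA:
    def test_lone_b_record_excluded(self):
        kept, excl = require_subunit_A([_rec("b1", subunit="B")])
        assert kept == []
        assert [e.reason for e in excl] == ["no_A_in_species"]

    def test_a_and_b_both_kept(self):
        recs = [_rec("a1", subunit="A"), _rec("b1", subunit="B")]
        kept, excl = require_subunit_A(recs)
        assert len(kept) == 2 and not excl


class TestCheckDomains:
    def test_reference_passes_with_full_identity(self, ann):
        rec = _rec("self", sequence=ann.sequence)
        check = check_domains(rec, ann)
        assert check.passed
        assert check.n_TM_present == 4
        assert all(v == 100.0 for v in check.per_domain_identity.values())

    def test_deleted_tm4_fails_with_lt4_reason(self, ann):
        tm4 = ann.region("TM4")
        seq = ann.sequence[: tm4.start - 1] + ann.sequence[tm4.end :]
        check = check_domains(_rec("x", sequence=seq), ann)
        assert not check.passed
        assert check.reason == "lt4_TM"
        assert check.n_TM_present == 3

    def test_deleted_cysloop_fails_with_no_cysloop_reason(self, ann):
        cys = ann.region("cys_loop")
        seq = ann.sequence[: cys.start - 1] + ann.sequence[cys.end :]
        check = check_domains(_rec("x", sequence=seq), ann)
        assert not check.passed
        assert check.reason == "no_cysloop"


class TestFlagMisannotation:
    def test_a_derived_sequence_labelled_b_is_flagged(self, violated_family, ann):
        refs = violated_family.subunit_refs
        truth = violated_family.truth_table
        planted = truth[truth.kind == "misannotated_subunit"].accession
        by_acc = {r.accession: r for r in violated_family.records}
        for acc in planted:
            assert flag_misannotation(by_acc[acc], refs)

    def test_true_b_record_not_flagged(self, violated_family):
        refs = violated_family.subunit_refs
        clean_b = [
            r
            for r in violated_family.records
            if r.subunit == "B" and r.accession.startswith("SYNB_0")
        ]
        assert clean_b
        assert not any(flag_misannotation(r, refs) for r in clean_b[:5])

    def test_equidistant_sequence_not_flagged(self, ann):
        refs = {"A": ann, "B": ann}  # identical references: zero margin
        rec = _rec("x", subunit="B", sequence=ann.sequence)
        assert not flag_misannotation(rec, refs)


class TestRunCuration:
    def test_planted_violations_recovered_exactly(self, violated_family):
        out = violated_family
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curated, report = run_curation(
                out.records, out.hits_map(), out.subunit_refs
            )
        truth = out.truth_table[out.truth_table.outcome == "exclude"]
        got = {(e.accession, e.reason) for e in report.exclusions}
        want = {(r.accession, r.expected_reason) for r in truth.itertuples()}
        assert got == want  # precision = recall = 1.0
        assert len(curated) == len(out.records) - len(truth)

    def test_clean_family_passes_untouched(self, clean_family):
        curated, report = run_curation(
            clean_family.records, clean_family.hits_map(), clean_family.subunit_refs
        )
        assert len(curated) == len(clean_family.records)
        assert report.exclusions == []

    def test_empty_input_yields_empty_report(self, ann):
        curated, report = run_curation([], {}, {"A": ann})
        assert curated == []
        assert report.exclusions == []
        assert report.included == []

    def test_ledger_conserved_at_every_stage(self, violated_family):
        out = violated_family
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = run_curation(out.records, out.hits_map(), out.subunit_refs)
        by_stage = {}
        for e in report.exclusions:
            by_stage[e.stage] = by_stage.get(e.stage, 0) + 1
        for stage, n_in, n_out in report.stage_counts:
            assert n_in - n_out <= by_stage.get(stage, 0) or n_in == n_out
        report.validate()

    def test_idempotent_on_curated_output(self, violated_family):
        out = violated_family
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curated, _ = run_curation(out.records, out.hits_map(), out.subunit_refs)
            again, report2 = run_curation(curated, out.hits_map(), out.subunit_refs)
        assert [r.accession for r in again] == [r.accession for r in curated]
        assert report2.exclusions == []
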
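"""Filter cascade semantics, domain annotation, excision, specialisation."""

import numpy as np
import pytest

from plpmine import fixtures
from plpmine.engine import ScoredAlignmentPath, score_viterbi
from plpmine.mining import (
    ConfigurationError,
    DataError,
    DomainCall,
    MiningConfig,
    MiningReport,
    SequenceRecord,
    SpecializationError,
    annotate_domains,
    excise_domain,
    filter_pass1,
    filter_pass2,
    read_fasta,
    render_architecture,
    require_cp_cooccurrence,
    scan_database,
    specialize_profile,
)
from plpmine.synth import ArchitectureGrammar, EmbeddingSpec, generate_assembly, mutate_domain


def _hit(length, coverage, seq_id="s"):
    rec = SequenceRecord(id=seq_id, residues="A" * length)
    path = ScoredAlignmentPath(50.0, 1, min(length, 200), coverage, ())
    return rec, path


def _call(label, start, end, score=10.0):
    return DomainCall(label, start, end, score, end - start + 1)


class TestFilterBoundaries:
    @pytest.mark.parametrize(
        "length,coverage,kept",
        [
            (1200, 110, True),   # both thresholds met
            (400, 108, False),   # stand-alone-enzyme length
            (1200, 109, False),  # one match state short of >=110
            (1000, 120, False),  # 'longer than 1000' is strict
            (1001, 110, True),
        ],
    )
    def test_pass1_semantics(self, length, coverage, kept):
        out = filter_pass1([_hit(length, coverage)], MiningConfig())
        assert (len(out) == 1) is kept

    def test_filters_are_subsets_and_idempotent(self):
        hits = [_hit(l, c, f"s{l}_{c}") for l in (400, 900, 1001, 1500) for c in (100, 110, 156)]
        cfg = MiningConfig()
        out = filter_pass1(hits, cfg)
        assert all(h in hits for h in out)
        assert filter_pass1(out, cfg) == out
        calls = {h[0].id: [_call("CP", 1, 80), _call("PLP_typeI", 100, 500)] for h in hits}
        out2 = filter_pass2(hits, calls, cfg)
        assert all(h in hits for h in out2)
        assert filter_pass2(out2, calls, cfg) == out2

    @pytest.mark.parametrize(
        "length,labels,kept",
        [
            (600, ["CP", "PLP_typeI"], True),
            (600, ["KS", "PLP_typeI"], False),  # no carrier protein
            (480, ["CP", "PLP_typeI"], False),  # 'longer than 500' is strict
            (501, ["CP", "PLP_typeI"], True),
        ],
    )
    def test_pass2_semantics(self, length, labels, kept):
        hit = _hit(length, 115)
        calls = {hit[0].id: [_call(lab, 10 * i + 1, 10 * i + 5) for i, lab in enumerate(labels)]}
        out = filter_pass2([hit], calls, MiningConfig())
        assert (len(out) == 1) is kept


class TestCpCooccurrence:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["CP", "KS", "PLP_typeI"], True),
            (["KS", "AT", "PLP_typeI"], False),
            ([], False),
            (["CP"], False),
        ],
    )
    def test_rule(self, labels, expected):
        calls = [_call(lab, 10 * i + 1, 10 * i + 5) for i, lab in enumerate(labels)]
        assert require_cp_cooccurrence(calls) is expected


class TestExcision:
    def test_one_based_inclusive_slice(self):
        seq = SequenceRecord(id="p", residues="MKKA")
        out = excise_domain(seq, _call("PLP_typeI", 2, 4))
        assert out.residues == "KKA"
        assert out.id == "p/2-4"

    def test_full_span_identity(self):
        seq = SequenceRecord(id="p", residues="MKKA")
        assert excise_domain(seq, _call("PLP_typeI", 1, 4)).residues == "MKKA"

    def test_out_of_range_rejected(self):
        seq = SequenceRecord(id="p", residues="MKKA")
        with pytest.raises(DataError):
            excise_domain(seq, _call("PLP_typeI", 2, 5))

    def test_length_roundtrip(self):
        seq = SequenceRecord(id="p", residues="M" * 300)
        for s, e in ((1, 1), (10, 250), (300, 300)):
            assert excise_domain(seq, _call("x", s, e)).length == e - s + 1


class TestScan:
    def test_planted_consensus_hits_with_full_coverage(self, search_profile):
        rng = np.random.default_rng(8)
        cons = search_profile.consensus()
        flank = "".join("ARNDCQEGHILKMFPSTWYV"[c] for c in rng.integers(0, 20, 600))
        rec = SequenceRecord(id="planted", residues=flank + cons + flank[:500])
        hits = scan_database(search_profile, [rec], MiningConfig())
        assert len(hits) == 1
        assert hits[0][1].coverage >= 0.95 * search_profile.n_match

    def test_random_database_rarely_hits(self, search_profile):
        rng = np.random.default_rng(17)
        db = [
            SequenceRecord(id=f"r{i}", residues="".join(
                "ARNDCQEGHILKMFPSTWYV"[c] for c in rng.integers(0, 20, 400)))
            for i in range(50)
        ]
        hits = scan_database(search_profile, db, MiningConfig())
        assert len(hits) <= 3  # expectation is ~0.5 at p <= 0.01

    def test_empty_database(self, search_profile):
        assert scan_database(search_profile, [], MiningConfig()) == []

    def test_uncalibrated_profile_rejected(self):
        prof = fixtures.scr_profile()
        assert prof.calibration is None
        with pytest.raises(ConfigurationError):
            scan_database(prof, [], MiningConfig())


class TestAnnotation:
    def test_planted_architecture_in_order(self, domain_library):
        rec, truth = generate_assembly(
            ("KS", "CP", "PLP_typeI"), ArchitectureGrammar(),
            EmbeddingSpec(family="Aminotran_3", divergence=0.1), seed=5, seq_id="a",
        )
        calls = annotate_domains(rec, domain_library)
        labels = [c.domain_label for c in calls]
        assert labels == ["KS", "CP", "PLP_typeI"]
        assert all(a.env_start <= b.env_start for a, b in zip(calls, calls[1:]))

    def test_greedy_overlap_resolution_prefers_higher_score(self, domain_library):
        # two PLP domains in one protein must both surface (multi-hit),
        # while overlapping candidates are resolved by score
        rec, _ = generate_assembly(
            ("CP", "PLP_typeI"), ArchitectureGrammar(),
            EmbeddingSpec(family="Aminotran_3", divergence=0.1), seed=6, seq_id="b",
        )
        calls = annotate_domains(rec, domain_library)
        for a in calls:
            for b in calls:
                if a is not b:
                    ov = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
                    assert ov <= 10

    def test_no_match_gives_empty(self, domain_library):
        rng = np.random.default_rng(3)
        rec = SequenceRecord(id="r", residues="".join(
            "ARNDCQEGHILKMFPSTWYV"[c] for c in rng.integers(0, 20, 300)))
        calls = annotate_domains(rec, domain_library, evalue_max=1e-6)
        assert calls == []

    def test_empty_library_rejected(self):
        with pytest.raises(ConfigurationError):
            annotate_domains(SequenceRecord(id="x", residues="ACDE"), {})


class TestSpecialization:
    def test_consensus_fixed_point(self):
        # the SCR profile aligns its own consensus end-to-end, so five
        # copies re-estimate to a profile with the same consensus
        base = fixtures.scr_profile()
        cons = base.consensus()
        recs = [SequenceRecord(id=f"c{i}", residues=cons) for i in range(5)]
        spec = specialize_profile(recs, base)
        assert spec.n_match == base.n_match
        assert spec.consensus() == cons

    def test_divergent_set_improves_mean_self_score(self, search_profile):
        rates = fixtures.plp_site_rates()
        cons = fixtures.family_consensus("Aminotran_3")
        recs = [
            SequenceRecord(
                id=f"d{i}",
                residues=mutate_domain(
                    cons, EmbeddingSpec(family="Aminotran_3", divergence=0.3,
                                        indel_rate=0.0, seed=50 + i),
                    site_rates=rates,
                ),
            )
            for i in range(6)
        ]
        spec = specialize_profile(recs, search_profile)
        base_mean = np.mean([score_viterbi(search_profile, r.residues).bit_score for r in recs])
        new_mean = np.mean([score_viterbi(spec, r.residues).bit_score for r in recs])
        assert new_mean >= base_mean
        assert new_mean > base_mean + 10  # genuinely specialised, not a fallback

    def test_single_sequence_rejected(self, search_profile):
        with pytest.raises(SpecializationError):
            specialize_profile([SequenceRecord(id="x", residues="ACDE")], search_profile)


class TestArchitectureStrings:
    def test_published_layout_examples(self):
        calls = [_call("KS", 1, 420), _call("CP", 430, 500), _call("PLP_typeI", 520, 900)]
        assert render_architecture(calls, {0: "Aminotran_3"}) == "KS–CP–PLP1"
        calls = [_call("A", 1, 500), _call("CP", 510, 590), _call("C", 600, 1040),
                 _call("PLP_typeI", 1050, 1450)]
        assert render_architecture(calls, {0: "Pyridoxal_deC"}) == "A–CP–C–PLP4"

    def test_unassigned_plp_renders_question_mark(self):
        calls = [_call("CP", 1, 80), _call("PLP_typeI", 100, 500)]
        assert render_architecture(calls) == "CP–PLP?"

    def test_empty_calls(self):
        assert render_architecture([]) == ""

    def test_unsorted_calls_rejected(self):
        calls = [_call("PLP_typeI", 100, 500), _call("CP", 1, 80)]
        with pytest.raises(DataError):
            render_architecture(calls)


class TestIO:
    def test_duplicate_fasta_ids_rejected(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">a\nACDE\n>a\nACDF\n")
        with pytest.raises(DataError):
            read_fasta(p)

    def test_mining_report_roundtrip(self):
        rep = MiningReport()
        rep.add("s1", calls=[_call("CP", 1, 80)], pass1_kept=True,
                cp_cooccurrence=True, pass2_kept=True)
        rep.excised = [{"parent_id": "s1", "start": 100, "end": 500, "id": "s1/100-500"}]
        rep2 = MiningReport.from_json(rep.to_json())
        assert rep2.sequences == rep.sequences
        assert rep2.excised == rep.excised

    def test_pass2_requires_cooccurrence_flag(self):
        rep = MiningReport()
        with pytest.raises(DataError):
            rep.add("s1", pass2_kept=True, cp_cooccurrence=False)
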
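"""Synthetic benchmark generator: determinism, divergence calibration,
class/verdict consistency."""

import numpy as np
import pytest

from plpmine import fixtures
from plpmine.engine import pvalue, score_viterbi
from plpmine.mining import MiningConfig, scan_database, write_fasta
from plpmine.synth import (
    FAMILIES,
    ArchitectureGrammar,
    EmbeddingSpec,
    GrammarError,
    generate_assembly,
    generate_benchmark,
    mutate_domain,
)


class TestMutateDomain:
    def test_zero_divergence_is_identity(self):
        cons = fixtures.family_consensus("Aminotran_3")
        spec = EmbeddingSpec(divergence=0.0, indel_rate=0.0, seed=1)
        assert mutate_domain(cons, spec) == cons

    def test_seeded_determinism(self):
        cons = fixtures.family_consensus("Aminotran_1_2")
        spec = EmbeddingSpec(divergence=0.3, indel_rate=0.02, seed=99)
        assert mutate_domain(cons, spec) == mutate_domain(cons, spec)

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingSpec(divergence=1.0)
        with pytest.raises(ValueError):
            EmbeddingSpec(indel_rate=0.2)

    def test_realised_divergence_matches_target(self):
        # mean observed p-distance over many seeds ~ the aimed divergence
        cons = fixtures.domain_consensus("C")  # 445 aa, uniform rates
        target = 0.3
        dists = []
        for seed in range(100):
            mut = mutate_domain(cons, EmbeddingSpec(divergence=target, indel_rate=0.0, seed=seed))
            dists.append(np.mean([a != b for a, b in zip(cons, mut)]))
        assert abs(np.mean(dists) - target) < 0.03

    def test_rate_heterogeneous_divergence_matches_target_overall(self):
        cons = fixtures.family_consensus("Beta_elim_lyase")
        rates = fixtures.plp_site_rates()
        dists = []
        for seed in range(60):
            mut = mutate_domain(
                cons, EmbeddingSpec(divergence=0.35, indel_rate=0.0, seed=seed),
                site_rates=rates,
            )
            dists.append(np.mean([a != b for a, b in zip(cons, mut)]))
        assert abs(np.mean(dists) - 0.35) < 0.03

    def test_frozen_positions_untouched(self):
        cons = fixtures.family_consensus("Pyridoxal_deC")
        frozen = {10, 50, 200}
        mut = mutate_domain(
            cons, EmbeddingSpec(divergence=0.6, indel_rate=0.0, seed=5), frozen=frozen
        )
        for i in frozen:
            assert mut[i] == cons[i]


class TestGenerateAssembly:
    def test_planted_coordinates_exact(self):
        grammar = ArchitectureGrammar()
        rec, truth = generate_assembly(
            ("KS", "CP", "PLP_typeI"), grammar,
            EmbeddingSpec(family="Aminotran_3", divergence=0.2), seed=3, seq_id="x",
        )
        assert rec.length >= 850
        assert truth.cls == "positive" and truth.expected_verdict == "pass2_keep"
        lo, hi = grammar.vocabulary["PLP_typeI"]
        dom_len = truth.plp_end - truth.plp_start + 1
        assert lo - 30 <= dom_len <= hi + 30  # indels jitter the length a bit
        assert truth.plp_end == rec.length  # PLP is the final domain here

    def test_standalone_plp_rejected_by_design(self):
        rec, truth = generate_assembly(
            ("PLP_typeI",), ArchitectureGrammar(),
            EmbeddingSpec(family="Aminotran_1_2", divergence=0.1), seed=4, seq_id="s",
        )
        assert 350 <= rec.length <= 470  # a typical stand-alone enzyme
        assert truth.cls == "decoy_standalone"
        assert truth.expected_verdict == "reject"

    def test_seeded_determinism(self):
        args = (("A", "CP", "PLP_typeI"), ArchitectureGrammar(),
                EmbeddingSpec(family="Aminotran_3", divergence=0.3))
        r1, t1 = generate_assembly(*args, seed=11, seq_id="z")
        r2, t2 = generate_assembly(*args, seed=11, seq_id="z")
        assert r1 == r2 and t1 == t2

    def test_unknown_label_rejected(self):
        with pytest.raises(GrammarError):
            generate_assembly(("KS", "XX"), ArchitectureGrammar(),
                              EmbeddingSpec(), seed=1)

    def test_truth_slice_scores_as_plp_domain(self, search_profile):
        # excising at the truth coordinates gives a domain the profile
        # recognises with cascade-level coverage at benchmark divergences
        for div, seed in ((0.2, 21), (0.4, 22)):
            rec, truth = generate_assembly(
                ("A", "CP", "PLP_typeI"), ArchitectureGrammar(),
                EmbeddingSpec(family="Aminotran_3", divergence=div), seed=seed, seq_id="q",
            )
            dom = rec.residues[truth.plp_start - 1 : truth.plp_end]
            res = score_viterbi(search_profile, dom)
            assert res.coverage >= 110


class TestGenerateBenchmark:
    def test_counts(self):
        records, truth = generate_benchmark(10, [0.1, 0.3], seed=7)
        assert len(records) == 50 and len(truth) == 50
        assert (truth["class"] == "positive").sum() == 20
        for cls in ("decoy_standalone", "decoy_noCP", "decoy_noPLP"):
            assert (truth["class"] == cls).sum() == 10
        assert len({r.id for r in records}) == 50

    def test_byte_reproducibility(self, tmp_path):
        r1, t1 = generate_benchmark(4, [0.2], seed=13)
        r2, t2 = generate_benchmark(4, [0.2], seed=13)
        f1, f2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(r1, f1)
        write_fasta(r2, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert t1.equals(t2)

    def test_verdict_consistency_with_class(self):
        _records, truth = generate_benchmark(6, [0.1, 0.4], seed=3)
        pos = truth[truth["class"] == "positive"]
        assert (pos["expected_verdict"] == "pass2_keep").all()
        assert (truth[truth["class"] != "positive"]["expected_verdict"] == "reject").all()
        assert (pos["plp_start"] > 0).all() and (pos["plp_end"] > pos["plp_start"]).all()

    def test_standalone_decoys_fail_pass1_length(self):
        records, truth = generate_benchmark(6, [0.1], seed=5)
        by_id = {r.id: r for r in records}
        for rid in truth[truth["class"] == "decoy_standalone"]["id"]:
            assert by_id[rid].length <= 1000

    def test_noplp_decoys_rarely_hit_the_profile(self, search_profile):
        records, truth = generate_benchmark(12, [0.2], seed=9)
        noplp = [r for r in records if r.id.startswith("DEC_noPLP")]
        hits = scan_database(search_profile, noplp, MiningConfig())
        assert len(hits) <= max(1, int(0.05 * len(noplp)))
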
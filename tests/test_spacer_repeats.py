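"""Spacer extraction, tandem decomposition, and remnant scanning, each checked
against an independent oracle or the generator's truth log."""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner

from mitorearr.annotation_io import GeneFeature, MitogenomeRecord, extract_feature_seq
from mitorearr.spacer_repeats import (
    RemnantScanParams,
    RepeatSearchParams,
    annotate_trus,
    decompose_tandem,
    extract_spacer,
    scan_remnants,
    smith_waterman,
    trna_library,
)
from mitorearr.synthetic import GeneratorSpec, PlantedEvent, generate_mitogenome, plant_rearrangement

BASES = list("ACGT")


def _random_seq(rng, n, probs=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(BASES, size=n, p=list(probs)))


class TestExtractSpacer:
    record = MitogenomeRecord(
        id="toy", sequence="AAAAAAAAAACCCTTTTTTTGGG", topology="linear",
        features=[GeneFeature("trnI", "tRNA", "J", 1, 10),
                  GeneFeature("trnQ", "tRNA", "N", 14, 20)],
    )

    def test_returns_gap_substring(self):
        sp = extract_spacer(self.record, "trnI", "trnQ")
        assert sp.seq == "CCC"
        assert (sp.start, sp.end) == (11, 13)

    def test_zero_gap_is_an_error(self):
        rec = MitogenomeRecord(
            id="t", sequence="A" * 20, topology="linear",
            features=[GeneFeature("trnI", "tRNA", "J", 1, 10),
                      GeneFeature("trnQ", "tRNA", "N", 11, 20)],
        )
        with pytest.raises(ValueError, match="0 bp"):
            extract_spacer(rec, "trnI", "trnQ")

    def test_non_adjacent_is_an_error(self):
        with pytest.raises(ValueError, match="not adjacent"):
            extract_spacer(self.record, "trnQ", "trnI")

    def test_planted_spacer_matches_truth(self, derived_record):
        record, truth = derived_record
        sp = extract_spacer(record, "trnC", "trnW")
        assert sp.seq == truth["spacer"]
        assert sp.start == truth["spacer_start"]


class TestDecomposeTandem:
    def test_exact_tandem_short_period(self):
        decs = decompose_tandem(
            "ACGTA" * 4, RepeatSearchParams(min_period=5, kmer=5, min_score=10)
        )
        assert len(decs) == 1
        d = decs[0]
        assert (d.period, d.copy_number, d.partial_unit_length) == (5, 4, 0)
        assert d.consensus == "ACGTA"

    def test_exact_copies_recovered_over_period_and_copy_grid(self):
        """k exact copies of a random unit: (period, k, partial 0) recovered
        exactly for periods 10..200 and k 2..10."""
        rng = np.random.default_rng(3)
        for period in (10, 25, 60, 111, 200):
            for k in (2, 3, 5, 10):
                unit = _random_seq(rng, period)
                decs = decompose_tandem(unit * k)
                assert decs, (period, k)
                d = decs[0]
                assert (d.period, d.copy_number, d.partial_unit_length) == (
                    period, k, 0)

    def test_published_tru_structure(self, derived_record):
        """Six 111 bp units + 44 bp partial, mirroring the observed spacer."""
        record, truth = derived_record
        sp = extract_spacer(record, "trnC", "trnW")
        d = decompose_tandem(sp.seq)[0]
        assert (d.period, d.copy_number, d.partial_unit_length) == (111, 6, 44)
        assert d.n_mismatches == 0

    def test_point_mutation_recorded_as_copy_mismatch(self, ancestral_record):
        record, _ = ancestral_record
        derived, truth = plant_rearrangement(
            record, PlantedEvent(n_remnant_mutations=1), seed=55
        )
        sp = extract_spacer(derived, "trnC", "trnW")
        d = decompose_tandem(sp.seq)[0]
        assert (d.period, d.copy_number) == (111, 6)
        assert d.n_mismatches == 1

    def test_reconstruction_from_consensus_and_mismatches(self, derived_record):
        """Consensus + recorded mismatches reproduce the covered span."""
        record, _ = derived_record
        sp = extract_spacer(record, "trnC", "trnW")
        d = decompose_tandem(sp.seq)[0]
        for off, mms in d.copy_alignments:
            rebuilt = list(d.consensus)
            for m in mms:
                rebuilt[m] = sp.seq[off + m]
            assert "".join(rebuilt) == sp.seq[off : off + d.period]

    def test_random_sequence_yields_no_decomposition(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            if decompose_tandem(_random_seq(rng, 300)):
                hits += 1
        assert hits <= 1  # >= 99% of seeds clean

    def test_too_short_sequence_returns_empty(self):
        assert decompose_tandem("ACGTACG") == []


class TestSmithWaterman:
    def _oracle(self):
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        return aligner

    def test_score_equals_biopython_local_aligner(self):
        """Dynamic-programming oracle on random instances <= 200 bp."""
        oracle = self._oracle()
        rng = np.random.default_rng(11)
        for _ in range(150):
            q = _random_seq(rng, int(rng.integers(10, 60)))
            t = _random_seq(rng, int(rng.integers(20, 200)))
            score, t0, t1, aq, at = smith_waterman(q, t)
            expected = oracle.score(q, t) if len(q) and len(t) else 0
            assert score == max(0, int(expected))

    def test_planted_similar_segment(self):
        rng = np.random.default_rng(12)
        oracle = self._oracle()
        for _ in range(60):
            q = _random_seq(rng, 40)
            insert = list(q[5:35])
            for i in rng.choice(30, size=3, replace=False):
                insert[i] = str(rng.choice([b for b in BASES if b != insert[i]]))
            t = _random_seq(rng, 60) + "".join(insert) + _random_seq(rng, 60)
            score, *_ = smith_waterman(q, t)
            assert score == int(oracle.score(q, t))

    def test_alignment_strings_are_consistent_with_score(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            q = _random_seq(rng, 30)
            t = _random_seq(rng, 80)
            score, t0, t1, aq, at = smith_waterman(q, t)
            recomputed = sum(
                1 if a == b else (-2 if "-" in (a, b) else -1)
                for a, b in zip(aq, at)
            )
            assert recomputed == score
            assert at.replace("-", "") == t[t0:t1]


class TestScanRemnants:
    def test_planted_exact_substring(self):
        rng = np.random.default_rng(21)
        gene = _random_seq(rng, 70)
        spacer = _random_seq(rng, 100) + gene[:29] + _random_seq(rng, 100)
        hits = scan_remnants(spacer, [("trnW", gene)])
        assert len(hits) == 1
        h = hits[0]
        assert (h.source_gene, h.spacer_offset, h.length, h.identity) == (
            "trnW", 100, 29, 1.0)
        assert h.strand == "J"

    def test_single_substitution_counted(self):
        rng = np.random.default_rng(22)
        gene = _random_seq(rng, 70)
        frag = list(gene[:29])
        frag[14] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[14]]
        spacer = _random_seq(rng, 80) + "".join(frag) + _random_seq(rng, 80)
        hits = scan_remnants(spacer, [("trnW", gene)])
        assert len(hits) == 1
        assert hits[0].mismatches == 1
        assert hits[0].identity == pytest.approx(28 / 29)

    def test_reverse_strand_hit(self):
        from mitorearr.annotation_io import reverse_complement

        rng = np.random.default_rng(23)
        gene = _random_seq(rng, 70)
        spacer = _random_seq(rng, 60) + reverse_complement(gene)[10:40] + _random_seq(rng, 60)
        hits = scan_remnants(spacer, [("trnW", gene)])
        assert hits and hits[0].strand == "N"

    def test_all_planted_copies_found(self, derived_record):
        record, truth = derived_record
        sp = extract_spacer(record, "trnC", "trnW")
        hits = scan_remnants(sp, trna_library(record))
        assert [h.source_gene for h in hits] == ["trnW"] * 6
        assert sorted(h.spacer_offset for h in hits) == truth["remnant_offsets"]
        assert all(h.length == 29 and h.identity == 1.0 for h in hits)

    def test_random_spacer_yields_no_hits(self, ancestral_record):
        """Null specificity: i.i.d. random spacers produce hits against the
        full tRNA library in at most 1% of seeds."""
        record, _ = ancestral_record
        lib = trna_library(record)
        bad = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            if scan_remnants(_random_seq(rng, 300), lib):
                bad += 1
        assert bad <= 0.01 * n_seeds


class TestAnnotateTrus:
    def test_planted_structure_fully_annotated(self, derived_record):
        record, truth = derived_record
        sp = extract_spacer(record, "trnC", "trnW")
        decomp = decompose_tandem(sp.seq)[0]
        hits = scan_remnants(sp, trna_library(record))
        tru = annotate_trus(decomp, hits, sp.seq)
        assert tru.n_copies == 6
        assert tru.n_remnant_copies == 6
        assert all(seg == (0, truth["linker_len"]) for seg in tru.linker_segments)
        assert tru.linkers_identical

    def test_no_hits_gives_all_linker_copies(self, derived_record):
        record, _ = derived_record
        sp = extract_spacer(record, "trnC", "trnW")
        decomp = decompose_tandem(sp.seq)[0]
        tru = annotate_trus(decomp, [], sp.seq)
        assert tru.n_remnant_copies == 0
        assert all(seg == (0, decomp.period) for seg in tru.linker_segments)

    def test_boundary_spanning_hit_flagged(self, derived_record):
        from mitorearr.spacer_repeats import RemnantHit

        record, _ = derived_record
        sp = extract_spacer(record, "trnC", "trnW")
        decomp = decompose_tandem(sp.seq)[0]
        rogue = RemnantHit(source_gene="trnX", spacer_offset=100, length=30,
                           identity=1.0, mismatches=0, gaps=0, strand="J", score=30)
        tru = annotate_trus(decomp, [rogue], sp.seq)
        assert tru.unassigned_hits == [rogue]


def test_parameter_recovery_battery():
    """Planted (n copies, remnant length, period) recovered exactly at
    mutation rate <= 1% in >= 95% of seeds."""
    ok = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        r = int(rng.integers(20, 41))
        linker = int(rng.integers(40, 100))
        rec, _ = generate_mitogenome(GeneratorSpec(seed=7))
        event = PlantedEvent(n_tru=n, remnant_len=r, linker_len=linker,
                             partial_len=(linker + r) // 3, mutation_rate=0.01)
        derived, truth = plant_rearrangement(rec, event, seed=seed + 500)
        sp = extract_spacer(derived, "trnC", "trnW")
        decs = decompose_tandem(sp.seq)
        w = extract_feature_seq(derived, derived.feature_by_name("trnW"))
        hits = [
            h for h in scan_remnants(sp, [("trnW", w)]) if h.source_gene == "trnW"
        ]
        lengths = sorted(h.length for h in hits)
        modal_len = max(set(lengths), key=lengths.count) if lengths else 0
        if (
            decs
            and decs[0].period == truth["period"]
            and decs[0].copy_number == n
            and len(hits) == n
            and modal_len == r  # edge mutations may truncate a minority of copies
        ):
            ok += 1
    assert ok >= 0.95 * n_seeds
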
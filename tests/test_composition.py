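"""Composition/skew arithmetic and NG86 Ka against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from mitorearr.composition import (
    KaSaturationError,
    at_skew,
    base_composition,
    codon_differences,
    codon_sites,
    gc_skew,
    ka_against_reference,
    ng86_ka,
    translate_codon,
    STOP_CODONS,
)
from mitorearr.annotation_io import reverse_complement
from mitorearr.synthetic import GeneratorSpec, generate_diverged_pair, generate_mitogenome

BASES = "ACGT"


# -- independent NG86 oracle (definition-level re-derivation) ----------------

def oracle_sites(codon):
    """Site fractions by direct enumeration of the 9 single mutations."""
    syn = 0.0
    for pos in range(3):
        changes = []
        for b in BASES:
            if b != codon[pos]:
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut not in STOP_CODONS:
                    changes.append(translate_codon(mut) == translate_codon(codon))
        if changes:
            syn += sum(changes) / len(changes)
    return syn, 3 - syn


def oracle_diffs(c1, c2):
    """Pathway average by explicit enumeration of all orderings."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    totals = []
    for order in itertools.permutations(pos):
        cur, steps = c1, []
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(translate_codon(cur) == translate_codon(nxt))
            cur = nxt
        if ok:
            totals.append((sum(steps), len(steps) - sum(steps)))
    if not totals:
        return None
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


class TestSkews:
    def test_symmetric_sequence_has_zero_skew(self):
        comp = base_composition("AATT")
        assert comp.freqA == comp.freqT == 0.5
        assert comp.at_skew == 0

    def test_published_composition_reproduces_published_skews(self):
        """A 47.1%, T 33.4%, G 7.4%, C 12.1% give skews 0.17 / -0.24."""
        assert round(at_skew(0.471, 0.334), 2) == 0.17
        assert round(gc_skew(0.074, 0.121), 2) == -0.24

    def test_reverse_complement_negates_skews(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            s = "".join(rng.choice(list(BASES), size=200))
            c, crc = base_composition(s), base_composition(reverse_complement(s))
            assert crc.at_skew == pytest.approx(-c.at_skew)
            assert crc.gc_skew == pytest.approx(-c.gc_skew)

    def test_skew_guard_when_denominator_is_zero(self):
        comp = base_composition("GGCC")
        assert comp.at_skew == 0.0 and not comp.at_skew_defined

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            base_composition("")


class TestCodonCounts:
    def test_sites_match_enumeration_oracle_for_all_codons(self):
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            if codon in STOP_CODONS:
                continue
            assert codon_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_sites_sum_to_three(self):
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            if codon in STOP_CODONS:
                continue
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_lys_to_asn_single_difference(self):
        """AAA -> AAC under the invertebrate mito code: 1 nonsynonymous
        difference; 1/3 synonymous site from the third position; frozen from
        the enumeration oracle."""
        assert codon_sites("AAA") == pytest.approx((1 / 3, 8 / 3))
        assert codon_differences("AAA", "AAC") == pytest.approx((0.0, 1.0))
        r = ng86_ka("AAA", "AAC")
        assert r.pN == pytest.approx(0.375)
        assert r.Ka == pytest.approx(-0.75 * math.log(0.5))

    def test_two_difference_pathway_average(self):
        """CCT vs CAA: mean over the two substitution orders (one passes
        through the synonymous CCT->CCA step)."""
        assert codon_differences("CCT", "CAA") == pytest.approx((0.5, 1.5))

    def test_pathways_match_oracle_on_random_codon_pairs(self):
        rng = np.random.default_rng(7)
        codons = ["".join(rng.choice(list(BASES), size=3)) for _ in range(200)]
        for c1, c2 in zip(codons[::2], codons[1::2]):
            if c1 in STOP_CODONS or c2 in STOP_CODONS:
                continue
            assert codon_differences(c1, c2) == pytest.approx(oracle_diffs(c1, c2))


class TestNg86:
    def test_identical_sequences_have_zero_ka(self):
        r = ng86_ka("ATGAAACCC", "ATGAAACCC")
        assert r.Ka == 0.0 and r.pN == 0.0

    def test_symmetry(self):
        a, b = "ATGAAATTTCCCGGG", "ATGAACTTACCAGGA"
        ra, rb = ng86_ka(a, b), ng86_ka(b, a)
        assert ra.Ka == pytest.approx(rb.Ka)
        assert ra.nonsyn_sites == pytest.approx(rb.nonsyn_sites)

    def test_gapped_and_stop_codons_are_skipped(self):
        r = ng86_ka("ATG---TAAAAA", "ATGCCCTAAAAC")
        assert r.n_codons_skipped == 2
        assert r.n_codons_used == 2

    def test_saturation_is_an_error(self):
        with pytest.raises(KaSaturationError):
            ng86_ka("AAACATTGG", "CCCGGCAAT")

    def test_length_not_multiple_of_three_is_an_error(self):
        with pytest.raises(ValueError):
            ng86_ka("ATGA", "ATGC")

    def test_agrees_with_independent_biopython_implementation(self):
        """Cross-check against Bio.codonalign cal_dn_ds (NG86); small
        tolerance absorbs its different stop-codon site convention."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from Bio.Data import CodonTable

        rng = np.random.default_rng(5)
        codons = []
        while len(codons) < 200:
            c = "".join(rng.choice(list(BASES), size=3))
            if c not in STOP_CODONS:
                codons.append(c)
        s1 = "".join(codons)
        s2 = list(s1)
        mutated = 0
        while mutated < 30:
            i = int(rng.integers(len(s1)))
            b = str(rng.choice([x for x in BASES if x != s2[i]]))
            old = s2[i]
            s2[i] = b
            codon = "".join(s2[3 * (i // 3) : 3 * (i // 3) + 3])
            if codon in STOP_CODONS:
                s2[i] = old
                continue
            mutated += 1
        s2 = "".join(s2)
        dn, _ds = cal_dn_ds(
            CodonSeq(s1), CodonSeq(s2), method="NG86",
            codon_table=CodonTable.unambiguous_dna_by_id[5],
        )
        assert ng86_ka(s1, s2).Ka == pytest.approx(dn, rel=0.02)


class TestKaAgainstReference:
    def test_self_comparison_is_zero(self, ancestral_record):
        record, _ = ancestral_record
        assert ka_against_reference(record, record).concatenated.Ka == 0.0

    def test_recovers_simulated_divergence(self, ancestral_record):
        record, _ = ancestral_record
        _, diverged, truth = generate_diverged_pair(record, 0.40, seed=11)
        rep = ka_against_reference(record, diverged)
        r = rep.concatenated
        expected_pn = truth["n_substitutions"] / r.nonsyn_sites
        expected_ka = -0.75 * math.log(1 - 4 / 3 * expected_pn)
        assert r.Ka == pytest.approx(expected_ka, rel=0.10)
        assert len(rep.per_gene) == 13

    def test_ka_monotone_in_divergence_rate(self, ancestral_record):
        record, _ = ancestral_record
        kas = []
        for rate in (0.05, 0.15, 0.30, 0.45):
            _, d, _ = generate_diverged_pair(record, rate, seed=3)
            kas.append(ka_against_reference(record, d).concatenated.Ka)
        assert kas == sorted(kas)

    def test_missing_gene_is_skipped_and_recorded(self, ancestral_record):
        record, _ = ancestral_record
        from mitorearr.annotation_io import MitogenomeRecord

        pruned = MitogenomeRecord(
            id="pruned", sequence=record.sequence, topology=record.topology,
            features=[f for f in record.features if f.name != "ND6"],
        )
        rep = ka_against_reference(record, pruned)
        assert rep.skipped_genes == ["ND6"]
        assert len(rep.per_gene) == 12

    def test_truth_log_matches_coding_hamming_distance(self, ancestral_record):
        record, _ = ancestral_record
        _, diverged, truth = generate_diverged_pair(record, 0.2, seed=8)
        ham = sum(
            a != b for a, b in zip(record.sequence, diverged.sequence)
        )
        assert ham == truth["n_substitutions"]
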
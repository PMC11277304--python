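"""Base composition, strand skews, and Nei–Gojobori (1986) nonsynonymous
divergence under the invertebrate mitochondrial code.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed over
unambiguous bases.  Ka follows the NG86 counting method: per-codon
synonymous/nonsynonymous site fractions from the nine possible single-base
changes (changes to stop codons excluded and the position renormalized),
differences averaged over all minimal mutational pathways that avoid stop
codons, then the Jukes–Cantor correction Ka = -(3/4)·ln(1 - (4/3)·pN).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .annotation_io import MitogenomeRecord, extract_feature_seq
from .vocab import PCGS

#: NCBI translation table 5 (invertebrate mitochondrial)
INVERT_MITO_TABLE_ID = 5
_TABLE = CodonTable.unambiguous_dna_by_id[INVERT_MITO_TABLE_ID]
STOP_CODONS = frozenset(_TABLE.stop_codons)

_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """Amino acid for a codon under the invertebrate mito code; '*' for stops."""
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


class KaSaturationError(ValueError):
    """pN >= 3/4: the Jukes-Cantor correction is undefined (saturation)."""


# ---------------------------------------------------------------------------
# Composition & skews
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseComposition:
    freqA: float
    freqT: float
    freqG: float
    freqC: float
    n_ambiguous: int
    at_skew: float
    gc_skew: float
    at_skew_defined: bool = True
    gc_skew_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "freqA": self.freqA, "freqT": self.freqT,
            "freqG": self.freqG, "freqC": self.freqC,
            "n_ambiguous": self.n_ambiguous,
            "at_skew": round(self.at_skew, 2), "gc_skew": round(self.gc_skew, 2),
        }


def at_skew(freq_a: float, freq_t: float) -> float:
    """(A - T)/(A + T); 0 when A + T = 0."""
    tot = freq_a + freq_t
    return 0.0 if tot == 0 else (freq_a - freq_t) / tot


def gc_skew(freq_g: float, freq_c: float) -> float:
    """(G - C)/(G + C); 0 when G + C = 0."""
    tot = freq_g + freq_c
    return 0.0 if tot == 0 else (freq_g - freq_c) / tot


def base_composition(seq: str) -> BaseComposition:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    counts = {b: s.count(b) for b in _BASES}
    n = sum(counts.values())
    n_amb = len(s) - n
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    fa, fc, fg, ft = (counts[b] / n for b in _BASES)
    return BaseComposition(
        freqA=fa, freqT=ft, freqG=fg, freqC=fc, n_ambiguous=n_amb,
        at_skew=at_skew(fa, ft), gc_skew=gc_skew(fg, fc),
        at_skew_defined=(fa + ft) > 0, gc_skew_defined=(fg + fc) > 0,
    )


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its possible changes that are
    synonymous; changes to stop codons are excluded and the position's
    denominator renormalized, so syn + nonsyn = 3 always.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            n_valid += 1
            if translate_codon(mut) == aa:
                n_syn += 1
        syn += n_syn / n_valid if n_valid else 0.0
    return syn, 3.0 - syn


def codon_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    codons; ``None`` if every minimal mutational pathway passes through a stop
    codon (the pair is then skipped with a flag upstream).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, nonsyn_tot / n_paths


@dataclass
class KaResult:
    """NG86 counts for one aligned coding sequence pair."""

    nonsyn_sites: float
    nonsyn_diffs: float
    syn_sites: float
    syn_diffs: float
    pN: float
    Ka: float
    n_codons_used: int
    n_codons_skipped: int
    gene_scope: str = "concatenated"

    def to_dict(self) -> dict:
        return {
            "gene_scope": self.gene_scope,
            "nonsyn_sites": self.nonsyn_sites, "nonsyn_diffs": self.nonsyn_diffs,
            "syn_sites": self.syn_sites, "syn_diffs": self.syn_diffs,
            "pN": self.pN, "Ka": self.Ka,
            "n_codons_used": self.n_codons_used,
            "n_codons_skipped": self.n_codons_skipped,
        }


def _jc_correct(p: float) -> float:
    import math

    if p >= 0.75:
        raise KaSaturationError(f"pN = {p:.4f} >= 3/4; Ka undefined (saturated)")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_ka(seq1: str, seq2: str, gene_scope: str = "concatenated") -> KaResult:
    """NG86 Ka between two pre-aligned in-frame sequences ('-' gaps allowed).

    Codons containing gaps, ambiguity codes, or stop codons (in either
    sequence) are skipped.  Site counts are averaged over the two sequences.
    Symmetric in its arguments.
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("aligned sequences must have equal length")
    if len(s1) % 3:
        raise ValueError("aligned length is not a multiple of 3")
    syn_sites = nonsyn_sites = syn_diffs = nonsyn_diffs = 0.0
    used = skipped = 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if any(b not in _BASES for b in c1 + c2):
            skipped += 1
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            skipped += 1
            continue
        diffs = codon_differences(c1, c2)
        if diffs is None:
            skipped += 1
            continue
        s1s, n1s = codon_sites(c1)
        s2s, n2s = codon_sites(c2)
        syn_sites += (s1s + s2s) / 2
        nonsyn_sites += (n1s + n2s) / 2
        syn_diffs += diffs[0]
        nonsyn_diffs += diffs[1]
        used += 1
    if nonsyn_sites == 0:
        raise ValueError("no usable codons")
    p_n = nonsyn_diffs / nonsyn_sites
    return KaResult(
        nonsyn_sites=nonsyn_sites, nonsyn_diffs=nonsyn_diffs,
        syn_sites=syn_sites, syn_diffs=syn_diffs,
        pN=p_n, Ka=_jc_correct(p_n),
        n_codons_used=used, n_codons_skipped=skipped, gene_scope=gene_scope,
    )


# ---------------------------------------------------------------------------
# Codon alignment + whole-mitogenome Ka
# ---------------------------------------------------------------------------

def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def align_codons(cds1: str, cds2: str) -> tuple[str, str]:
    """Codon-aware alignment: translate (table 5), globally align the
    proteins, back-thread gaps as '---' triplets."""
    c1 = cds1[: len(cds1) - len(cds1) % 3]
    c2 = cds2[: len(cds2) - len(cds2) % 3]
    p1 = str(Seq(c1).translate(table=INVERT_MITO_TABLE_ID))
    p2 = str(Seq(c2).translate(table=INVERT_MITO_TABLE_ID))
    aln = _protein_aligner().align(p1, p2)[0]
    a1, a2 = str(aln[0]), str(aln[1])
    out1, out2 = [], []
    i = j = 0
    for x, y in zip(a1, a2):
        out1.append("---" if x == "-" else c1[3 * i : 3 * i + 3])
        out2.append("---" if y == "-" else c2[3 * j : 3 * j + 3])
        i += x != "-"
        j += y != "-"
    return "".join(out1), "".join(out2)


@dataclass
class KaReport:
    concatenated: KaResult
    per_gene: dict[str, KaResult] = field(default_factory=dict)
    skipped_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "concatenated": self.concatenated.to_dict(),
            "per_gene": {g: r.to_dict() for g, r in self.per_gene.items()},
            "skipped_genes": self.skipped_genes,
        }


def _cds_without_stop(record: MitogenomeRecord, gene: str) -> str:
    seq = extract_feature_seq(record, record.feature_by_name(gene))
    seq = seq[: len(seq) - len(seq) % 3]
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    return seq


def ka_against_reference(query: MitogenomeRecord, reference: MitogenomeRecord) -> KaReport:
    """Per-gene and concatenated 13-PCG NG86 Ka of ``query`` vs ``reference``.

    Genes missing from either record are skipped and listed; per-gene results
    that saturate are also recorded as skipped.
    """
    per_gene: dict[str, KaResult] = {}
    skipped: list[str] = []
    cat1: list[str] = []
    cat2: list[str] = []
    q_names = {f.name for f in query.features}
    r_names = {f.name for f in reference.features}
    for gene in PCGS:
        if gene not in q_names or gene not in r_names:
            skipped.append(gene)
            continue
        a1, a2 = align_codons(
            _cds_without_stop(query, gene), _cds_without_stop(reference, gene)
        )
        cat1.append(a1)
        cat2.append(a2)
        try:
            per_gene[gene] = ng86_ka(a1, a2, gene_scope=gene)
        except (KaSaturationError, ValueError):
            skipped.append(gene)
    if not cat1:
        raise ValueError("no shared protein-coding genes")
    concat = ng86_ka("".join(cat1), "".join(cat2))
    return KaReport(concatenated=concat, per_gene=per_gene, skipped_genes=skipped)
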
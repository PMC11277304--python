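"""Synthetic annotated mitogenomes with known ground truth.

The generator lays out the 37 canonical genes + control region in the
ancestral insect arrangement on a circular, AT-biased molecule (defaults match
the study system: 16,546 bp target, base probabilities A 0.471 / T 0.334 /
G 0.074 / C 0.121, 12 gene overlaps of 1-8 bp and five small spacers).
``plant_rearrangement`` converts it into the derived state: the trnW/trnC
block swapped with an intergenic spacer of n tandem repeat units, each an
identical linker followed by a degenerate fragment of the displaced gene, plus
a trailing partial unit — by default 6 x (82 + 29) + 44 = 710 bp.  Every
coordinate, junction gap, spacer string, remnant offset and mutation is
recorded in a truth log so each analysis stage can be checked against the
construction.

All randomness flows through one numpy Generator seeded by the spec.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation_io import GeneFeature, MitogenomeRecord, extract_feature_seq, reverse_complement
from .composition import STOP_CODONS, translate_codon
from .vocab import ANCESTRAL_ORDER, CONTROL_REGION, GENE_CLASS

_BASES = np.array(list("ACGT"))

#: canonical-ish invertebrate mitochondrial PCG lengths (bp, incl. stop)
PCG_LENGTHS = {
    "ND2": 1023, "COX1": 1536, "COX2": 684, "ATP8": 162, "ATP6": 675,
    "COX3": 786, "ND3": 354, "ND5": 1716, "ND4": 1341, "ND4L": 291,
    "ND6": 522, "CYTB": 1140, "ND1": 945,
}
RRNA_LENGTHS = {"rrnL": 1285, "rrnS": 785}


@dataclass(frozen=True)
class PlantedEvent:
    """Parameters of the planted transposition + TRU spacer."""

    block: tuple[str, str] = ("trnW", "trnC")
    n_tru: int = 6
    remnant_len: int = 29
    linker_len: int = 82
    partial_len: int = 44
    mutation_rate: float = 0.0
    n_remnant_mutations: int = 0  # exact count of point mutations inside remnants

    @property
    def period(self) -> int:
        return self.remnant_len + self.linker_len


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 1
    genome_length_target: int = 16546
    base_probs: tuple[float, float, float, float] = (0.471, 0.334, 0.074, 0.121)  # A,T,G,C
    trna_len_range: tuple[int, int] = (60, 75)
    n_overlaps: int = 12
    overlap_range: tuple[int, int] = (1, 8)
    n_spacers: int = 5
    spacer_range: tuple[int, int] = (5, 25)
    min_control_region: int = 120
    planted_event: PlantedEvent | None = None
    divergence: float = 0.0  # nonsynonymous per-codon rate for paired output

    def __post_init__(self):
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")


def _random_seq(rng: np.random.Generator, n: int, probs) -> str:
    p_a, p_t, p_g, p_c = probs  # spec order A,T,G,C -> _BASES order A,C,G,T
    return "".join(rng.choice(_BASES, size=n, p=[p_a, p_c, p_g, p_t]))


def _random_cds(rng: np.random.Generator, length: int, probs) -> str:
    """Random in-frame CDS: ATG start, TAA stop, stop-free interior.

    Interior stop codons are letter-shuffled into a non-stop permutation so
    the base composition of the draw is preserved exactly.
    """
    assert length % 3 == 0 and length >= 9
    n_mid = length // 3 - 2
    codons = ["ATG"]
    for _ in range(n_mid):
        c = _random_seq(rng, 3, probs)
        while c in STOP_CODONS:
            perm = rng.permutation(3)
            c = "".join(c[k] for k in perm)
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


# junctions adjacent to the default planted block stay gap-free so planting
# can cut cleanly between intact genes
_PROTECTED = {("ND2", "trnW"), ("trnW", "trnC"), ("trnC", "trnY")}


def generate_mitogenome(spec: GeneratorSpec) -> tuple[MitogenomeRecord, dict]:
    """Build the ancestral-arrangement record; returns (record, truth log)."""
    rng = np.random.default_rng(spec.seed)
    order = ANCESTRAL_ORDER
    lengths: dict[str, int] = {}
    for name, _ in order:
        cls = GENE_CLASS[name]
        if cls == "PCG":
            lengths[name] = PCG_LENGTHS[name]
        elif cls == "tRNA":
            lengths[name] = int(rng.integers(spec.trna_len_range[0],
                                             spec.trna_len_range[1] + 1))
        elif cls == "rRNA":
            lengths[name] = RRNA_LENGTHS[name]
    # junction i sits between gene i and gene i+1 (control region junctions
    # and block-adjacent junctions excluded from overlap/spacer assignment)
    n_junctions = len(order) - 1
    eligible_overlap = [
        i for i in range(n_junctions)
        if GENE_CLASS[order[i + 1][0]] == "tRNA"
        and (order[i][0], order[i + 1][0]) not in _PROTECTED
        and order[i][0] != CONTROL_REGION
    ]
    if spec.n_overlaps > len(eligible_overlap):
        raise ValueError("more overlaps requested than eligible junctions")
    gaps = np.zeros(n_junctions, dtype=int)
    ov_idx = rng.choice(eligible_overlap, size=spec.n_overlaps, replace=False)
    gaps[ov_idx] = -rng.integers(spec.overlap_range[0], spec.overlap_range[1] + 1,
                                 size=spec.n_overlaps)
    eligible_spacer = [
        i for i in range(n_junctions)
        if gaps[i] == 0
        and (order[i][0], order[i + 1][0]) not in _PROTECTED
        and CONTROL_REGION not in (order[i][0], order[i + 1][0])
    ]
    sp_idx = rng.choice(eligible_spacer, size=spec.n_spacers, replace=False)
    gaps[sp_idx] = rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1,
                                size=spec.n_spacers)
    fixed = sum(lengths.values()) + int(gaps.sum())
    cr_len = spec.genome_length_target - fixed
    if cr_len < spec.min_control_region:
        raise ValueError(
            f"infeasible spec: genes + gaps leave {cr_len} bp for the control "
            f"region (minimum {spec.min_control_region})"
        )
    lengths[CONTROL_REGION] = cr_len

    coding: dict[str, str] = {}
    p_a, p_t, p_g, p_c = spec.base_probs
    comp_probs = (p_t, p_a, p_c, p_g)  # complemented: N-strand genes are
    # placed as reverse complements, so drawing their coding strand from the
    # complemented distribution keeps the J-strand composition on target
    for name, strand in order:
        cls = GENE_CLASS[name]
        probs = spec.base_probs if strand == "J" else comp_probs
        if cls == "PCG":
            coding[name] = _random_cds(rng, lengths[name], probs)
        elif cls in ("tRNA", "rRNA", "control_region"):
            coding[name] = _random_seq(rng, lengths[name], probs)

    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0  # 0-based length assembled so far
    truth_gaps = []
    for idx, (name, strand) in enumerate(order):
        if idx > 0:
            g = int(gaps[idx - 1])
            truth_gaps.append(
                {"left": order[idx - 1][0], "right": name, "gap": g}
            )
            if g > 0:
                parts.append(_random_seq(rng, g, spec.base_probs))
                pos += g
        placed = coding[name] if strand == "J" else reverse_complement(coding[name])
        g = int(gaps[idx - 1]) if idx > 0 else 0
        if g < 0:
            start = pos + g  # share |g| bases with the previous gene
            parts.append(placed[-g:])
            pos += len(placed) + g
        else:
            start = pos
            parts.append(placed)
            pos += len(placed)
        features.append(
            GeneFeature(name=name, gene_class=GENE_CLASS[name], strand=strand,
                        start=start + 1, end=start + len(placed))
        )
    truth_gaps.append({"left": order[-1][0], "right": order[0][0], "gap": 0})
    sequence = "".join(parts)
    record = MitogenomeRecord(
        id=f"SYN{spec.seed:07d}", sequence=sequence, topology="circular",
        features=features,
    )
    truth = {
        "seed": spec.seed,
        "genome_length": len(sequence),
        "gene_order": [(n, s) for n, s in order],
        "gene_lengths": dict(lengths),
        "coordinates": {f.name: (f.start, f.end, f.strand) for f in features},
        "junction_gaps": truth_gaps,
        "n_overlaps": int(spec.n_overlaps),
        "n_spacers": int(spec.n_spacers),
    }
    if len(sequence) != spec.genome_length_target:
        raise AssertionError("assembled length does not match target")
    return record, truth


def plant_rearrangement(
    record: MitogenomeRecord,
    event: PlantedEvent | None = None,
    seed: int = 0,
) -> tuple[MitogenomeRecord, dict]:
    """Swap the (adjacent, gap-free flanked) two-gene block and insert the TRU
    spacer between the swapped genes; returns (derived record, truth log).

    The spacer is ``n_tru`` units of (identical linker + degenerate fragment of
    the displaced first block gene) plus a trailing partial unit (a unit
    prefix), then point mutations: Bernoulli per base at ``mutation_rate``, and
    exactly ``n_remnant_mutations`` extra substitutions placed inside distinct
    remnant copies (emulating the observed single A->G in one repeat unit).
    """
    event = event or PlantedEvent()
    if event.partial_len >= event.period:
        raise ValueError("partial unit must be shorter than one period")
    if event.remnant_len < 1 or event.linker_len < 1:
        raise ValueError("remnant_len and linker_len must be positive")
    rng = np.random.default_rng(seed)
    g1_name, g2_name = event.block
    g1 = record.feature_by_name(g1_name)
    g2 = record.feature_by_name(g2_name)
    if g1.start > g2.start:
        g1, g2 = g2, g1
        g1_name, g2_name = g2_name, g1_name
    if g2.start - g1.end - 1 != 0:
        raise ValueError(
            f"block genes {g1_name},{g2_name} must abut (gap "
            f"{g2.start - g1.end - 1} bp)"
        )
    genome = record.sequence
    seg1 = genome[g1.start - 1 : g1.end]
    seg2 = genome[g2.start - 1 : g2.end]
    # remnant: leading fragment of the displaced gene as it lies on the J strand
    remnant = seg1[: event.remnant_len]
    if len(remnant) < event.remnant_len:
        raise ValueError(f"{g1_name} shorter than remnant_len")
    linker = _random_seq(rng, event.linker_len, (0.471, 0.334, 0.074, 0.121))
    # keep the remnant boundary crisp: the base after each remnant copy (the
    # next unit's first linker base) must differ from the gene's next base,
    # or local alignment would extend the planted match by chance
    follow = seg1[event.remnant_len] if len(seg1) > event.remnant_len else None
    while follow is not None and linker[0] == follow:
        linker = str(rng.choice([b for b in "ACGT" if b != follow])) + linker[1:]
    unit = linker + remnant
    spacer = unit * event.n_tru + unit[: event.partial_len]
    spacer_list = list(spacer)
    mutations: list[dict] = []
    if event.mutation_rate > 0:
        hits = np.nonzero(rng.random(len(spacer_list)) < event.mutation_rate)[0]
        for i in hits:
            old = spacer_list[i]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            spacer_list[i] = new
            mutations.append({"offset": int(i), "from": old, "to": new})
    remnant_offsets = [event.linker_len + k * event.period for k in range(event.n_tru)]
    if event.n_remnant_mutations:
        if event.n_remnant_mutations > event.n_tru:
            raise ValueError("at most one planted mutation per remnant copy")
        if event.remnant_len < 11:
            raise ValueError("remnant too short for interior mutations")
        copies = rng.choice(event.n_tru, size=event.n_remnant_mutations, replace=False)
        for c in copies:
            # interior placement (>=5 bp flanks) keeps the degenerate copy one
            # contiguous hit rather than two truncated ones
            off = remnant_offsets[int(c)] + int(rng.integers(5, event.remnant_len - 5))
            old = spacer_list[off]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            spacer_list[off] = new
            mutations.append({"offset": int(off), "from": old, "to": new,
                              "remnant_copy": int(c)})
    spacer = "".join(spacer_list)

    new_genome = (
        genome[: g1.start - 1] + seg2 + spacer + seg1 + genome[g2.end :]
    )
    delta = len(new_genome) - len(genome)
    new_feats: list[GeneFeature] = []
    for f in record.features:
        if f.name == g1_name:
            ns = g1.start + len(seg2) + len(spacer)
            new_feats.append(replace(f, start=ns, end=ns + len(seg1) - 1))
        elif f.name == g2_name:
            new_feats.append(replace(f, start=g1.start, end=g1.start + len(seg2) - 1))
        elif f.start > g2.end:
            new_feats.append(replace(f, start=f.start + delta, end=f.end + delta))
        else:
            new_feats.append(f)
    derived = MitogenomeRecord(
        id=record.id + "_derived", sequence=new_genome, topology=record.topology,
        features=new_feats,
    )
    spacer_start = g1.start + len(seg2)  # 1-based
    truth = {
        "block": [g1_name, g2_name],
        "derived_block_order": [g2_name, g1_name],
        "n_tru": event.n_tru,
        "period": event.period,
        "remnant_len": event.remnant_len,
        "linker_len": event.linker_len,
        "partial_len": event.partial_len,
        "spacer": spacer,
        "spacer_start": spacer_start,
        "spacer_end": spacer_start + len(spacer) - 1,
        "spacer_length": len(spacer),
        "remnant_offsets": remnant_offsets,
        "remnant_source": g1_name,
        "mutations": mutations,
    }
    return derived, truth


def _nonsyn_variants(codon: str) -> list[tuple[int, str]]:
    """(position, base) single changes that alter the amino acid, avoid stops."""
    if codon in STOP_CODONS:
        return []
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if translate_codon(mut) != aa:
                out.append((pos, b))
    return out


def generate_diverged_pair(
    record: MitogenomeRecord, nonsyn_rate: float, seed: int = 0
) -> tuple[MitogenomeRecord, MitogenomeRecord, dict]:
    """Copy the record and introduce nonsynonymous substitutions: each internal
    codon of each PCG mutates with probability ``nonsyn_rate`` by one uniformly
    chosen amino-acid-changing, stop-avoiding base change (synonymous sites are
    untouched).  Returns (original, diverged, truth log)."""
    rng = np.random.default_rng(seed)
    genome = list(record.sequence)
    subs: list[dict] = []
    for f in record.features:
        if f.gene_class != "PCG":
            continue
        cds = extract_feature_seq(record, f)
        n_codons = len(cds) // 3
        for ci in range(1, n_codons - 1):  # keep start and stop codons intact
            if rng.random() >= nonsyn_rate:
                continue
            codon = cds[3 * ci : 3 * ci + 3]
            variants = _nonsyn_variants(codon)
            if not variants:
                continue
            pos, b = variants[int(rng.integers(len(variants)))]
            cds_pos = 3 * ci + pos  # 0-based within coding sequence
            if f.strand == "J":
                gpos = f.start - 1 + cds_pos
                genome[gpos] = b
            else:
                gpos = f.end - 1 - cds_pos
                genome[gpos] = {"A": "T", "T": "A", "G": "C", "C": "G"}[b]
            subs.append({"gene": f.name, "codon": ci, "codon_pos": pos,
                         "genome_pos": gpos + 1, "from": codon[pos], "to": b})
    diverged = MitogenomeRecord(
        id=record.id + "_div", sequence="".join(genome),
        topology=record.topology, features=copy.deepcopy(record.features),
    )
    truth = {
        "nonsyn_rate": nonsyn_rate,
        "n_substitutions": len(subs),
        "substitutions": subs,
    }
    return record, diverged, truth
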
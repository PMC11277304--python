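"""Canonical mitochondrial gene vocabulary and the ancestral insect arrangement.

The insect mitogenome carries 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs
and one A+T-rich control region.  Gene labels in public annotations are wildly
inconsistent ("COI", "cox1", "tRNA-Trp", "trnW-UCA" ...); everything downstream
works on the closed canonical vocabulary defined here.  The leucine and serine
tRNA paralogs are distinguished by anticodon: trnL1 = Leu(CUN), trnL2 = Leu(UUR),
trnS1 = Ser(AGN), trnS2 = Ser(UCN).
"""

from __future__ import annotations

import re

PCGS = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COX1", "COX2", "COX3", "ATP6", "ATP8", "CYTB",
)

TRNAS = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnY", "trnV",
)

RRNAS = ("rrnS", "rrnL")

CONTROL_REGION = "control_region"

#: the full closed vocabulary: 37 genes + control region
CANONICAL_GENES = frozenset(PCGS) | frozenset(TRNAS) | frozenset(RRNAS) | {CONTROL_REGION}

GENE_CLASS = {g: "PCG" for g in PCGS}
GENE_CLASS.update({g: "tRNA" for g in TRNAS})
GENE_CLASS.update({g: "rRNA" for g in RRNAS})
GENE_CLASS[CONTROL_REGION] = "control_region"

# Ancestral pancrustacean / typical firefly arrangement in J-strand coordinate
# order starting from trnI.  Strand: J = majority, N = minority.  The ND2
# neighborhood reads ND2-trnW-trnC-trnY; 14 genes sit on the N strand
# (8 tRNAs, 4 PCGs, both rRNAs).
ANCESTRAL_ORDER: tuple[tuple[str, str], ...] = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("ND2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"), ("COX1", "J"),
    ("trnL2", "J"), ("COX2", "J"), ("trnK", "J"), ("trnD", "J"),
    ("ATP8", "J"), ("ATP6", "J"), ("COX3", "J"), ("trnG", "J"),
    ("ND3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("ND5", "N"),
    ("trnH", "N"), ("ND4", "N"), ("ND4L", "N"), ("trnT", "J"),
    ("trnP", "N"), ("ND6", "J"), ("CYTB", "J"), ("trnS2", "J"),
    ("ND1", "N"), ("trnL1", "N"), ("rrnL", "N"), ("trnV", "N"),
    ("rrnS", "N"), (CONTROL_REGION, "J"),
)

_AA3_TO_TOKEN = {
    "ALA": "trnA", "ARG": "trnR", "ASN": "trnN", "ASP": "trnD",
    "CYS": "trnC", "GLU": "trnE", "GLN": "trnQ", "GLY": "trnG",
    "HIS": "trnH", "ILE": "trnI", "LYS": "trnK", "MET": "trnM",
    "PHE": "trnF", "PRO": "trnP", "THR": "trnT", "TRP": "trnW",
    "TYR": "trnY", "VAL": "trnV",
}

_AA1_TO_TOKEN = {
    "A": "trnA", "R": "trnR", "N": "trnN", "D": "trnD", "C": "trnC",
    "E": "trnE", "Q": "trnQ", "G": "trnG", "H": "trnH", "I": "trnI",
    "K": "trnK", "M": "trnM", "F": "trnF", "P": "trnP", "T": "trnT",
    "W": "trnW", "Y": "trnY", "V": "trnV",
}

# Leu/Ser paralogs: codon family or anticodon decides the number.
_LEU_SER = {
    ("LEU", "CUN"): "trnL1", ("LEU", "UUR"): "trnL2",
    ("SER", "AGN"): "trnS1", ("SER", "UCN"): "trnS2",
}
# anticodons (DNA or RNA spelling) for the paralogs
_ANTICODON_PARALOG = {
    "TAG": "trnL1", "UAG": "trnL1",
    "TAA": "trnL2", "UAA": "trnL2",
    "GCT": "trnS1", "GCU": "trnS1", "TCT": "trnS1", "UCU": "trnS1",
    "TGA": "trnS2", "UGA": "trnS2",
}

_DIRECT = {
    # PCG synonyms
    "COI": "COX1", "CO1": "COX1", "COXI": "COX1", "COX1": "COX1", "MT-CO1": "COX1",
    "COII": "COX2", "CO2": "COX2", "COXII": "COX2", "COX2": "COX2",
    "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3", "COX3": "COX3",
    "CYTB": "CYTB", "COB": "CYTB", "CYB": "CYTB", "CYT B": "CYTB",
    "CYTOCHROME B": "CYTB", "CYTOCHROME OXIDASE SUBUNIT I": "COX1",
    "CYTOCHROME OXIDASE SUBUNIT II": "COX2",
    "CYTOCHROME OXIDASE SUBUNIT III": "COX3",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPASE 6": "ATP6", "ATP SYNTHASE F0 SUBUNIT 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATPASE 8": "ATP8", "ATP SYNTHASE F0 SUBUNIT 8": "ATP8",
    "ND1": "ND1", "NAD1": "ND1", "NADH1": "ND1", "NADH DEHYDROGENASE SUBUNIT 1": "ND1",
    "ND2": "ND2", "NAD2": "ND2", "NADH2": "ND2", "NADH DEHYDROGENASE SUBUNIT 2": "ND2",
    "ND3": "ND3", "NAD3": "ND3", "NADH3": "ND3", "NADH DEHYDROGENASE SUBUNIT 3": "ND3",
    "ND4": "ND4", "NAD4": "ND4", "NADH4": "ND4", "NADH DEHYDROGENASE SUBUNIT 4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L", "NADH4L": "ND4L", "NADH DEHYDROGENASE SUBUNIT 4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5", "NADH5": "ND5", "NADH DEHYDROGENASE SUBUNIT 5": "ND5",
    "ND6": "ND6", "NAD6": "ND6", "NADH6": "ND6", "NADH DEHYDROGENASE SUBUNIT 6": "ND6",
    # rRNAs
    "RRNL": "rrnL", "L-RRNA": "rrnL", "LRRNA": "rrnL", "16S": "rrnL",
    "16S RIBOSOMAL RNA": "rrnL", "16S RRNA": "rrnL", "LSU": "rrnL",
    "LARGE SUBUNIT RIBOSOMAL RNA": "rrnL",
    "RRNS": "rrnS", "S-RRNA": "rrnS", "SRRNA": "rrnS", "12S": "rrnS",
    "12S RIBOSOMAL RNA": "rrnS", "12S RRNA": "rrnS", "SSU": "rrnS",
    "SMALL SUBUNIT RIBOSOMAL RNA": "rrnS",
    # control region
    "CONTROL_REGION": CONTROL_REGION, "CONTROL REGION": CONTROL_REGION,
    "A+T-RICH REGION": CONTROL_REGION, "AT-RICH REGION": CONTROL_REGION,
    "A+T RICH REGION": CONTROL_REGION, "D-LOOP": CONTROL_REGION,
    "PUTATIVE CONTROL REGION": CONTROL_REGION, "CR": CONTROL_REGION,
}


def canonical_gene_name(raw: str) -> tuple[str, bool]:
    """Normalize a free-text gene label to a canonical token.

    Returns ``(token, is_canonical)``.  Unrecognized labels come back unchanged
    with ``is_canonical=False``; they are never an error.
    """
    label = raw.strip()
    if label in CANONICAL_GENES:
        return label, True
    up = label.upper().replace("_", " ").strip()
    up = re.sub(r"\s+", " ", up)
    if up in _DIRECT:
        return _DIRECT[up], True
    # single-letter two-char shorthand like "TW" (tRNA-Trp)
    m = re.fullmatch(r"T([ACDEFGHIKMNPQRTVWY])", up)
    if m:
        return _AA1_TO_TOKEN[m.group(1)], True
    # tRNA-Xxx / tRNA-Xxx(acg) forms (before trnX: "TRNA-TRP" must not be
    # read as trnA with anticodon "TRP")
    m = re.fullmatch(r"T-?RNA[- ]([A-Z]{3})\s*(?:\(([A-Z]{3})\))?", up)
    if m and (m.group(1) in _AA3_TO_TOKEN or m.group(1) in ("LEU", "SER")):
        aa3, codon = m.groups()
        if aa3 in ("LEU", "SER"):
            if codon:
                fam = codon.replace("U", "T")
                # codon family: UUR Leu -> L2, CUN Leu -> L1, UCN Ser -> S2, AGN Ser -> S1
                if aa3 == "LEU":
                    return ("trnL2", True) if fam.startswith("TT") else ("trnL1", True)
                return ("trnS1", True) if fam.startswith("AG") else ("trnS2", True)
            return label, False  # ambiguous paralog
        return _AA3_TO_TOKEN[aa3], True
    # trnX / trnX-anticodon forms
    m = re.fullmatch(r"TRN([A-Z])([12])?(?:[-(]([A-Z]{3})\)?)?", up)
    if m:
        letter, number, anticodon = m.groups()
        if letter in ("L", "S"):
            if number:
                return f"trn{letter}{number}", True
            if anticodon and anticodon in _ANTICODON_PARALOG:
                tok = _ANTICODON_PARALOG[anticodon]
                if tok[3] == letter:
                    return tok, True
            return label, False  # ambiguous paralog
        if letter in _AA1_TO_TOKEN:
            return _AA1_TO_TOKEN[letter], True
    return label, False


def gene_class_of(token: str) -> str:
    """Gene class of a canonical token; 'unknown' for non-canonical labels."""
    return GENE_CLASS.get(token, "unknown")
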
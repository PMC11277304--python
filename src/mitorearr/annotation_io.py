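"""Annotated-mitogenome I/O: GenBank / feature-table parsing, strand- and
origin-aware sequence extraction, and junction (overlap/spacer) accounting.

Coordinates are 1-based inclusive externally (GenBank convention).  A feature
whose span crosses the origin of the circular molecule has ``wraps_origin=True``
and ``start > end``; its length is computed by circular arithmetic.  Strands
use the mitogenome convention J (majority, '+') / N (minority, '-').
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .vocab import CONTROL_REGION, canonical_gene_name, gene_class_of

IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


class MitogenomeParseError(ValueError):
    """Raised when an input annotation file cannot be parsed."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the mitogenome.

    ``strand`` is 'J' (majority) or 'N' (minority); ``start``/``end`` are
    1-based inclusive on the J strand; ``wraps_origin`` marks features whose
    span crosses position 1 of the circle (then ``start > end``).
    """

    name: str
    gene_class: str  # PCG | tRNA | rRNA | control_region | unknown
    strand: str  # J | N
    start: int
    end: int
    wraps_origin: bool = False
    canonical: bool = True

    def __post_init__(self):
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError(
                f"{self.name}: start {self.start} > end {self.end} without wraps_origin"
            )

    def span(self, genome_length: int) -> int:
        """Feature length in bp under circular wrap."""
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def effective_end(self, genome_length: int) -> int:
        """End coordinate on the unrolled axis (may exceed genome_length)."""
        return self.end + genome_length if self.wraps_origin else self.end


@dataclass
class MitogenomeRecord:
    """A (usually circular) annotated mitochondrial genome."""

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start > len(self.sequence) or f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.name} ({f.start}..{f.end}) outside "
                    f"{len(self.sequence)} bp sequence"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def gene_sequences(self, gene_class: str | None = None) -> dict[str, str]:
        """Strand-corrected (coding) sequences, optionally restricted by class."""
        out = {}
        for f in self.features:
            if gene_class is None or f.gene_class == gene_class:
                out[f.name] = extract_feature_seq(self, f)
        return out


def extract_feature_seq(record: MitogenomeRecord, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature (reverse complement for N strand)."""
    s = record.sequence
    if feature.wraps_origin:
        if record.topology != "circular":
            raise ValueError("wraps_origin feature on a linear record")
        arc = s[feature.start - 1 :] + s[: feature.end]
    else:
        arc = s[feature.start - 1 : feature.end]
    return reverse_complement(arc) if feature.strand == "N" else arc


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_FEATURE_KEYS = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature")


def parse_genbank(text: str) -> MitogenomeRecord:
    """Parse a single-record GenBank flat file into a :class:`MitogenomeRecord`.

    Gene names are normalized through :func:`~mitorearr.vocab.canonical_gene_name`;
    unknown names raise a warning and are retained flagged non-canonical.
    """
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise MitogenomeParseError(f"malformed GenBank record: {exc}") from exc
    length = len(rec.seq)
    topology = rec.annotations.get("topology", "linear")
    feats: list[GeneFeature] = []
    for sf in rec.features:
        if sf.type not in _FEATURE_KEYS:
            continue
        raw = (
            sf.qualifiers.get("gene", [None])[0]
            or sf.qualifiers.get("product", [None])[0]
            or sf.qualifiers.get("note", [None])[0]
        )
        if raw is None:
            continue
        name, canonical = canonical_gene_name(raw)
        if sf.type == "misc_feature" and not canonical:
            continue  # unrelated annotation, not a gene
        if not canonical:
            warnings.warn(f"non-canonical gene name {raw!r} retained as-is")
        strand = "N" if sf.location.strand == -1 else "J"
        loc = sf.location
        if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            head, tail = parts[1], parts[0]
            if int(tail.start) == 0 and int(head.end) == length:
                feats.append(
                    GeneFeature(
                        name=name,
                        gene_class=_class_for(name, sf.type),
                        strand=strand,
                        start=int(head.start) + 1,
                        end=int(tail.end),
                        wraps_origin=True,
                        canonical=canonical,
                    )
                )
                continue
        feats.append(
            GeneFeature(
                name=name,
                gene_class=_class_for(name, sf.type),
                strand=strand,
                start=int(loc.start) + 1,
                end=int(loc.end),
                canonical=canonical,
            )
        )
    return MitogenomeRecord(
        id=rec.id or rec.name, sequence=str(rec.seq), topology=topology, features=feats
    )


def _class_for(name: str, sf_type: str) -> str:
    cls = gene_class_of(name)
    if cls != "unknown":
        return cls
    return {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(sf_type, "unknown")


_SF_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control_region": "D-loop"}


def write_genbank(record: MitogenomeRecord) -> str:
    """Serialize to a GenBank flat file (inverse of :func:`parse_genbank`)."""
    seq = Seq(record.sequence)
    rec = SeqRecord(seq, id=record.id, name=record.id[:16], description="mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    rec.annotations["data_file_division"] = "INV"
    length = len(record.sequence)
    rec.features.append(
        SeqFeature(SimpleLocation(0, length, strand=1), type="source",
                   qualifiers={"organism": ["synthetic construct"]})
    )
    for f in record.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, length, strand=strand),
                 SimpleLocation(0, f.end, strand=strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        sft = _SF_TYPE.get(f.gene_class, "misc_feature")
        rec.features.append(SeqFeature(loc, type=sft, qualifiers={"gene": [f.name]}))
    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Feature table + FASTA
# ---------------------------------------------------------------------------

def parse_feature_table(tsv: str, fasta: str) -> MitogenomeRecord:
    """Parse a TSV gene table (columns: name, class, strand, start, end
    [, wraps_origin]) plus a single-sequence FASTA into a record.
    """
    recs = list(SeqIO.parse(io.StringIO(fasta), "fasta"))
    if len(recs) != 1:
        raise MitogenomeParseError(f"expected one FASTA sequence, got {len(recs)}")
    seq = str(recs[0].seq)
    feats: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for lineno, line in enumerate(tsv.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            raise MitogenomeParseError(f"line {lineno}: expected >=5 columns")
        raw, cls, strand, start_s, end_s = cols[:5]
        wraps = len(cols) > 5 and cols[5].strip().lower() in ("1", "true", "yes")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise MitogenomeParseError(f"line {lineno}: bad coordinates") from exc
        if not (1 <= start <= len(seq)) or not (1 <= end <= len(seq)):
            raise MitogenomeParseError(
                f"line {lineno}: {raw}: coordinates outside 1..{len(seq)}"
            )
        if start > end and not wraps:
            raise MitogenomeParseError(
                f"line {lineno}: {raw}: start > end without wraps_origin flag"
            )
        name, canonical = canonical_gene_name(raw)
        if canonical and name not in ("trnL1", "trnL2", "trnS1", "trnS2"):
            seen[name] = seen.get(name, 0) + 1
            if seen[name] > 1:
                warnings.warn(f"duplicate canonical gene {name}")
        if not canonical:
            warnings.warn(f"non-canonical gene name {raw!r} retained as-is")
        feats.append(
            GeneFeature(name=name, gene_class=cls, strand=strand, start=start,
                        end=end, wraps_origin=wraps, canonical=canonical)
        )
    return MitogenomeRecord(id=recs[0].id, sequence=seq, features=feats)


def write_feature_table(record: MitogenomeRecord) -> str:
    lines = ["name\tclass\tstrand\tstart\tend\twraps_origin"]
    for f in record.features:
        lines.append(
            f"{f.name}\t{f.gene_class}\t{f.strand}\t{f.start}\t{f.end}"
            f"\t{'true' if f.wraps_origin else 'false'}"
        )
    return "\n".join(lines) + "\n"


def write_fasta(record: MitogenomeRecord) -> str:
    out = io.StringIO()
    SeqIO.write(SeqRecord(Seq(record.sequence), id=record.id, description=""),
                out, "fasta")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Junction accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    left: str
    right: str
    gap: int  # negative = overlap, 0 = abutting, positive = spacer


@dataclass
class JunctionReport:
    junctions: list[Junction]
    n_overlaps: int
    n_spacers: int
    min_overlap: int | None
    max_overlap: int | None
    longest_spacer: Junction | None
    excluded_nested: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "junctions": [
                {"left": j.left, "right": j.right, "gap": j.gap} for j in self.junctions
            ],
            "n_overlaps": self.n_overlaps,
            "n_spacers": self.n_spacers,
            "min_overlap": self.min_overlap,
            "max_overlap": self.max_overlap,
            "longest_spacer": (
                None
                if self.longest_spacer is None
                else {
                    "left": self.longest_spacer.left,
                    "right": self.longest_spacer.right,
                    "length": self.longest_spacer.gap,
                }
            ),
            "excluded_nested": self.excluded_nested,
        }


def junction_report(record: MitogenomeRecord) -> JunctionReport:
    """Per-adjacent-pair gap accounting: gap = start(next) - end(prev) - 1,
    with circular wrap on the last junction.  Fully nested features are
    excluded (with a warning) so junctions form a linear tiling.
    """
    L = len(record)
    feats = sorted(record.features, key=lambda f: (f.start, -f.effective_end(L)))
    kept: list[GeneFeature] = []
    excluded: list[str] = []
    for f in feats:
        if kept and f.effective_end(L) <= kept[-1].effective_end(L):
            excluded.append(f.name)
            warnings.warn(f"feature {f.name} nested inside {kept[-1].name}; "
                          "excluded from junction accounting")
            continue
        kept.append(f)
    junctions: list[Junction] = []
    if len(kept) >= 2:
        for prev, nxt in zip(kept, kept[1:]):
            junctions.append(
                Junction(prev.name, nxt.name, nxt.start - prev.effective_end(L) - 1)
            )
        if record.topology == "circular":
            last, first = kept[-1], kept[0]
            gap = (first.start + L) - last.effective_end(L) - 1
            junctions.append(Junction(last.name, first.name, gap))
    overlaps = [j for j in junctions if j.gap < 0]
    spacers = [j for j in junctions if j.gap > 0]
    return JunctionReport(
        junctions=junctions,
        n_overlaps=len(overlaps),
        n_spacers=len(spacers),
        min_overlap=min((-j.gap for j in overlaps), default=None),
        max_overlap=max((-j.gap for j in overlaps), default=None),
        longest_spacer=max(spacers, key=lambda j: j.gap, default=None),
        excluded_nested=excluded,
    )


def reverse_complement_record(record: MitogenomeRecord) -> MitogenomeRecord:
    """Whole-record reverse complement with strands flipped (testing aid)."""
    L = len(record)
    feats = []
    for f in record.features:
        # reflection p -> L - p + 1 swaps start/end; wrap status is preserved
        feats.append(
            replace(f, strand=("N" if f.strand == "J" else "J"),
                    start=L - f.end + 1, end=L - f.start + 1)
        )
    return MitogenomeRecord(
        id=record.id, sequence=reverse_complement(record.sequence),
        topology=record.topology, features=feats,
    )
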
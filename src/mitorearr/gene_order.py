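"""Circular signed gene orders and single-event rearrangement classification.

A gene order is a circular list of (canonical gene, strand) tokens; equality is
rotation-invariant.  ``compare_orders`` classifies an observed order against a
reference by generate-and-test over all single rearrangement events: an
adjacent swap of two genes (each keeping its own strand), a contiguous block
transposition, or a block inversion (strands flipped); anything else is
"complex".  Breakpoints are ordered circular adjacencies of the observed order
absent from the reference, so identical orders — and only those — score zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import MitogenomeRecord
from .vocab import ANCESTRAL_ORDER, CANONICAL_GENES

Token = tuple[str, str]  # (gene name, strand J|N)


@dataclass(frozen=True)
class GeneOrder:
    """Circular signed permutation of gene tokens.

    ``origin_token`` fixes the rotation used for serialization (default trnI,
    falling back to the first gene present).
    """

    tokens: tuple[Token, ...]
    origin_token: str = "trnI"

    def __post_init__(self):
        names = [t[0] for t in self.tokens]
        if len(names) != len(set(names)):
            raise ValueError("duplicate genes in order")
        for _, strand in self.tokens:
            if strand not in ("J", "N"):
                raise ValueError(f"bad strand {strand!r}")

    def names(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)

    def rotated_to(self, anchor: str | None = None) -> tuple[Token, ...]:
        """Tokens rotated so the anchor gene comes first."""
        anchor = anchor or self.origin_token
        names = self.names()
        if anchor not in names:
            anchor = names[0]
        i = names.index(anchor)
        return self.tokens[i:] + self.tokens[:i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        if len(self.tokens) != len(other.tokens):
            return False
        if set(self.names()) != set(other.names()):
            return False
        return self.rotated_to(self.names()[0]) == other.rotated_to(self.names()[0])

    def __hash__(self):
        return hash(frozenset(self.tokens))

    def restrict(self, genes: set[str]) -> "GeneOrder":
        return GeneOrder(tuple(t for t in self.tokens if t[0] in genes),
                         origin_token=self.origin_token)

    def to_string(self) -> str:
        return ",".join(
            ("-" if s == "N" else "") + g for g, s in self.rotated_to()
        )

    @classmethod
    def from_string(cls, text: str, origin_token: str = "trnI") -> "GeneOrder":
        tokens = []
        for part in text.strip().split(","):
            part = part.strip()
            if not part:
                continue
            if part.startswith("-"):
                tokens.append((part[1:], "N"))
            else:
                tokens.append((part, "J"))
        return cls(tuple(tokens), origin_token=origin_token)


def extract_gene_order(record: MitogenomeRecord) -> GeneOrder:
    """Canonical features of a record in circular J-strand coordinate order."""
    feats = [f for f in sorted(record.features, key=lambda f: f.start) if f.canonical]
    if not feats:
        raise ValueError("record has no canonical features")
    return GeneOrder(tuple((f.name, f.strand) for f in feats))


def ancestral_insect_order() -> GeneOrder:
    """The 37-gene + control-region ancestral insect arrangement (trnI first)."""
    return GeneOrder(ANCESTRAL_ORDER)


@dataclass(frozen=True)
class RearrangementCall:
    status: str  # identical | adjacent_swap | block_transposition | inversion | complex
    affected_genes: tuple[str, ...]
    window: tuple[str, str] | None  # flanking genes of the affected region
    breakpoint_count: int
    restricted_to: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "affected_genes": list(self.affected_genes),
            "window": list(self.window) if self.window else None,
            "breakpoint_count": self.breakpoint_count,
        }


def _adjacencies(tokens: tuple[Token, ...]) -> set[tuple[Token, Token]]:
    n = len(tokens)
    return {(tokens[i], tokens[(i + 1) % n]) for i in range(n)}


def _breakpoints(observed: tuple[Token, ...], reference: tuple[Token, ...]) -> int:
    # signed ordered adjacencies: zero iff the circular signed orders coincide
    return len(_adjacencies(observed) - _adjacencies(reference))


def _rot_equal(a: tuple[Token, ...], b: tuple[Token, ...]) -> bool:
    return GeneOrder(a) == GeneOrder(b)


def compare_orders(observed: GeneOrder, reference: GeneOrder) -> RearrangementCall:
    """Classify the observed order against the reference.

    Orders over different gene sets are restricted to their intersection (the
    restriction is recorded); disjoint sets are an error.
    """
    common = set(observed.names()) & set(reference.names())
    if not common:
        raise ValueError("gene orders share no genes")
    restricted = tuple(sorted((set(observed.names()) | set(reference.names())) - common))
    obs = observed.restrict(common)
    ref = reference.restrict(common)
    obs_t = obs.rotated_to(sorted(common)[0])
    ref_t = ref.rotated_to(sorted(common)[0])
    n = len(ref_t)
    bps = _breakpoints(obs_t, ref_t)

    if obs == ref:
        return RearrangementCall("identical", (), None, 0, restricted)

    # adjacent swap: two circular neighbors exchange positions, strands kept
    for i in range(n):
        j = (i + 1) % n
        cand = list(ref_t)
        cand[i], cand[j] = cand[j], cand[i]
        if _rot_equal(tuple(cand), obs_t):
            left = ref_t[(i - 1) % n][0]
            right = ref_t[(j + 1) % n][0]
            return RearrangementCall(
                "adjacent_swap", (ref_t[i][0], ref_t[j][0]), (left, right),
                bps, restricted,
            )

    # block transposition: contiguous block (len 1..n-2) moved elsewhere
    best = None
    for start in range(n):
        for blen in range(1, n - 1):
            rot = ref_t[start:] + ref_t[:start]
            block, rest = rot[:blen], rot[blen:]
            for ins in range(1, len(rest) + 1):
                cand = rest[:ins] + block + rest[ins:]
                if _rot_equal(tuple(cand), obs_t):
                    left = rest[ins - 1][0]
                    right = rest[ins % len(rest)][0]
                    score = blen
                    if best is None or score < best[0]:
                        best = (score, tuple(t[0] for t in block), (left, right))
    if best is not None:
        return RearrangementCall(
            "block_transposition", best[1], best[2], bps, restricted
        )

    # inversion: contiguous block reversed with strands flipped
    for start in range(n):
        for blen in range(1, n):
            rot = ref_t[start:] + ref_t[:start]
            block = tuple(
                (g, "N" if s == "J" else "J") for g, s in reversed(rot[:blen])
            )
            cand = block + rot[blen:]
            if _rot_equal(cand, obs_t):
                left = rot[-1][0]
                right = rot[blen][0] if blen < n else rot[0][0]
                return RearrangementCall(
                    "inversion", tuple(t[0] for t in rot[:blen]), (left, right),
                    bps, restricted,
                )

    return RearrangementCall("complex", tuple(sorted(common)), None, bps, restricted)
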
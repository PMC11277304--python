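"""Tandem-duplication-random-loss (TDRL) scenario inference.

A TDRL event duplicates a contiguous block of genes in tandem (2..max copies)
and then deletes all but one copy of each gene.  Losses are cost-free parts of
the single event; copy count is a secondary parsimony criterion.  Strands are
carried through unchanged — a TDRL cannot invert a gene, so windows whose
strands disagree are rejected outright.

Scenario enumeration is exhaustive over (block, copy count, per-gene retained
copy); with ``max_copies`` at least the window size a single event reaches any
same-strand permutation, so one event is always the minimal explanation of a
pure transposition.  Lost copies that sit between the retained genes are the
copies expected to leave pseudogene remnants, which is how remnant evidence
(count and identity of trnW fragments in the spacer) ranks otherwise
equally-parsimonious scenarios: k observed remnants of a gene retained outside
the remnant run force copy_count >= k + 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


@dataclass(frozen=True)
class TDRLScenario:
    duplicated_block: tuple[str, ...]
    block_start: int  # index of the block within the ancestral window
    copy_count: int
    retained_copy: tuple[tuple[str, int], ...]  # gene -> 1-based copy retained
    predicted_order: tuple[str, ...]
    predicted_remnants: tuple[tuple[str, int], ...]  # lost (gene, copy), expansion order
    interior_remnants: tuple[tuple[str, int], ...]   # lost copies between retained genes
    event_count: int

    @property
    def loss_pattern(self) -> dict[str, tuple[int, ...]]:
        """Per gene, the copies lost (complement of the retained copy)."""
        retained = dict(self.retained_copy)
        return {
            g: tuple(c for c in range(1, self.copy_count + 1) if c != retained[g])
            for g in self.duplicated_block
        }

    def to_dict(self) -> dict:
        return {
            "duplicated_block": list(self.duplicated_block),
            "block_start": self.block_start,
            "copy_count": self.copy_count,
            "retained_copy": dict(self.retained_copy),
            "loss_pattern": {g: list(v) for g, v in self.loss_pattern.items()},
            "predicted_order": list(self.predicted_order),
            "predicted_remnants": [list(r) for r in self.predicted_remnants],
            "event_count": self.event_count,
        }


def _strip_strands(window) -> tuple[str, ...]:
    out = []
    for t in window:
        out.append(t[0] if isinstance(t, tuple) else t)
    return tuple(out)


def _check_strands(ancestral, derived) -> None:
    anc = {t[0]: t[1] for t in ancestral if isinstance(t, tuple)}
    der = {t[0]: t[1] for t in derived if isinstance(t, tuple)}
    flipped = [g for g in anc if g in der and anc[g] != der[g]]
    if flipped:
        raise ValueError(
            f"strand changes for {flipped}: TDRL cannot invert genes "
            "(inversion evidence rejects TDRL)"
        )


def apply_scenario(ancestral_window, scenario: TDRLScenario) -> tuple[str, ...]:
    """Deterministic expansion (tandem copies) then deletion of lost copies."""
    window = _strip_strands(ancestral_window)
    b0 = scenario.block_start
    block = scenario.duplicated_block
    if window[b0 : b0 + len(block)] != block:
        raise ValueError("scenario block is not contiguous at block_start")
    retained = dict(scenario.retained_copy)
    if set(retained) != set(block):
        raise ValueError("loss pattern must retain each block gene exactly once")
    for g, c in retained.items():
        if not (1 <= c <= scenario.copy_count):
            raise ValueError(f"retained copy {c} of {g} outside 1..{scenario.copy_count}")
    if scenario.copy_count == 0:  # identity scenario
        return window
    surviving = []
    for copy in range(1, scenario.copy_count + 1):
        for g in block:
            if retained[g] == copy:
                surviving.append(g)
    return window[:b0] + tuple(surviving) + window[b0 + len(block) :]


def _build_scenario(window, b0, blen, copies, retention) -> TDRLScenario:
    block = window[b0 : b0 + blen]
    retained = tuple(zip(block, retention))
    retained_map = dict(retained)
    expansion = [(g, c) for c in range(1, copies + 1) for g in block]
    retained_pos = [
        i for i, (g, c) in enumerate(expansion) if retained_map[g] == c
    ]
    first, last = retained_pos[0], retained_pos[-1]
    lost = [(g, c) for i, (g, c) in enumerate(expansion) if retained_map[g] != c]
    interior = tuple(
        (g, c) for i, (g, c) in enumerate(expansion)
        if retained_map[g] != c and first < i < last
    )
    surviving = tuple(g for g, c in expansion if retained_map[g] == c)
    predicted = window[:b0] + surviving + window[b0 + blen :]
    return TDRLScenario(
        duplicated_block=block, block_start=b0, copy_count=copies,
        retained_copy=retained, predicted_order=predicted,
        predicted_remnants=tuple(lost), interior_remnants=interior,
        event_count=1,
    )


def enumerate_scenarios(ancestral_window, derived_window, max_copies: int = 4
                        ) -> list[TDRLScenario]:
    """All single-TDRL-event scenarios turning the ancestral window into the
    derived window, sorted by (event_count, copy_count, block length).

    The identity scenario (no duplication, event_count 0) is returned alone
    when the windows already agree.
    """
    _check_strands(ancestral_window, derived_window)
    anc = _strip_strands(ancestral_window)
    der = _strip_strands(derived_window)
    if sorted(anc) != sorted(der):
        raise ValueError("windows must contain the same gene set")
    if anc == der:
        return [
            TDRLScenario(
                duplicated_block=(), block_start=0, copy_count=0,
                retained_copy=(), predicted_order=anc, predicted_remnants=(),
                interior_remnants=(), event_count=0,
            )
        ]
    n = len(anc)
    out: list[TDRLScenario] = []
    for b0 in range(n):
        for blen in range(2, n - b0 + 1):
            if anc[:b0] != der[:b0] or anc[b0 + blen :] != der[b0 + blen :]:
                continue  # flanks are fixed; only the block reorders
            for copies in range(2, max_copies + 1):
                for retention in itertools.product(range(1, copies + 1), repeat=blen):
                    s = _build_scenario(anc, b0, blen, copies, retention)
                    if s.predicted_order == der:
                        out.append(s)
    out.sort(key=lambda s: (s.event_count, s.copy_count, len(s.duplicated_block),
                            s.block_start, s.retained_copy))
    return out


@dataclass(frozen=True)
class RemnantEvidence:
    """Observed pseudogene remnants inside the rearranged region, in spacer
    order: e.g. six trnW fragments between the retained trnC and trnW ->
    counts (("trnW", 6),), between ("trnC", "trnW")."""

    counts: tuple[tuple[str, int], ...]
    between: tuple[str, str] | None = None  # flanking retained genes of the spacer


def _remnants_between(s: TDRLScenario, left: str, right: str) -> list[str] | None:
    """Lost genes between the retained copies of left and right in the
    expansion; None if those two are not consecutively retained."""
    retained_map = dict(s.retained_copy)
    if left not in retained_map or right not in retained_map:
        return None
    expansion = [
        (g, c) for c in range(1, s.copy_count + 1) for g in s.duplicated_block
    ]
    kept_idx = [i for i, (g, c) in enumerate(expansion) if retained_map[g] == c]
    li = next((i for i in kept_idx if expansion[i] == (left, retained_map[left])), None)
    ri = next((i for i in kept_idx if expansion[i] == (right, retained_map[right])), None)
    if li is None or ri is None or ri < li:
        return None
    if any(li < k < ri for k in kept_idx):
        return None  # another retained gene sits inside the putative spacer
    return [expansion[i][0] for i in range(li + 1, ri)]


def rank_by_remnants(
    scenarios: list[TDRLScenario],
    observed: RemnantEvidence | list[tuple[str, int]],
) -> list[TDRLScenario]:
    """Rank scenarios by agreement with observed remnant evidence.

    A scenario matches when the lost copies it places inside the observed
    spacer interval (between the two retained flanking genes when given,
    otherwise anywhere between the first and last retained copy) reproduce
    the observed genes in order and count.  Predicted remnants of unobserved
    genes may simply have decayed and do not penalize.  Matching scenarios
    come first; ties resolve by (event count, copy count, block length).
    """
    if isinstance(observed, RemnantEvidence):
        counts, between = observed.counts, observed.between
    else:
        counts, between = tuple(observed), None
    expected = [g for gene, k in counts for g in [gene] * k]
    obs_genes = {gene for gene, _ in counts}

    def matches(s: TDRLScenario) -> bool:
        if s.event_count == 0:
            return not expected
        if between is not None:
            gap = _remnants_between(s, *between)
            if gap is None:
                return False
            return [g for g in gap if g in obs_genes] == expected
        got = [g for g, _ in s.interior_remnants if g in obs_genes]
        return got == expected

    return sorted(
        scenarios,
        key=lambda s: (0 if matches(s) else 1, s.event_count, s.copy_count,
                       len(s.duplicated_block), s.block_start, s.retained_copy),
    )


def render_pathway(ancestral_window, scenario: TDRLScenario) -> str:
    """Human-readable duplication-loss pathway:
    ancestral -> tandem expansion -> losses struck out -> derived."""
    window = _strip_strands(ancestral_window)
    lines = ["ancestral : " + "-".join(window)]
    if scenario.event_count == 0:
        lines.append("derived   : " + "-".join(window) + "   (no event)")
        return "\n".join(lines)
    retained = dict(scenario.retained_copy)
    expansion = []
    for c in range(1, scenario.copy_count + 1):
        for g in scenario.duplicated_block:
            expansion.append(f"{g}({c})" if retained[g] == c else f"[{g}({c})]")
    pre = list(window[: scenario.block_start])
    post = list(window[scenario.block_start + len(scenario.duplicated_block) :])
    lines.append("duplicated: " + "-".join(pre + expansion + post)
                 + f"   (x{scenario.copy_count} tandem copies; [] = lost)")
    lines.append("derived   : " + "-".join(apply_scenario(window, scenario)))
    return "\n".join(lines)
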
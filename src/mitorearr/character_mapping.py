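"""Parsimony mapping of a binary gene-order character on a phylogeny.

The rearrangement (e.g. the trnW/trnC swap) is coded 0 = ancestral order,
1 = rearranged, ? = unknown, at the leaves of a rooted tree; the mapping uses
Hartigan's generalization of Fitch parsimony (exact for binary and polytomous
rooted trees).  A character is a synapomorphy of a clade when exactly one
change is required and it is a 0->1 gain on the edge subtending exactly that
clade.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


class NewickParseError(ValueError):
    pass


@dataclass
class PhyloTree:
    """A rooted tree with uniquely labeled leaves (thin dendropy wrapper)."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels are not unique")

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def support_of(self, *leaves: str) -> float | None:
        """Support value stored on the MRCA node of the given leaves."""
        node = self.tree.mrca(taxon_labels=list(leaves))
        if node is None or node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string (internal-node labels kept as support values)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed newick: {exc}") from exc
    tree.is_rooted = True
    return PhyloTree(tree)


def root_on_outgroup(phylo: PhyloTree, outgroup: str) -> PhyloTree:
    """Reroot so the named leaf is the sister of everything else."""
    tree = phylo.tree.clone(depth=1)
    node = tree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not found")
    tree.to_outgroup_position(node, update_bipartitions=False)
    tree.is_rooted = True
    return PhyloTree(tree)


@dataclass
class CharacterMap:
    leaf_states: dict[str, str]
    min_changes: int
    node_states: dict[int, str]  # node id -> assigned state
    change_edges: frozenset[tuple[str, ...]]  # each edge named by its subtended leaves
    gain_edges: frozenset[tuple[str, ...]]    # 0->1 changes among those
    is_synapomorphy_of: tuple[str, ...] | None

    def to_dict(self) -> dict:
        return {
            "leaf_states": dict(self.leaf_states),
            "min_changes": self.min_changes,
            "change_edges": sorted(list(e) for e in self.change_edges),
            "is_synapomorphy_of": (
                list(self.is_synapomorphy_of) if self.is_synapomorphy_of else None
            ),
        }


_FULL = frozenset({"0", "1"})


def fitch_map(phylo: PhyloTree, states: dict[str, str]) -> CharacterMap:
    """Hartigan/Fitch parsimony for a binary character with missing data.

    ``states`` maps leaf labels to '0', '1' or '?'; leaves absent from the
    mapping are treated as '?', a state for an unknown leaf is an error.
    Returns the minimum change count, one optimal internal assignment, and the
    synapomorphy clade when the map is a single 0->1 gain.
    """
    tree = phylo.tree
    leaves = set(phylo.leaf_labels())
    unknown = set(states) - leaves
    if unknown:
        raise ValueError(f"states given for unknown leaves: {sorted(unknown)}")
    for lab, st in states.items():
        if st not in ("0", "1", "?"):
            raise ValueError(f"bad state {st!r} for {lab}")

    upper: dict[int, frozenset[str]] = {}
    changes = 0
    # up-pass (Hartigan): each node keeps the states with the maximum vote
    # count among its children; cost += n_children - max_votes
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            st = states.get(node.taxon.label, "?")
            upper[id(node)] = _FULL if st == "?" else frozenset({st})
            continue
        votes = {"0": 0, "1": 0}
        for child in node.child_nodes():
            for s in upper[id(child)]:
                votes[s] += 1
        vmax = max(votes.values())
        upper[id(node)] = frozenset(s for s, v in votes.items() if v == vmax)
        changes += len(node.child_nodes()) - vmax

    # down-pass: parent state kept when allowed, else smallest allowed state
    node_states: dict[int, str] = {}
    change_edges: set[tuple[str, ...]] = set()
    gain_edges: set[tuple[str, ...]] = set()
    root = tree.seed_node
    node_states[id(root)] = min(upper[id(root)])
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = node_states[id(node.parent_node)]
        allowed = upper[id(node)]
        state = parent_state if parent_state in allowed else min(allowed)
        node_states[id(node)] = state
        if state != parent_state:
            clade = tuple(sorted(
                lf.taxon.label for lf in node.leaf_iter()
            )) if not node.is_leaf() else (node.taxon.label,)
            change_edges.add(clade)
            if parent_state == "0" and state == "1":
                gain_edges.add(clade)

    synapo = None
    if changes == 1 and len(gain_edges) == 1 and len(change_edges) == 1:
        synapo = next(iter(gain_edges))
    return CharacterMap(
        leaf_states={lab: states.get(lab, "?") for lab in leaves},
        min_changes=changes,
        node_states=node_states,
        change_edges=frozenset(change_edges),
        gain_edges=frozenset(gain_edges),
        is_synapomorphy_of=synapo,
    )


def parse_leaf_states(tsv: str) -> dict[str, str]:
    """TSV of 'leaf<TAB>state' rows (state in {0, 1, ?}); '#' comments allowed."""
    out: dict[str, str] = {}
    for line in tsv.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"bad leaf-state line: {line!r}")
        out[parts[0].strip()] = parts[1].strip()
    return out
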
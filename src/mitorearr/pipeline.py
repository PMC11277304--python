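"""Full-analysis orchestration: composition -> junctions -> gene order ->
spacer/remnant -> TDRL -> (Ka) -> (character mapping), with graceful
degradation of optional stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation_io import (
    MitogenomeRecord,
    junction_report,
    parse_feature_table,
    parse_genbank,
)
from .composition import base_composition, ka_against_reference
from .gene_order import ancestral_insect_order, compare_orders, extract_gene_order
from .character_mapping import fitch_map, parse_leaf_states, read_newick
from .spacer_repeats import (
    RemnantScanParams,
    RepeatSearchParams,
    annotate_trus,
    decompose_tandem,
    extract_spacer,
    scan_remnants,
    trna_library,
)
from .tdrl import RemnantEvidence, enumerate_scenarios, rank_by_remnants, render_pathway

log = logging.getLogger("mitorearr")


def load_record(path: str | Path, table_path: str | Path | None = None) -> MitogenomeRecord:
    """Load a mitogenome from GenBank, or from FASTA + TSV feature table."""
    path = Path(path)
    text = path.read_text()
    if table_path is not None:
        return parse_feature_table(Path(table_path).read_text(), text)
    return parse_genbank(text)


@dataclass
class AnalysisConfig:
    repeat_params: RepeatSearchParams = field(default_factory=RepeatSearchParams)
    remnant_params: RemnantScanParams = field(default_factory=RemnantScanParams)
    tdrl_max_copies: int = 10
    min_spacer_for_repeats: int = 50

    def to_dict(self) -> dict:
        return {
            "repeat_params": vars(self.repeat_params),
            "remnant_params": vars(self.remnant_params),
            "tdrl_max_copies": self.tdrl_max_copies,
            "min_spacer_for_repeats": self.min_spacer_for_repeats,
        }


def analyze_record(
    record: MitogenomeRecord,
    reference: MitogenomeRecord | None = None,
    tree_text: str | None = None,
    leaf_states: dict[str, str] | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full analysis chain on one record; returns a JSON-able report."""
    config = config or AnalysisConfig()
    report: dict = {
        "tool": {"name": "mitorearr", "version": __version__},
        "record_id": record.id,
        "genome_length": len(record),
        "parameters": config.to_dict(),
        "warnings": [],
    }

    comp = base_composition(record.sequence)
    report["composition"] = comp.to_dict()
    report["n_minority_strand_genes"] = sum(
        1 for f in record.features if f.strand == "N"
    )
    report["junctions"] = junction_report(record).to_dict()

    order = extract_gene_order(record)
    call = compare_orders(order, ancestral_insect_order())
    report["gene_order"] = {"order": order.to_string(), "call": call.to_dict()}

    # spacer / remnant / TDRL on the longest spacer if one is worth analyzing
    jr = junction_report(record)
    if jr.longest_spacer and jr.longest_spacer.gap >= config.min_spacer_for_repeats:
        left, right = jr.longest_spacer.left, jr.longest_spacer.right
        try:
            spacer = extract_spacer(record, left, right)
            decomps = decompose_tandem(spacer.seq, config.repeat_params)
            hits = scan_remnants(spacer, trna_library(record), config.remnant_params)
            report["spacer"] = {
                "left": left, "right": right, "length": spacer.length,
                "decompositions": [d.to_dict() for d in decomps],
                "remnant_hits": [h.to_dict() for h in hits],
            }
            if decomps:
                tru = annotate_trus(decomps[0], hits, spacer.seq)
                report["spacer"]["tru_annotation"] = tru.to_dict()
        except ValueError as exc:
            report["warnings"].append(f"spacer stage: {exc}")

    if call.status == "adjacent_swap" and len(call.affected_genes) == 2:
        ref = ancestral_insect_order()
        names = [t[0] for t in ref.rotated_to()]
        n = len(names)
        g1, g2 = call.affected_genes
        idx = names.index(g1)
        if names[(idx + 1) % n] != g2:
            g1, g2 = g2, g1
            idx = names.index(g1)
        anc_window = tuple(names[(idx - 1 + k) % n] for k in range(4))
        der_window = (anc_window[0], anc_window[2], anc_window[1], anc_window[3])
        observed = []
        spacer_info = report.get("spacer", {})
        remnant_genes = [
            h["source_gene"] for h in spacer_info.get("remnant_hits", [])
        ]
        for g in dict.fromkeys(remnant_genes):
            observed.append((g, remnant_genes.count(g)))
        scenarios = enumerate_scenarios(
            anc_window, der_window, max_copies=config.tdrl_max_copies
        )
        between = None
        if spacer_info:
            between = (spacer_info["left"], spacer_info["right"])
        ranked = rank_by_remnants(
            scenarios, RemnantEvidence(tuple(observed), between=between)
        )
        report["tdrl"] = {
            "ancestral_window": list(anc_window),
            "derived_window": list(der_window),
            "observed_remnants": observed,
            "n_scenarios": len(scenarios),
            "top_scenario": ranked[0].to_dict() if ranked else None,
            "pathway": render_pathway(anc_window, ranked[0]) if ranked else None,
        }

    if reference is not None:
        try:
            report["ka"] = ka_against_reference(record, reference).to_dict()
        except ValueError as exc:
            report["warnings"].append(f"Ka stage: {exc}")

    if tree_text is not None and leaf_states is not None:
        try:
            cmap = fitch_map(read_newick(tree_text), leaf_states)
            report["character_map"] = cmap.to_dict()
        except ValueError as exc:
            report["warnings"].append(f"character mapping stage: {exc}")

    return report


def run_full_analysis(
    record_path: str | Path,
    reference_path: str | Path | None = None,
    tree_path: str | Path | None = None,
    leaf_states_path: str | Path | None = None,
    table_path: str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    record = load_record(record_path, table_path)
    reference = load_record(reference_path) if reference_path else None
    tree_text = Path(tree_path).read_text() if tree_path else None
    states = (
        parse_leaf_states(Path(leaf_states_path).read_text())
        if leaf_states_path
        else None
    )
    return analyze_record(record, reference, tree_text, states, config)


# ---------------------------------------------------------------------------
# Deposited-record verification battery
# ---------------------------------------------------------------------------

def verify_deposited_record(path: str | Path) -> dict:
    """Recompute the headline annotation statistics of a deposited mitogenome
    record (e.g. GenBank ON985401): genome length, minority-strand gene count,
    overlap count, longest spacer, tandem-repeat structure of that spacer and
    its tRNA remnants.  Requires a locally available GenBank file."""
    record = load_record(path)
    jr = junction_report(record)
    out = {
        "genome_length": len(record),
        "n_minority_strand_genes": sum(1 for f in record.features if f.strand == "N"),
        "n_gene_overlaps": jr.n_overlaps,
        "n_spacers": jr.n_spacers,
        "longest_spacer_bp": jr.longest_spacer.gap if jr.longest_spacer else 0,
        "longest_spacer_flanks": (
            [jr.longest_spacer.left, jr.longest_spacer.right]
            if jr.longest_spacer else None
        ),
    }
    if jr.longest_spacer and jr.longest_spacer.gap > 50:
        spacer = extract_spacer(record, jr.longest_spacer.left, jr.longest_spacer.right)
        decomps = decompose_tandem(spacer.seq)
        hits = scan_remnants(spacer, trna_library(record))
        if decomps:
            out["tru_period_bp"] = decomps[0].period
            out["tru_copy_number"] = decomps[0].copy_number
            out["tru_partial_unit_bp"] = decomps[0].partial_unit_length
        out["remnant_hits"] = [h.to_dict() for h in hits]
        if hits:
            out["remnant_gene"] = hits[0].source_gene
            out["remnant_length_bp"] = hits[0].length
            out["remnant_total_mismatches"] = sum(h.mismatches for h in hits)
    return out
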
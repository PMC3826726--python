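"""End-to-end orchestration: scan, classify, and cross-strain comparison."""

from __future__ import annotations

import pandas as pd

from .ani import ani as run_ani_pair
from .classify import (DEFAULT_CATALOG, assign_family, classify as
                       classify_element, detect_modules, summarize)
from . import finder
from .genome_io import GenomeSet
from .homology import reciprocal_orthologs


def scan_genome(genome: GenomeSet, mode: str = "keyword", query_proteins=None,
                catalog=DEFAULT_CATALOG, families: bool = False,
                **finder_params):
    """Full single-strain pipeline: integrase anchors -> direct repeats ->
    tRNA association -> element selection -> cargo-module classification.

    Returns (elements, report DataFrame).  With ``families=True`` elements
    are additionally grouped by shared backbone sequence, which can
    promote a family member's label.
    """
    elements = finder.find_elements(genome, mode=mode,
                                    query_proteins=query_proteins,
                                    **finder_params)
    for el in elements:
        feats = [f for f in genome.features
                 if f.replicon_id == el.replicon_id
                 and f.start >= el.start and f.end <= el.end]
        hits = detect_modules(feats, catalog)
        el.classification = classify_element(hits, el.size_bp, features=feats)
    if families and len(elements) > 1:
        seqs = {
            el.element_id:
                genome.record(el.replicon_id).sequence[el.start:el.end]
            for el in elements
        }
        assign_family(elements, seqs)
    report = summarize(elements, strain_id=genome.strain_id)
    return elements, report


def presence_matrix(elements, genome_self: GenomeSet,
                    genome_other: GenomeSet) -> pd.DataFrame:
    """Occurrence codes of scanned elements in another strain.

    ``+``: attL and attR junctions found; ``-, s``: only the attB empty
    site; ``-``: neither (the border/attB PCR typing codes)."""
    code = {"present": "+", "absent_with_empty_site": "-, s", "no_site": "-"}
    rows = []
    for el in elements:
        record = genome_self.record(el.replicon_id)
        status = finder.cross_strain_presence(el, record, genome_other)
        rows.append({
            "element_id": el.element_id,
            "replicon": el.replicon_id,
            "status": status,
            "code": code[status],
        })
    return pd.DataFrame(rows, columns=["element_id", "replicon", "status", "code"])


def compare_strains(genome_a: GenomeSet, genome_b: GenomeSet,
                    proteome_a=None, proteome_b=None,
                    run_ani: bool = True, scan: bool = True) -> dict:
    """Two-strain comparison: orthologs/unique genes, ANI and element
    presence codes in both directions."""
    out: dict = {}
    if proteome_a is not None and proteome_b is not None:
        table = reciprocal_orthologs(proteome_a, proteome_b)
        out["orthologs"] = table
        out["n_pairs"] = len(table.pairs)
        out["unique_a"] = len(table.unique_a)
        out["unique_b"] = len(table.unique_b)
    if run_ani:
        result = run_ani_pair(genome_a, genome_b)
        out["ani"] = result
        out["ani_percent"] = result.ani_percent
    if scan:
        elements_a, report_a = scan_genome(genome_a)
        elements_b, report_b = scan_genome(genome_b)
        out["report_a"] = report_a
        out["report_b"] = report_b
        out["presence_a_in_b"] = presence_matrix(elements_a, genome_a, genome_b)
        out["presence_b_in_a"] = presence_matrix(elements_b, genome_b, genome_a)
    return out
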
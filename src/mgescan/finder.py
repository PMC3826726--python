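"""Integrase-anchored detection of integrative mobile genetic elements.

The detection logic mirrors how tyrosine-integrase elements are laid out
in bacterial chromosomes: site-specific integration at the 3' end of a
tRNA (or another small RNA) gene duplicates the attachment site, leaving
the element flanked by a pair of direct repeats (attL/attR) with the
integrase gene just inside one of them.  The pipeline therefore

1. maps integrase CDS (by product keyword/COG id, or by similarity to
   query proteins),
2. searches the sequence around each integrase for direct repeats within
   a bounded span,
3. associates repeat pairs with nearby tRNA 3' ends,
4. selects the best-supported pair per anchor and builds the candidate
   element, and
5. reconstructs the attB (empty site) and attI (excised circle) junction
   sequences that excision would produce.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .composition import gc_content
from .genome_io import Feature, GenomeRecord, GenomeSet, extract, reverse_complement
from .seedext import Match, maximal_matches

# search defaults: flank window around the anchor, maximum element span,
# minimum repeat length and repeat identity
DEFAULT_FLANK_WINDOW = 10_000
DEFAULT_MAX_SPAN = 250_000
DEFAULT_MIN_REPEAT = 14
DEFAULT_MIN_REPEAT_ID = 0.9
#: repeat length required of pairs with no tRNA/tmRNA association: short
#: repeats are accepted only on the strength of an RNA-gene att target
MIN_FREE_REPEAT = 18
MIN_ELEMENT_SIZE = 5_000
JUNCTION_FLANK = 200
TRNA_ASSOC_DIST = 100

INTEGRASE_RE = re.compile(r"integrase|recombinase", re.IGNORECASE)
INTEGRASE_EXCLUDE_RE = re.compile(r"transposase|retron", re.IGNORECASE)
INTEGRASE_COG = "COG4974"
#: products of small RNA genes that can serve as att targets besides tRNAs
RNA_TARGET_RE = re.compile(r"tmRNA|ssrA|srrA", re.IGNORECASE)


@dataclass(frozen=True)
class IntegraseAnchor:
    """A CDS identified as a (putative) site-specific integrase."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    detection_mode: str  # "keyword" or "similarity"


@dataclass
class DirectRepeatPair:
    """attL/attR candidate: two same-orientation copies of an att site.

    The detected lengths are those of the ungapped common core of the two
    copies, so a 3'-truncated right repeat yields equal detected lengths on
    both sides (the shared prefix).
    """

    replicon_id: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    identity: float
    trna_id: str | None = None
    att_label: str = "non-tRNA"
    #: the RNA gene's 3' end falls inside the repeat itself (a true att
    #: site contains the conserved tRNA 3' end), not merely nearby
    att_overlap: bool = False
    #: bases of the RNA gene covered by the repeat interval — a genuine
    #: att repeat overlaps the tRNA tail it preserves, chance repeats
    #: that merely straddle the 3' end cover less of the gene
    att_overlap_len: int = 0

    @property
    def left_len(self) -> int:
        return self.left_end - self.left_start

    @property
    def right_len(self) -> int:
        return self.right_end - self.right_start

    @property
    def span(self) -> int:
        return self.right_end - self.left_start

    @property
    def is_trna_associated(self) -> bool:
        return self.trna_id is not None


@dataclass
class CandidateElement:
    """A putative integrative element: extent, anchor, repeats, junctions."""

    element_id: str
    replicon_id: str
    start: int
    end: int
    anchor: IntegraseAnchor
    repeat: DirectRepeatPair
    orf_count: int = 0
    gc_percent: float = 0.0
    att_b: str = ""
    att_i: str = ""
    classification: object = None

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def find_integrases(features, mode: str = "keyword", query_proteins=None,
                    records=None) -> list[IntegraseAnchor]:
    """Map integrase CDS.

    ``keyword`` mode matches product text against an integrase pattern
    while excluding transposases/retrons, or accepts a COG4974 qualifier.
    ``similarity`` mode translates each CDS and keeps those aligning to any
    query protein at >=30% identity over >=50% of the query.
    """
    if mode == "keyword":
        out = []
        for f in features:
            if f.ftype != "CDS":
                continue
            cog_hit = INTEGRASE_COG in " ".join(str(v) for v in f.qualifiers.values())
            if cog_hit or (INTEGRASE_RE.search(f.product)
                           and not INTEGRASE_EXCLUDE_RE.search(f.product)):
                out.append(IntegraseAnchor(f.feature_id, f.replicon_id,
                                           f.start, f.end, "keyword"))
        return out
    if mode == "similarity":
        if not query_proteins:
            raise ValueError("similarity mode requires query proteins")
        if records is None:
            raise ValueError("similarity mode requires replicon records")
        return _find_integrases_similarity(features, query_proteins, records)
    raise ValueError(f"unknown integrase detection mode {mode!r}")


def _find_integrases_similarity(features, query_proteins, records,
                                min_identity: float = 0.3,
                                min_query_cov: float = 0.5):
    from Bio.Seq import Seq

    from .homology import ProteinRecord, align_pair

    rec_by_id = {r.replicon_id: r for r in records}
    out = []
    for f in features:
        if f.ftype != "CDS" or f.replicon_id not in rec_by_id:
            continue
        nt = extract(rec_by_id[f.replicon_id], f.start, f.end, f.strand)
        aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate()).rstrip("*")
        if not aa or "*" in aa:
            aa = aa.replace("*", "X") or "X"
        cds_prot = ProteinRecord(f.feature_id, "query", aa)
        for q in query_proteins:
            hit = align_pair(q, cds_prot)
            qcov = hit.alignment_length / len(q.sequence)
            if hit.identity >= min_identity and qcov >= min_query_cov:
                out.append(IntegraseAnchor(f.feature_id, f.replicon_id,
                                           f.start, f.end, "similarity"))
                break
    return out


def find_direct_repeats(record: GenomeRecord, anchor: IntegraseAnchor,
                        flank_window: int = DEFAULT_FLANK_WINDOW,
                        max_span: int = DEFAULT_MAX_SPAN,
                        min_len: int = DEFAULT_MIN_REPEAT,
                        min_identity: float = DEFAULT_MIN_REPEAT_ID,
                        ) -> list[DirectRepeatPair]:
    """Direct repeats flanking a possible element around one integrase.

    The flank region (``flank_window`` either side of the anchor) is
    compared against the sequence within ``max_span`` of the anchor; every
    maximal same-orientation match of length >= ``min_len`` at identity
    >= ``min_identity`` whose two copies bracket the anchor becomes an
    attL/attR candidate, sorted by score (matched bases).
    """
    n = len(record)
    f0 = max(0, anchor.start - flank_window)
    f1 = min(n, anchor.end + flank_window)
    if f1 - f0 < min_len * 2:
        warnings.warn(f"anchor {anchor.feature_id}: no usable flank")
        return []
    r0 = max(0, anchor.start - max_span)
    r1 = min(n, anchor.end + max_span)
    flank = record.sequence[f0:f1]
    region = record.sequence[r0:r1]
    pairs: dict[tuple, DirectRepeatPair] = {}
    for m in maximal_matches(flank, region, k=10, min_len=min_len,
                             min_identity=min_identity):
        a0, a1 = m.a_start + f0, m.a_end + f0
        b0, b1 = m.b_start + r0, m.b_end + r0
        if a0 < b1 and b0 < a1:  # self match / overlapping copies
            continue
        (l0, l1), (r0_, r1_) = sorted([(a0, a1), (b0, b1)])
        if r1_ - l0 > max_span:
            continue
        if not (l0 <= anchor.start and anchor.end <= r1_):
            continue
        key = (l0, l1, r0_, r1_)
        if key not in pairs:
            pairs[key] = DirectRepeatPair(
                replicon_id=record.replicon_id,
                left_start=l0, left_end=l1, right_start=r0_, right_end=r1_,
                identity=m.identity,
            )
    return sorted(
        pairs.values(),
        key=lambda p: (-(p.left_len * p.identity), p.span, p.left_start),
    )


def associate_trna(pair: DirectRepeatPair, features,
                   max_dist: int = TRNA_ASSOC_DIST) -> DirectRepeatPair:
    """Label a repeat pair with the tRNA (or tmRNA-like RNA gene) whose 3'
    end lies within ``max_dist`` bp of attL (attR is checked second).

    The label follows the att-site convention ``AminoAcid-ANTICODON``;
    pairs with no nearby RNA gene keep the label ``non-tRNA``.  When two
    RNA genes abut the same repeat a dual comma-separated label is
    emitted.  ``att_overlap`` is set when the RNA gene's 3' end lies
    inside the repeat interval itself (within a few bases of slack for
    truncated repeat cores) — the geometry a genuine att site must have.
    """
    candidates = [f for f in features if f.replicon_id == pair.replicon_id
                  and (f.ftype == "tRNA" or RNA_TARGET_RE.search(f.product or ""))]

    def near(interval, f):
        s, e = interval
        tp = f.three_prime
        return (s - max_dist) <= tp <= (e + max_dist)

    def overlaps(interval, f):
        # the 3' end must sit inside the repeat (end slack covers cores
        # truncated just short of it); a repeat starting past the 3' end
        # cannot be the preserved att site
        s, e = interval
        return s <= f.three_prime <= (e + 5)

    def covered(interval, f):
        s, e = interval
        return max(0, min(e, f.end) - max(s, f.start))

    for interval in ((pair.left_start, pair.left_end),
                     (pair.right_start, pair.right_end)):
        hits = [f for f in candidates if near(interval, f)]
        if hits:
            over = [f for f in hits if overlaps(interval, f)]
            pair.att_overlap = bool(over)
            pair.att_overlap_len = max(
                (covered(interval, f) for f in over), default=0)
            labels = []
            for f in sorted(hits, key=lambda f: f.start):
                if f.ftype == "tRNA":
                    labels.append(f.anticodon_label or f.product or f.feature_id)
                else:
                    labels.append(f.product or f.feature_id)
            pair.trna_id = hits[0].feature_id
            pair.att_label = ", ".join(labels)
            return pair
    return pair


def select_element(pairs, anchor: IntegraseAnchor, record: GenomeRecord,
                   features, min_size: int = MIN_ELEMENT_SIZE,
                   max_size: int = DEFAULT_MAX_SPAN,
                   min_free_repeat: int = MIN_FREE_REPEAT,
                   element_id: str = "element") -> CandidateElement | None:
    """Pick the best repeat pair for one anchor and build the element.

    Priority: repeats containing an RNA-gene 3' end (true att geometry)
    first, then any tRNA-associated pair, then longest repeat, then
    smallest span (fully ordered, hence deterministic).  Pairs whose span
    falls outside ``[min_size, max_size]`` are not reportable, and pairs
    without an RNA-gene att target must reach ``min_free_repeat`` bp —
    isolated short repeats on random sequence are not element evidence.
    """
    usable = [p for p in pairs if min_size <= p.span <= max_size
              and (p.is_trna_associated or p.left_len >= min_free_repeat)]
    if not usable:
        return None
    usable.sort(key=lambda p: (not p.att_overlap, not p.is_trna_associated,
                               -p.att_overlap_len, -p.left_len,
                               p.span, p.left_start))
    best = usable[0]
    start, end = best.left_start, best.right_end
    orf_count = sum(
        1 for f in features
        if f.ftype == "CDS" and f.replicon_id == record.replicon_id
        and f.start >= start and f.end <= end
    )
    element = CandidateElement(
        element_id=element_id,
        replicon_id=record.replicon_id,
        start=start, end=end,
        anchor=anchor, repeat=best,
        orf_count=orf_count,
        gc_percent=round(100.0 * gc_content(record.sequence[start:end]), 2),
    )
    element.att_b, element.att_i = junctions(element, record)
    return element


def junctions(element: CandidateElement, record: GenomeRecord,
              flank: int = JUNCTION_FLANK) -> tuple[str, str]:
    """Reconstruct the two junction sequences created by excision.

    attB (empty site): upstream flank + one repeat copy + downstream flank —
    what the chromosome looks like after the element leaves.
    attI (circular intermediate): cargo end + repeat + cargo start — the
    junction formed when the excised element circularizes.
    Flanks truncated by a replicon edge are returned shorter, with a warning.
    """
    rep = element.repeat
    seq = record.sequence
    up0 = rep.left_start - flank
    down1 = rep.right_end + flank
    if up0 < 0 or down1 > len(seq):
        warnings.warn(
            f"{element.element_id}: junction flank truncated at replicon edge")
        up0 = max(0, up0)
        down1 = min(len(seq), down1)
    repeat_seq = seq[rep.left_start:rep.left_end]
    att_b = seq[up0:rep.left_start] + repeat_seq + seq[rep.right_end:down1]
    inside_end = seq[max(rep.left_end, rep.right_start - flank):rep.right_start]
    inside_start = seq[rep.left_end:min(rep.right_start, rep.left_end + flank)]
    att_i = inside_end + seq[rep.right_start:rep.right_end] + inside_start
    return att_b, att_i


def excise(element: CandidateElement, record: GenomeRecord) -> tuple[str, str]:
    """Simulate excision: return (empty-site replicon sequence, excised
    circle sequence, linearized at its att junction).

    Re-inserting the circle immediately after the retained repeat copy of
    the empty site reconstructs the original replicon exactly; the repeat
    appears once in each product.
    """
    rep = element.repeat
    seq = record.sequence
    empty = seq[:rep.left_end] + seq[rep.right_end:]
    circle = seq[rep.left_end:rep.right_end]
    return empty, circle


def _junction_found(query: str, records, min_identity: float = 0.9,
                    min_cov: float = 0.8) -> bool:
    """Search a junction sequence against replicons (both strands) with
    banded edit-distance alignment; a hit needs >= ``min_identity`` over
    the full query, or over its central ``min_cov`` fraction."""
    import edlib

    def hits(q, target):
        k = int(len(q) * (1.0 - min_identity))
        res = edlib.align(q, target, mode="HW", task="distance", k=k)
        return res["editDistance"] != -1

    trim = int(len(query) * (1.0 - min_cov) / 2.0)
    core = query[trim:len(query) - trim] if trim else query
    for rec in records:
        for target in (rec.sequence, reverse_complement(rec.sequence)):
            if hits(query, target) or (trim and hits(core, target)):
                return True
    return False


def cross_strain_presence(element: CandidateElement, record: GenomeRecord,
                          other: GenomeSet, flank: int = JUNCTION_FLANK,
                          ) -> str:
    """Classify an element's status in another strain.

    ``present``: both integrated junctions (attL and attR, element/host
    boundaries) are found; ``absent_with_empty_site``: the attB empty-site
    junction is found instead; ``no_site``: neither.  These mirror the
    +, "-, s" and "-" occurrence codes of border/attB PCR typing.
    """
    rep = element.repeat
    seq = record.sequence
    att_l = seq[max(0, rep.left_start - flank):min(len(seq), rep.left_end + flank)]
    att_r = seq[max(0, rep.right_start - flank):min(len(seq), rep.right_end + flank)]
    records = other.records
    if _junction_found(att_l, records) and _junction_found(att_r, records):
        return "present"
    if _junction_found(element.att_b, records):
        return "absent_with_empty_site"
    return "no_site"


def find_elements(genome: GenomeSet, mode: str = "keyword",
                  query_proteins=None,
                  flank_window: int = DEFAULT_FLANK_WINDOW,
                  max_span: int = DEFAULT_MAX_SPAN,
                  min_len: int = DEFAULT_MIN_REPEAT,
                  min_identity: float = DEFAULT_MIN_REPEAT_ID,
                  min_size: int = MIN_ELEMENT_SIZE,
                  min_free_repeat: int = MIN_FREE_REPEAT,
                  ) -> list[CandidateElement]:
    """Run anchor -> repeat -> tRNA association -> selection over a strain.

    Anchors are processed independently; overlapping elements are all
    reported (nesting is resolved downstream, not here).
    """
    anchors = find_integrases(genome.features, mode=mode,
                              query_proteins=query_proteins,
                              records=genome.records)
    elements = []
    counter = 0
    for anchor in anchors:
        record = genome.record(anchor.replicon_id)
        pairs = find_direct_repeats(record, anchor, flank_window=flank_window,
                                    max_span=max_span, min_len=min_len,
                                    min_identity=min_identity)
        pairs = [associate_trna(p, genome.features) for p in pairs]
        counter += 1
        element = select_element(
            pairs, anchor, record, genome.features,
            min_size=min_size, max_size=max_span,
            min_free_repeat=min_free_repeat,
            element_id=f"{genome.strain_id}_el{counter}",
        )
        if element is not None:
            elements.append(element)
    return elements
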
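"""Proteome comparisons: paralogs, reciprocal best hits, unique genes, COG tallies.

Strain proteomes are compared all-vs-all with local protein alignment
(BLOSUM62, affine gaps) and a 95% aligned-region identity cutoff, the
convention under which a pair of genes is called orthologous when each is
the other's best hit.  Genes left without a reciprocal partner form the
strain-specific (flexible) gene complement.  A k-mer prefilter keeps the
all-vs-all comparison tractable; it is required never to drop a pair whose
true identity reaches the cutoff over >= 50 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_SCORE = 50.0
PREFILTER_K = 5
PREFILTER_SHARED = 10


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein of one strain."""

    gene_id: str
    strain_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: illegal residues {sorted(bad)}")


@dataclass
class HomologyHit:
    """A local alignment between two proteins.

    ``identity`` is identities / alignment length, with internal gap
    columns counted in the length (end overhangs are outside the local
    alignment and never counted).  ``coverage`` is the aligned fraction of
    the shorter protein.
    """

    query_id: str
    subject_id: str
    identity: float
    alignment_length: int
    coverage: float
    score: float


@dataclass
class OrthologTable:
    """Reciprocal-best-hit pairs plus per-strain unique gene sets."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unique_a: set[str] = field(default_factory=set)
    unique_b: set[str] = field(default_factory=set)


def read_proteome(path, strain_id: str) -> list[ProteinRecord]:
    """Load a protein FASTA as one strain's proteome."""
    out = [
        ProteinRecord(rec.id, strain_id, str(rec.seq).upper().rstrip("*"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not out:
        raise ValueError(f"{path}: no protein records")
    return out


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: a gap of length g costs 11 + g
    al.open_gap_score = -12.0
    al.extend_gap_score = -1.0
    return al


_ALIGNER = _aligner()


def align_pair(a: ProteinRecord, b: ProteinRecord) -> HomologyHit:
    """Locally align two proteins and report identity, coverage and score."""
    seq_a = a.sequence.replace("*", "X")
    seq_b = b.sequence.replace("*", "X")
    alignments = _ALIGNER.align(seq_a, seq_b)
    if len(alignments) == 0 or alignments.score <= 0:
        return HomologyHit(a.gene_id, b.gene_id, 0.0, 0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / length if length else 0.0
    blocks = aln.aligned
    span_a = int(blocks[0][-1][1] - blocks[0][0][0]) if len(blocks[0]) else 0
    span_b = int(blocks[1][-1][1] - blocks[1][0][0]) if len(blocks[1]) else 0
    shorter = min(len(seq_a), len(seq_b))
    coverage = (span_a if len(seq_a) <= len(seq_b) else span_b) / shorter
    return HomologyHit(a.gene_id, b.gene_id, identity, int(length),
                       min(coverage, 1.0), float(alignments.score))


def _kmers(seq: str, k: int = PREFILTER_K) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _prefilter_pass(ka: set[str], kb: set[str]) -> bool:
    """Candidate pair survives when it shares enough k-mers; the threshold
    degrades for proteins too short to hold PREFILTER_SHARED k-mers, so
    genuinely near-identical short pairs are never dropped."""
    need = min(PREFILTER_SHARED, len(ka), len(kb))
    if need == 0:
        return True
    return len(ka & kb) >= need


def best_hits(proteome_a, proteome_b, min_identity: float = DEFAULT_MIN_IDENTITY,
              min_score: float = DEFAULT_MIN_SCORE, prefilter: bool = True,
              ) -> dict[str, HomologyHit]:
    """Best passing subject for every query.

    Ties on score break by higher identity, then lexicographic subject id;
    queries with no hit passing the thresholds are omitted.
    """
    kb = {p.gene_id: _kmers(p.sequence) for p in proteome_b} if prefilter else {}
    out: dict[str, HomologyHit] = {}
    for qa in proteome_a:
        ka = _kmers(qa.sequence) if prefilter else None
        best: HomologyHit | None = None
        for sb in proteome_b:
            if prefilter and not _prefilter_pass(ka, kb[sb.gene_id]):
                continue
            hit = align_pair(qa, sb)
            if hit.identity < min_identity or hit.score < min_score:
                continue
            if best is None or (hit.score, hit.identity, ) > (best.score, best.identity) \
                    or (hit.score == best.score and hit.identity == best.identity
                        and hit.subject_id < best.subject_id):
                best = hit
        if best is not None:
            out[qa.gene_id] = best
    return out


def reciprocal_orthologs(proteome_a, proteome_b,
                         min_identity: float = DEFAULT_MIN_IDENTITY,
                         min_score: float = DEFAULT_MIN_SCORE,
                         prefilter: bool = True) -> OrthologTable:
    """Reciprocal best hits at the identity cutoff; everything unpaired is
    strain-specific."""
    ab = best_hits(proteome_a, proteome_b, min_identity, min_score, prefilter)
    ba = best_hits(proteome_b, proteome_a, min_identity, min_score, prefilter)
    pairs = []
    paired_a, paired_b = set(), set()
    for a_id, hit in sorted(ab.items()):
        b_id = hit.subject_id
        back = ba.get(b_id)
        if back is not None and back.subject_id == a_id:
            pairs.append((a_id, b_id))
            paired_a.add(a_id)
            paired_b.add(b_id)
    unique_a = {p.gene_id for p in proteome_a} - paired_a
    unique_b = {p.gene_id for p in proteome_b} - paired_b
    return OrthologTable(pairs=pairs, unique_a=unique_a, unique_b=unique_b)


def paralog_clusters(proteome, min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_score: float = DEFAULT_MIN_SCORE,
                     prefilter: bool = True) -> list[set[str]]:
    """Single-linkage clusters of genes related at >= the identity cutoff
    within one proteome (self-matches excluded).  Singletons are returned as
    size-1 clusters, so the non-redundant gene count is ``len(clusters)``."""
    ids = [p.gene_id for p in proteome]
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    km = {p.gene_id: _kmers(p.sequence) for p in proteome} if prefilter else {}
    for i, a in enumerate(proteome):
        for b in proteome[i + 1:]:
            if prefilter and not _prefilter_pass(km[a.gene_id], km[b.gene_id]):
                continue
            hit = align_pair(a, b)
            if hit.identity >= min_identity and hit.score >= min_score:
                parent[find(a.gene_id)] = find(b.gene_id)
    clusters: dict[str, set[str]] = {}
    for g in ids:
        clusters.setdefault(find(g), set()).add(g)
    return sorted(clusters.values(), key=lambda s: sorted(s)[0])


def nonredundant_count(proteome, **kwargs) -> int:
    """Number of distinct genes after collapsing >=95%-identical paralogs."""
    return len(paralog_clusters(proteome, **kwargs))


#: COG category letters as used in the functional-category legend
COG_CATEGORIES = frozenset("LDKJOCGEFHPIQMNTUV")


def cog_tally(gene_sets: dict[str, list[str]],
              category_map: dict[str, str]) -> dict[str, dict[str, float]]:
    """Percentage of genes per COG category for each named gene set.

    Genes without a category assignment are excluded from the denominator.
    Unknown category letters raise ``ValueError``.
    """
    bad = set(category_map.values()) - COG_CATEGORIES
    if bad:
        raise ValueError(f"unknown COG category letters: {sorted(bad)}")
    out: dict[str, dict[str, float]] = {}
    for name, genes in gene_sets.items():
        counts: dict[str, int] = {}
        total = 0
        for g in genes:
            cat = category_map.get(g)
            if cat is None:
                continue
            counts[cat] = counts.get(cat, 0) + 1
            total += 1
        out[name] = {c: 100.0 * k / total for c, k in sorted(counts.items())} if total else {}
    return out
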
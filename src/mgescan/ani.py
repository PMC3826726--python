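"""Fragment-based average nucleotide identity (ANI) between genome sets.

The query genome is cut into consecutive 1020-bp fragments, each fragment
is searched against the subject genome with blastn, and ANI is the mean
percent identity of fragments retained at >=30% identity over >=70% of
their length — the Goris fragment convention.  Reported one-way (query vs
subject) and as the symmetric mean of the two directions.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import GenomeRecord

DEFAULT_FRAGMENT = 1020
DEFAULT_MIN_ID = 0.3
DEFAULT_MIN_COV = 0.7
MAX_N_FRACTION = 0.2  # fragments with more N than this are skipped


@dataclass
class AniResult:
    """One-way fragment ANI."""

    ani_percent: float
    n_fragments_used: int
    n_fragments_total: int
    identities: list[float] = field(default_factory=list)


@dataclass
class SymmetricAni:
    forward: AniResult
    reverse: AniResult

    @property
    def ani_percent(self) -> float:
        return (self.forward.ani_percent + self.reverse.ani_percent) / 2.0


def _as_records(genome) -> list[GenomeRecord]:
    if isinstance(genome, GenomeRecord):
        return [genome]
    if hasattr(genome, "records"):  # GenomeSet
        return list(genome.records)
    return list(genome)


def fragment_genome(records, fragment: int = DEFAULT_FRAGMENT):
    """Cut replicons into consecutive fragments; the trailing remainder is
    kept (its own length is used for the coverage filter).  Fragments with
    more than 20% N are dropped."""
    out = []
    for rec in _as_records(records):
        seq = rec.sequence
        for i, start in enumerate(range(0, len(seq), fragment)):
            piece = seq[start:start + fragment]
            if len(piece) < 100:
                continue
            if piece.count("N") / len(piece) > MAX_N_FRACTION:
                continue
            out.append((f"{rec.replicon_id}__frag{i}", piece))
    return out


def ani_oneway(query, subject, fragment: int = DEFAULT_FRAGMENT,
               min_id: float = DEFAULT_MIN_ID, min_cov: float = DEFAULT_MIN_COV,
               ) -> AniResult:
    """ANI of ``query`` fragments against the ``subject`` genome."""
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastn/makeblastdb not found on PATH")
    frags = fragment_genome(query, fragment)
    if not frags:
        raise ValueError("query genome produced no usable fragments")
    with tempfile.TemporaryDirectory(prefix="mgescan_ani_") as tmp:
        tmp = Path(tmp)
        sub_fa = tmp / "subject.fasta"
        with open(sub_fa, "w") as fh:
            for rec in _as_records(subject):
                fh.write(f">{rec.replicon_id}\n{rec.sequence}\n")
        frag_fa = tmp / "frags.fasta"
        with open(frag_fa, "w") as fh:
            for fid, seq in frags:
                fh.write(f">{fid}\n{seq}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(sub_fa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        proc = subprocess.run(
            [
                "blastn", "-query", str(frag_fa), "-db", str(sub_fa),
                "-task", "blastn", "-evalue", "1e-15", "-dust", "no",
                "-xdrop_gap_final", "150",
                "-outfmt", "6 qseqid pident length qlen bitscore",
            ],
            check=True, capture_output=True, text=True,
        )
    best: dict[str, tuple[float, float, int, int]] = {}
    for line in proc.stdout.splitlines():
        qid, pident, length, qlen, bits = line.split("\t")
        key = (float(bits), float(pident))
        if qid not in best or key > best[qid][:2]:
            best[qid] = (float(bits), float(pident), int(length), int(qlen))
    identities = []
    for qid, (bits, pident, length, qlen) in best.items():
        if pident / 100.0 >= min_id and length >= min_cov * qlen:
            identities.append(pident)
    if not identities:
        raise ValueError("no fragment passed the identity/coverage filters")
    return AniResult(
        ani_percent=sum(identities) / len(identities),
        n_fragments_used=len(identities),
        n_fragments_total=len(frags),
        identities=identities,
    )


def ani(genome_a, genome_b, fragment: int = DEFAULT_FRAGMENT,
        min_id: float = DEFAULT_MIN_ID, min_cov: float = DEFAULT_MIN_COV,
        ) -> SymmetricAni:
    """Symmetric fragment ANI: mean of A-vs-B and B-vs-A one-way values."""
    fwd = ani_oneway(genome_a, genome_b, fragment, min_id, min_cov)
    rev = ani_oneway(genome_b, genome_a, fragment, min_id, min_cov)
    return SymmetricAni(forward=fwd, reverse=rev)
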
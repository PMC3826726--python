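"""Genome and feature data model plus FASTA/GFF3/BED/TSV input-output.

All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive GFF3 convention happens only at the I/O boundary.  Replicons are
linear by default; circular topology must be declared explicitly and is the
only case where interval wraparound is allowed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: three-letter amino-acid code -> one used in att-site labels like "Met-CAT"
_AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Sec", "Pyl", "fMet",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Malformed input file or inconsistent genome/feature data."""


@dataclass
class GenomeRecord:
    """One replicon: a chromosome or plasmid sequence.

    Parameters
    ----------
    replicon_id : unique identifier within a genome set.
    sequence : uppercase DNA over ``{A, C, G, T, N}``.
    topology : ``"linear"`` (default) or ``"circular"``.
    """

    replicon_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"{self.replicon_id}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise GenomeIOError(f"unknown topology {self.topology!r}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise GenomeIOError(
                f"{self.replicon_id}: illegal character {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """An annotated interval (CDS, tRNA, rRNA or other) on a replicon."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    ftype: str
    product: str = ""
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise GenomeIOError(
                f"{self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.ftype in ("CDS", "tRNA") and self.strand not in ("+", "-"):
            raise GenomeIOError(
                f"{self.feature_id}: {self.ftype} requires strand + or -"
            )

    @property
    def three_prime(self) -> int:
        """Position of the 3' end (end for + strand, start for - strand)."""
        return self.end if self.strand == "+" else self.start

    @property
    def anticodon_label(self) -> str | None:
        """Att-site style label ``"AminoAcid-ANTICODON"`` for tRNA features."""
        if self.ftype != "tRNA":
            return None
        aa, ac = _parse_trna_product(self.product, self.qualifiers)
        if ac is None:
            return None
        return f"{aa}-{ac}" if aa else ac


@dataclass
class GenomeSet:
    """A strain: its replicons and their features."""

    strain_id: str
    records: list[GenomeRecord] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.replicon_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise GenomeIOError(f"{self.strain_id}: duplicate replicon ids")
        known = set(ids)
        for f in self.features:
            if f.replicon_id not in known:
                raise GenomeIOError(
                    f"feature {f.feature_id}: unknown replicon {f.replicon_id}"
                )

    def record(self, replicon_id: str) -> GenomeRecord:
        for r in self.records:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def features_on(self, replicon_id: str, ftype: str | None = None) -> list[Feature]:
        out = [f for f in self.features if f.replicon_id == replicon_id]
        if ftype is not None:
            out = [f for f in out if f.ftype == ftype]
        return sorted(out, key=lambda f: (f.start, f.end))


_TRNA_RE = re.compile(
    r"tRNA[-_ ]([A-Za-z]{3,4})(?:[-_ ]?\(?([A-Za-z]{3})\)?)?", re.IGNORECASE
)


def _parse_trna_product(product: str, qualifiers: dict) -> tuple[str | None, str | None]:
    """Extract (amino acid, anticodon) from product text like ``tRNA-Lys-CTT``
    or ``tRNA-Met (cat)``; an explicit ``anticodon`` qualifier wins."""
    aa = None
    ac = qualifiers.get("anticodon")
    m = _TRNA_RE.search(product or "")
    if m:
        cand = m.group(1).capitalize()
        if cand in _AA3 or cand.lower() == "fmet":
            aa = cand
        if ac is None and m.group(2):
            ac = m.group(2)
    return aa, (ac.upper() if ac else None)


def read_fasta(path: str | Path, topology: str | dict | None = None) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is converted to T; any residue outside
    ``{A,C,G,T,N}`` raises :class:`GenomeIOError` naming its position.
    ``topology`` may be a single value for all records or a mapping
    ``replicon_id -> topology``; records default to linear.
    """
    records = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise GenomeIOError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().replace("U", "T")
        if isinstance(topology, dict):
            topo = topology.get(entry.id, "linear")
        else:
            topo = topology or "linear"
        records.append(GenomeRecord(entry.id, seq, topo))
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records")
    return records


#: documented TSV feature dialect: tab-separated, header line, internal
#: (0-based half-open) coordinates.
TSV_FEATURE_COLUMNS = [
    "feature_id", "replicon_id", "start", "end", "strand", "ftype", "product",
]


def read_features(path: str | Path, dialect: str = "gff3") -> list[Feature]:
    """Read features from GFF3 (1-based inclusive) or the package TSV dialect.

    GFF3 coordinates are converted to 0-based half-open.  The ``product``
    attribute is carried verbatim; tRNA anticodons are parsed from product
    text shaped like ``tRNA-Lys-CTT`` / ``tRNA-Met (cat)`` or taken from an
    ``anticodon`` attribute.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "tsv":
        return _read_feature_tsv(path)
    raise GenomeIOError(f"unknown feature dialect {dialect!r}")


def _read_gff3(path: str | Path) -> list[Feature]:
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", keep_order=True,
            merge_strategy="create_unique", sort_attribute_values=True,
        )
    except Exception as exc:
        raise GenomeIOError(f"{path}: not parseable as GFF3 ({exc})") from exc
    features = []
    for i, rec in enumerate(db.all_features()):
        ftype = rec.featuretype if rec.featuretype in ("CDS", "tRNA", "rRNA") else "other"
        if rec.strand not in ("+", "-", ".", "?"):
            raise GenomeIOError(f"{path}: unknown strand symbol {rec.strand!r}")
        if rec.start is None or rec.end is None:
            raise GenomeIOError(
                f"{path}: feature {i + 1} has no coordinates (malformed GFF3)")
        product = (rec.attributes.get("product") or [""])[0]
        quals = {k: v[0] for k, v in rec.attributes.items() if k != "product"}
        fid = rec.id or (rec.attributes.get("ID") or [f"feature{i}"])[0]
        features.append(
            Feature(
                feature_id=fid,
                replicon_id=rec.seqid,
                start=rec.start - 1,  # GFF3 is 1-based inclusive
                end=rec.end,
                strand=rec.strand if rec.strand in ("+", "-") else "+",
                ftype=ftype,
                product=product,
                qualifiers=quals,
            )
        )
    return features


def _read_feature_tsv(path: str | Path) -> list[Feature]:
    features = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(TSV_FEATURE_COLUMNS)] != TSV_FEATURE_COLUMNS:
            raise GenomeIOError(f"{path}: bad TSV header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            features.append(
                Feature(
                    feature_id=row["feature_id"],
                    replicon_id=row["replicon_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    ftype=row["ftype"],
                    product=row.get("product", ""),
                )
            )
    return features


def extract(record: GenomeRecord, start: int, end: int, strand: str = "+") -> str:
    """Extract ``[start, end)`` from a replicon; ``-`` returns the reverse
    complement.  On circular replicons ``end`` may exceed the length and the
    interval wraps around the origin."""
    n = len(record)
    if start < 0 or start >= n or end <= start:
        raise GenomeIOError(f"invalid interval [{start}, {end}) on {record.replicon_id}")
    if end > n:
        if record.topology != "circular":
            raise GenomeIOError(
                f"interval [{start}, {end}) exceeds linear replicon "
                f"{record.replicon_id} of length {n}"
            )
        if end - start > n:
            raise GenomeIOError("wraparound interval longer than replicon")
        seq = record.sequence[start:] + record.sequence[: end - n]
    else:
        seq = record.sequence[start:end]
    return reverse_complement(seq) if strand == "-" else seq


def write_intervals(elements, path: str | Path, format: str = "tsv") -> None:
    """Write intervals to BED (0-based half-open), GFF3 (1-based inclusive)
    or the package TSV dialect; TSV and GFF3 round-trip through
    :func:`read_features`.

    ``elements`` may be :class:`Feature` objects or anything exposing
    ``replicon_id``, ``start``, ``end`` and optionally ``strand``/``ftype``.
    """
    if format not in ("bed", "gff3", "tsv"):
        raise GenomeIOError(f"unknown interval format {format!r}")
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
        if format == "tsv":
            fh.write("\t".join(TSV_FEATURE_COLUMNS) + "\n")
        for i, el in enumerate(elements):
            name = getattr(el, "feature_id", None) or getattr(el, "element_id", f"iv{i}")
            strand = getattr(el, "strand", "+")
            ftype = getattr(el, "ftype", "other")
            product = getattr(el, "product", "")
            if format == "bed":
                fh.write(f"{el.replicon_id}\t{el.start}\t{el.end}\t{name}\t0\t{strand}\n")
            elif format == "gff3":
                attrs = f"ID={name}"
                if product:
                    attrs += f";product={product}"
                fh.write(
                    f"{el.replicon_id}\tmgescan\t{ftype}\t{el.start + 1}\t{el.end}"
                    f"\t.\t{strand}\t.\t{attrs}\n"
                )
            else:
                fh.write(
                    f"{name}\t{el.replicon_id}\t{el.start}\t{el.end}\t{strand}"
                    f"\t{ftype}\t{product}\n"
                )
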
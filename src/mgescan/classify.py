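"""Cargo-module detection and ICE/IME/GI/prophage classification.

Integrative elements are told apart by what they carry, not by how they
were found: a mating-pair-formation type IV secretion system (virB/trb
genes) makes an element self-transmissible (ICE); a relaxase plus
coupling protein without the mating apparatus makes it mobilizable (IME);
a phage regulatory/structural module (cI/cII/Cro/Xis, capsid, terminase)
marks a prophage; and a repeat-flanked integrase-bearing region >= 5 kb
with none of these signatures is a genomic island (GI).  Toxin-antitoxin
and partition modules are detected as stabilization evidence, and
elements sharing long high-identity backbones are grouped into families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .seedext import maximal_matches

T4SS_MIN_GENES = 4          # distinct mating-pair genes to call a T4SS
PHAGE_MIN_TAGS = 3          # distinct phage tags to call a prophage
GI_MIN_SIZE = 5_000
FAMILY_MIN_BLOCK = 5_000    # individual shared-block floor
FAMILY_MIN_SHARED = 25_000  # summed shared sequence to join a family
FAMILY_MIN_ID = 0.9
TA_MAX_INTERVENING = 2      # genes allowed between toxin and antitoxin


@dataclass(frozen=True)
class CatalogEntry:
    tag: str
    patterns: tuple[str, ...]
    role: str = "module"      # module | t4ss | toxin | antitoxin
    cog: str | None = None


def _e(tag, patterns, role="module", cog=None):
    return CatalogEntry(tag, tuple(patterns), role, cog)


#: default product-keyword catalog; user-editable via TSV
DEFAULT_CATALOG: tuple[CatalogEntry, ...] = (
    _e("int", [r"\bintegrase\b", r"tyrosine recombinase"], cog="COG4974"),
    _e("xis", [r"\bexcisionase\b", r"\bxis\b"], cog="COG1257"),
    _e("cI", [r"\bcI\b.{0,20}(repressor|regulator)", r"repressor protein cI"],
       cog="COG2932"),
    _e("cII", [r"\bcII\b"], cog="pfam05269"),
    _e("cro", [r"\bcro\b"], cog="COG4197"),
    _e("phage_struct", [r"capsid", r"terminase", r"tail protein", r"portal"]),
    # mating-pair formation (T4SS) genes: each name counted separately
    _e("t4ss", [rf"\bvirB{i}\b" for i in range(1, 12)]
       + [rf"\btrb{c}\b" for c in "BCDEFGHIJKLN"]
       + [r"mating pair formation"], role="t4ss"),
    _e("virD2", [r"\bvirD2\b", r"\brelaxase\b", r"\bmobA\b", r"\btraI\b"]),
    _e("virD4", [r"\bvirD4\b", r"\btraD\b", r"coupling protein"]),
    _e("parAB", [r"\bparA\b", r"\bparB\b", r"\bparAB\b", r"partition"]),
    _e("parB_thiF", [r"parB[-/ ]thiF"]),
    _e("prtrc", [r"\bPRTRC\b"]),
    _e("tox_VapC", [r"\bvapC\b"], role="toxin"),
    _e("tox_MazF", [r"\bmazF\b"], role="toxin"),
    _e("tox_HigB", [r"\bhigB\b"], role="toxin"),
    _e("tox_HicA", [r"\bhicA\b"], role="toxin"),
    _e("tox_RelE", [r"\brelE\b"], role="toxin"),
    _e("tox_HipA", [r"\bhipA\b"], role="toxin"),
    _e("anti_YefM", [r"\byefM\b"], role="antitoxin"),
    _e("anti_MazE", [r"\bmazE\b"], role="antitoxin"),
    _e("anti_HigA", [r"\bhigA\b"], role="antitoxin"),
    _e("anti_HicB", [r"\bhicB\b"], role="antitoxin"),
    _e("anti_RelB", [r"\brelB\b"], role="antitoxin"),
    _e("anti_Phd", [r"\bphd\b"], role="antitoxin"),
    _e("anti_HipB", [r"\bhipB\b"], role="antitoxin"),
)


def load_catalog(path) -> tuple[CatalogEntry, ...]:
    """Load a catalog TSV with columns tag, patterns (;-separated), role,
    cog (optional)."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, row in df.iterrows():
        entries.append(CatalogEntry(
            tag=row["tag"],
            patterns=tuple(str(row["patterns"]).split(";")),
            role=row.get("role", "module") if pd.notna(row.get("role")) else "module",
            cog=row["cog"] if "cog" in df.columns and pd.notna(row["cog"]) else None,
        ))
    return tuple(entries)


@dataclass(frozen=True)
class ModuleHit:
    tag: str
    feature_id: str
    role: str
    matched: str        # the pattern or gene name that matched


@dataclass
class Classification:
    label: str                               # ICE | IME | GI | prophage | unclassified
    evidence: set[str] = field(default_factory=set)
    t4ss_genes: set[str] = field(default_factory=set)
    ta_pairs: list[tuple[str, str]] = field(default_factory=list)
    orphan_ta: list[str] = field(default_factory=list)
    family: str | None = None
    by_family: bool = False


def detect_modules(features, catalog=DEFAULT_CATALOG) -> list[ModuleHit]:
    """Match CDS product strings against the module catalog; one CDS may
    hit several tags.  COG ids in qualifiers are honored as hits too."""
    if not catalog:
        raise ValueError("empty module catalog")
    hits = []
    for f in features:
        if f.ftype != "CDS":
            continue
        text = f.product or ""
        quals = " ".join(str(v) for v in f.qualifiers.values())
        for entry in catalog:
            if entry.cog and entry.cog in quals:
                hits.append(ModuleHit(entry.tag, f.feature_id, entry.role, entry.cog))
                continue
            for pat in entry.patterns:
                if re.search(pat, text, re.IGNORECASE):
                    hits.append(ModuleHit(entry.tag, f.feature_id, entry.role, pat))
                    break
    return hits


def pair_toxin_antitoxin(hits, features) -> tuple[list, list]:
    """Pair toxin and antitoxin CDS lying within TA_MAX_INTERVENING genes
    of each other (greedy nearest matching); returns (pairs, orphans).

    Pairs are (toxin ModuleHit, antitoxin ModuleHit)."""
    cds = [f for f in features if f.ftype == "CDS"]
    order = {f.feature_id: i for i, f in enumerate(sorted(cds, key=lambda f: f.start))}
    toxins = [h for h in hits if h.role == "toxin" and h.feature_id in order]
    antis = [h for h in hits if h.role == "antitoxin" and h.feature_id in order]
    candidates = []
    for t in toxins:
        for a in antis:
            d = abs(order[t.feature_id] - order[a.feature_id])
            if 0 < d <= TA_MAX_INTERVENING + 1:
                candidates.append((d, t, a))
    candidates.sort(key=lambda c: (c[0], c[1].feature_id, c[2].feature_id))
    used_t, used_a, pairs = set(), set(), []
    for d, t, a in candidates:
        if t.feature_id in used_t or a.feature_id in used_a:
            continue
        pairs.append((t, a))
        used_t.add(t.feature_id)
        used_a.add(a.feature_id)
    orphans = [h.tag for h in toxins if h.feature_id not in used_t]
    orphans += [h.tag for h in antis if h.feature_id not in used_a]
    return pairs, orphans


def classify(hits, size_bp: int, features=None) -> Classification:
    """Apply the classification rules in order.

    1. phage regulatory/structural set (>= PHAGE_MIN_TAGS distinct phage
       tags) without a T4SS -> prophage;
    2. mating-pair T4SS (>= T4SS_MIN_GENES distinct virB/trb genes) -> ICE;
    3. relaxase and coupling protein without the mating-pair set -> IME;
    4. size >= 5 kb -> GI;
    5. otherwise unclassified.
    The order is total, so exactly one label results.
    """
    tags = {h.tag for h in hits}
    t4ss_genes = {h.matched for h in hits if h.role == "t4ss"}
    has_t4ss = len(t4ss_genes) >= T4SS_MIN_GENES
    phage_tags = tags & {"xis", "cI", "cII", "cro", "phage_struct"}
    cls = Classification(label="unclassified", evidence=tags, t4ss_genes=t4ss_genes)
    if features is not None:
        cls.ta_pairs, cls.orphan_ta = pair_toxin_antitoxin(hits, features)
    if len(phage_tags) >= PHAGE_MIN_TAGS and not has_t4ss:
        cls.label = "prophage"
    elif has_t4ss:
        cls.label = "ICE"
    elif "virD2" in tags and "virD4" in tags:
        cls.label = "IME"
    elif size_bp >= GI_MIN_SIZE:
        cls.label = "GI"
    return cls


def assign_family(elements, sequences: dict[str, str],
                  min_block: int = FAMILY_MIN_BLOCK,
                  min_shared: int = FAMILY_MIN_SHARED,
                  min_identity: float = FAMILY_MIN_ID) -> dict[str, str]:
    """Group elements sharing long, high-identity backbone sequence.

    Two elements join a family when their ungapped shared blocks
    (individually >= ``min_block``) sum to >= ``min_shared`` at
    >= ``min_identity``.  Families are connected components; within a
    family, GI/unclassified members are promoted to the label of a
    conjugation-competent member (ICE, else IME) with ``by_family`` set.
    Returns {element_id: family_id}.
    """
    ids = [el.element_id for el in elements]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, ea in enumerate(elements):
        for eb in elements[i + 1:]:
            blocks = maximal_matches(
                sequences[ea.element_id], sequences[eb.element_id],
                k=16, min_len=min_block, min_identity=min_identity,
            )
            shared = sum(b.length for b in blocks)
            if shared >= min_shared:
                parent[find(ea.element_id)] = find(eb.element_id)
    groups: dict[str, list] = {}
    for el in elements:
        groups.setdefault(find(el.element_id), []).append(el)
    families = {}
    for n, (_, members) in enumerate(sorted(groups.items()), start=1):
        fam = f"F{n}"
        labels = {el.classification.label for el in members
                  if el.classification is not None}
        promote = "ICE" if "ICE" in labels else ("IME" if "IME" in labels else None)
        for el in members:
            families[el.element_id] = fam
            if el.classification is not None:
                el.classification.family = fam
                if promote and el.classification.label in ("GI", "unclassified"):
                    el.classification.label = promote
                    el.classification.by_family = True
    return families


_TYPE_PREFIX = {"ICE": "ICE", "IME": "IME", "GI": "GI",
                "prophage": "PP", "unclassified": "U"}


def summarize(elements, strain_id: str = "") -> pd.DataFrame:
    """Render classified elements as a report table.

    One row per element: auto-generated MGE_ID (<Type><strain>.<n>), type,
    coordinates, size, ORF count, G+C %, att label and DR lengths rendered
    ``DR (l, r)``.
    """
    rows = []
    counters: dict[str, int] = {}
    for el in elements:
        label = el.classification.label if el.classification else "unclassified"
        prefix = _TYPE_PREFIX.get(label, "U")
        counters[prefix] = counters.get(prefix, 0) + 1
        cls = el.classification
        rows.append({
            "MGE_ID": f"{prefix}{strain_id}.{counters[prefix]}",
            "type": label,
            "replicon": el.replicon_id,
            "start": el.start,
            "end": el.end,
            "size_bp": el.size_bp,
            "orf_count": el.orf_count,
            "gc_percent": f"{el.gc_percent:.2f}",
            "att": el.repeat.att_label,
            "dr": f"DR ({el.repeat.left_len}, {el.repeat.right_len})",
            "modules": ";".join(sorted(cls.evidence)) if cls else "",
            "ta_pairs": ";".join(
                f"{t.tag.split('_', 1)[1]}/{a.tag.split('_', 1)[1]}"
                for t, a in (cls.ta_pairs if cls else [])),
            "family": cls.family if cls else None,
            "by_family": cls.by_family if cls else False,
        })
    columns = ["MGE_ID", "type", "replicon", "start", "end", "size_bp",
               "orf_count", "gc_percent", "att", "dr", "modules",
               "ta_pairs", "family", "by_family"]
    return pd.DataFrame(rows, columns=columns)
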
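"""Synthetic strain pairs with ground-truthed integrative elements.

The generator emulates the genome architecture the detection pipeline is
built for: a multi-replicon genome (a ~61% G+C chromosome, a lower-G+C
megaplasmid and small plasmids), integrative elements of 10-250 kb whose
~57% G+C cargo is flanked by direct repeats of possibly unequal length,
with the left repeat overlapping the 3' end of a tRNA (or tmRNA) gene and
an integrase CDS just inside it.  Paired "strains" are derived from a
common ancestor: strain-specific elements leave an empty attachment site
in the strain that lacks them, and a configurable background divergence
separates the two sequences.  Proteome pairs with exactly controlled
ortholog identities and planted strain-specific genes are generated as a
separate channel, so reciprocal-best-hit behaviour around the 95% cutoff
is testable against exact ground truth.

Everything is driven by a single seed; the same seed reproduces the same
output byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genome_io import Feature, GenomeRecord, GenomeSet
from .homology import ProteinRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: codon per amino acid, chosen to sit closest to 57% G+C cargo composition
_CODON_FOR_AA = {}
for _codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
    _aa = str(Seq(_codon).translate())
    if _aa == "*":
        continue
    _gc = sum(b in "GC" for b in _codon) / 3.0
    cur = _CODON_FOR_AA.get(_aa)
    if cur is None or abs(_gc - 0.57) < abs(cur[1] - 0.57):
        _CODON_FOR_AA[_aa] = (_codon, _gc)
_CODON_FOR_AA = {aa: c for aa, (c, _) in _CODON_FOR_AA.items()}

#: CDS product strings realized for each module tag; these are drawn from
#: the classifier's keyword catalog so simulator and classifier stay
#: contract-coupled.
MODULE_PRODUCTS: dict[str, list[str]] = {
    "int": ["site-specific integrase"],
    "xis": ["excisionase Xis"],
    "cI": ["cI repressor protein"],
    "cII": ["cII protein"],
    "cro": ["Cro protein"],
    "phage_struct": ["phage capsid protein", "terminase large subunit",
                     "phage tail protein"],
    "t4ss": ["TrbB mating pair formation protein",
             "TrbC conjugal transfer protein", "TrbE conjugal transfer protein",
             "TrbL conjugal transfer protein", "VirB4 secretion component"],
    "virD2": ["VirD2 relaxase"],
    "virD4": ["VirD4 coupling protein"],
    "parAB": ["ParA partition protein", "ParB partition protein"],
    "prtrc": ["PRTRC system protein"],
    "ta_mazFE": ["MazF toxin", "MazE antitoxin"],
    "ta_vapC_phd": ["VapC toxin", "Phd antitoxin"],
    "ta_higBA": ["HigB toxin", "HigA antitoxin"],
    "ta_hicAB": ["HicA toxin", "HicB antitoxin"],
    "ta_hipAB": ["HipA toxin", "HipB antitoxin"],
}

CLASS_DEFAULT_MODULES = {
    "prophage": ("int", "xis", "cI", "cII", "cro", "phage_struct"),
    "ICE": ("int", "t4ss", "parAB", "ta_mazFE"),
    "IME": ("int", "virD2", "virD4"),
    "GI": ("int",),
}


@dataclass(frozen=True)
class ImplantSpec:
    """One ground-truthed element to integrate into one or both strains."""

    element_id: str
    element_class: str            # prophage | ICE | IME | GI
    size_bp: int
    dr_left_len: int = 77
    dr_right_len: int = 46
    anticodon: str | None = "CAT"  # None -> tmRNA (srrA-like) att target
    module_inventory: tuple[str, ...] = ()
    insert_replicon: str = "chromosome"
    cargo_gc: float = 0.57
    strains: tuple[str, ...] = ("A", "B")
    backbone_id: str | None = None   # elements sharing an id share backbone
    backbone_len: int = 0
    backbone_divergence: float = 0.03

    def __post_init__(self):
        if self.size_bp < 1000:
            raise ValueError(f"{self.element_id}: size_bp must be >= 1000")
        if not 10 <= self.dr_right_len <= self.dr_left_len <= 800:
            raise ValueError(
                f"{self.element_id}: repeat lengths must satisfy "
                "10 <= right <= left <= 800")
        if self.size_bp < self.dr_left_len + self.dr_right_len + 2000:
            raise ValueError(f"{self.element_id}: element too small for its repeats")
        if self.element_class not in CLASS_DEFAULT_MODULES:
            raise ValueError(f"unknown element class {self.element_class!r}")

    @property
    def modules(self) -> tuple[str, ...]:
        return self.module_inventory or CLASS_DEFAULT_MODULES[self.element_class]


@dataclass(frozen=True)
class OrthologSpec:
    """One gene shared by both strains at a designed protein identity."""

    length_aa: int = 250
    identity: float = 1.0


@dataclass
class SimConfig:
    """Study-condition defaults for a simulated strain pair."""

    seed: int = 0
    replicons: tuple = (
        ("chromosome", 1_200_000, "linear", 0.61),
        ("megaplasmid", 120_000, "circular", 0.55),
        ("plasmid1", 28_000, "circular", 0.59),
        ("plasmid2", 10_000, "circular", 0.50),
    )
    implants: tuple[ImplantSpec, ...] = ()
    orthologs: tuple[OrthologSpec, ...] = tuple(
        [OrthologSpec(250, i) for i in
         [1.0] * 6 + [0.98] * 6 + [0.96] * 4 + [0.92] * 4 + [0.90] * 4]
    )
    unique_a: int = 6
    unique_b: int = 8
    divergence: float = 0.02      # strain B substitution rate vs the ancestor
    trna_per_replicon: int = 24
    host_cds_spacing: int = 4000
    repeat_mutation_rate: float = 0.0  # optional noise over att repeats


def default_implants() -> tuple[ImplantSpec, ...]:
    """The default element cohort: two strains carrying seven elements each
    (three shared), spanning the size, repeat-length and att-target
    geometry of naturally observed tRNA-anchored elements (9.9-208 kb,
    repeats 14-738 bp, truncated right repeats, a tmRNA-targeted
    prophage, ICE/IME/GI cargo types and a shared ICE backbone family)."""
    return (
        ImplantSpec("prophage_A", "prophage", 59_363, 14, 14, None,
                    strains=("A",)),
        ImplantSpec("ICE1_A", "ICE", 71_960, 77, 46, "CAT", strains=("A",),
                    module_inventory=("int", "t4ss", "parAB", "ta_higBA")),
        ImplantSpec("GI1", "GI", 13_719, 77, 77, "CCG",
                    module_inventory=("int", "ta_vapC_phd", "ta_mazFE")),
        ImplantSpec("GI3_A", "GI", 45_079, 76, 45, "CTT", strains=("A",),
                    module_inventory=("int", "ta_hipAB", "ta_vapC_phd")),
        ImplantSpec("GI4_A", "GI", 104_967, 738, 738, "GGA", strains=("A",)),
        ImplantSpec("GI5", "GI", 9_952, 77, 45, "TCT"),
        ImplantSpec("ICE2_A", "ICE", 183_318, 77, 47, "GTT", strains=("A",),
                    module_inventory=("int", "xis", "cI", "cII", "cro", "t4ss",
                                      "parAB", "ta_hicAB"),
                    backbone_id="ICE2", backbone_len=100_000),
        ImplantSpec("ICE1_B", "ICE", 104_341, 77, 46, "CAT", strains=("B",),
                    module_inventory=("int", "t4ss", "parAB", "ta_mazFE")),
        ImplantSpec("GI2_B", "GI", 50_579, 77, 46, "GCT", strains=("B",),
                    module_inventory=("int", "ta_hipAB")),
        ImplantSpec("IME1_B", "IME", 80_923, 89, 18, "CGA", strains=("B",)),
        ImplantSpec("ICE2_B", "ICE", 208_271, 76, 50, "CTT", strains=("B",),
                    module_inventory=("int", "xis", "cI", "cII", "cro", "t4ss",
                                      "parAB", "ta_hicAB"),
                    backbone_id="ICE2", backbone_len=100_000),
        ImplantSpec("ICE3_B", "ICE", 157_371, 77, 47, "ACG", strains=("B",),
                    module_inventory=("int", "t4ss", "prtrc")),
    )


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed, implants=default_implants())


@dataclass
class TruthElement:
    """Ground truth for one implanted element in one strain."""

    element_id: str
    strain: str
    element_class: str
    replicon_id: str
    start: int
    end: int
    attl_start: int
    attl_end: int
    attr_start: int
    attr_end: int
    dr_left_len: int
    dr_right_len: int
    att_label: str
    modules: tuple[str, ...]
    integrase_id: str
    cargo_gc: float
    n_orfs: int

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass
class StrainPair:
    """A simulated pair of strains plus all ground truth."""

    config: SimConfig
    genome_a: GenomeSet
    genome_b: GenomeSet
    proteome_a: list[ProteinRecord]
    proteome_b: list[ProteinRecord]
    truth_elements: list[TruthElement]
    ortholog_truth: dict

    def truth_for(self, strain: str) -> list[TruthElement]:
        return [t for t in self.truth_elements if t.strain == strain]

    def truth_df(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truth_elements])


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    """i.i.d. bases at the requested G+C, split evenly G/C and A/T."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at ``rate``; every substitution changes the base."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    codes = code[arr]
    mask = (rng.random(arr.size) < rate) & (codes >= 0)
    idx = np.nonzero(mask)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(codes[idx] + shift) % 4]
    return arr.tobytes().decode()


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _mutate_protein(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Mutate exactly round(L*(1-identity)) distinct positions."""
    n_mut = max(0, int(round(len(seq) * (1.0 - min(identity, 1.0)))))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        choices = [a for a in _AA20 if a != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def reverse_translate(protein: str) -> str:
    """Deterministic reverse translation (one codon per residue) + TAA stop."""
    return "".join(_CODON_FOR_AA[aa] for aa in protein) + "TAA"


def _alt_base(avoid: set[str]) -> str:
    for b in "ACGT":
        if b not in avoid:
            return b
    return "A"


def _anticodon_label(anticodon: str) -> str:
    codon = str(Seq(anticodon).reverse_complement())
    aa = str(Seq(codon).translate())
    return f"{seq3(aa)}-{anticodon.upper()}"


def _build_cargo(spec: ImplantSpec, rng: np.random.Generator,
                 backbones: dict) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Cargo sequence (between attL and attR) plus CDS layout.

    Returns (sequence, [(rel_start, rel_end, strand, product)]); relative
    coordinates are from the cargo start (i.e. attL end).
    """
    cargo_len = spec.size_bp - spec.dr_left_len - spec.dr_right_len
    seq = list(random_dna(rng, cargo_len, spec.cargo_gc))
    if spec.backbone_id is not None and spec.backbone_len:
        if spec.backbone_id not in backbones:
            backbones[spec.backbone_id] = random_dna(
                rng, spec.backbone_len, spec.cargo_gc)
            bb = backbones[spec.backbone_id]
        else:
            bb = _mutate(backbones[spec.backbone_id],
                         spec.backbone_divergence, rng)
        # backbone occupies the tail of the cargo, leaving room for modules
        off = max(0, cargo_len - len(bb) - 200)
        bb = bb[: cargo_len - off]
        seq[off:off + len(bb)] = list(bb)
    cds: list[tuple[int, int, str, str]] = []
    pos = 100
    integrase_nt = reverse_translate(_random_protein(rng, 399))
    seq[pos:pos + len(integrase_nt)] = list(integrase_nt)
    cds.append((pos, pos + len(integrase_nt), "+", MODULE_PRODUCTS["int"][0]))
    pos += len(integrase_nt) + 120
    for tag in spec.modules:
        if tag == "int":
            continue
        products = MODULE_PRODUCTS[tag]
        for prod in products:
            length = 600
            if pos + length + 200 > cargo_len:
                break
            cds.append((pos, pos + length, "+", prod))
            pos += length + (60 if tag.startswith("ta_") else 150)
    # filler ORFs through the rest of the cargo
    while pos + 1100 < cargo_len:
        cds.append((pos, pos + 900, "+", "hypothetical protein"))
        pos += 1200
    return "".join(seq), cds


def _place_loci(rng: np.random.Generator, length: int, count: int) -> list[int]:
    """Evenly slotted, jittered att-locus positions with wide separation."""
    margin = 30_000
    if count == 0:
        return []
    slot = (length - 2 * margin) // count
    if slot < 12_000:
        raise ValueError("replicon too short for the requested implants")
    return sorted(
        margin + i * slot + int(rng.integers(0, max(1, slot - 10_000)))
        for i in range(count)
    )


_TRNA_POOL = ["GCC", "GTT", "GAT", "TGC", "CAA", "TTC", "CTG", "GAA",
              "GTG", "AAT", "TAG", "TTT", "GGT", "TGG", "CCA", "GTA"]


def simulate_strain_pair(config: SimConfig) -> StrainPair:
    """Build two strains from a common ancestor per the configuration.

    Each implant is integrated so that its attL overlaps the 3' end of a
    generated tRNA (or tmRNA) gene, the right repeat is a possibly
    truncated copy of the left, and the integrase CDS sits within 5 kb
    inside attL.  A strain lacking an element retains the empty
    attachment site.  The truth table records exact extents, repeat
    coordinates, class labels and module inventories.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_seq, rng_feat, rng_cargo, rng_div, rng_prot = (
        np.random.default_rng(s) for s in ss.spawn(5))

    implants_by_rep: dict[str, list[ImplantSpec]] = {}
    for spec in config.implants:
        implants_by_rep.setdefault(spec.insert_replicon, []).append(spec)
    rep_names = [r[0] for r in config.replicons]
    for spec in config.implants:
        if spec.insert_replicon not in rep_names:
            raise ValueError(f"{spec.element_id}: unknown replicon "
                             f"{spec.insert_replicon}")

    backbones: dict[str, str] = {}
    cargo_store = {s.element_id: _build_cargo(s, rng_cargo, backbones)
                   for s in config.implants}

    strain_records: dict[str, list[GenomeRecord]] = {"A": [], "B": []}
    strain_features: dict[str, list[Feature]] = {"A": [], "B": []}
    truth: list[TruthElement] = []

    for rep_name, rep_len, topology, gc in config.replicons:
        ancestor = random_dna(rng_seq, rep_len, gc)
        specs = implants_by_rep.get(rep_name, [])
        loci = _place_loci(rng_feat, rep_len, len(specs))
        # host features on the ancestor (shared by both strains)
        host_feats: list[tuple] = []  # (start, end, strand, ftype, product)
        blocked = []
        att_info = []  # (spec, attl_start_anc, att_seq_written)
        for spec, locus in zip(specs, loci):
            dl = spec.dr_left_len
            overlap = min(20, dl)
            t0 = locus
            t1 = t0 + 76
            a0 = t1 - overlap
            if spec.anticodon is not None:
                label = _anticodon_label(spec.anticodon)
                product = f"tRNA-{label}"
                ftype = "tRNA"
            else:
                product = "srrA tmRNA"
                ftype = "other"
            host_feats.append((t0, t1, "+", ftype, product))
            blocked.append((t0 - 1000, a0 + dl + 1000))
            att_info.append((spec, a0))
        # generic host tRNAs and CDS, away from att loci
        def free(s, e):
            return all(e <= b0 or s >= b1 for b0, b1 in blocked)

        n_trna = config.trna_per_replicon if rep_len >= 100_000 else 0
        for i in range(n_trna):
            t0 = int(rng_feat.integers(1000, rep_len - 1100))
            if not free(t0, t0 + 76):
                continue
            ac = _TRNA_POOL[int(rng_feat.integers(0, len(_TRNA_POOL)))]
            host_feats.append((t0, t0 + 76, "+",
                               "tRNA", f"tRNA-{_anticodon_label(ac)}"))
            blocked.append((t0, t0 + 76))
        pos = 500
        while pos + 1000 < rep_len:
            if free(pos, pos + 900):
                host_feats.append((pos, pos + 900, "+", "CDS",
                                   "hypothetical protein"))
            pos += config.host_cds_spacing
        host_feats.sort()

        for strain in ("A", "B"):
            seq = ancestor if strain == "A" else _mutate(
                ancestor, config.divergence, rng_div)
            my_atts = [(spec, a0) for spec, a0 in att_info
                       if strain in spec.strains]
            # insert from the rightmost locus so earlier coordinates hold
            seq_parts = seq
            for spec, a0 in sorted(my_atts, key=lambda x: -x[1]):
                dl, dr = spec.dr_left_len, spec.dr_right_len
                cargo, _ = cargo_store[spec.element_id]
                att_seq = seq_parts[a0:a0 + dl]
                h_after = seq_parts[a0 + dl]
                # force mismatches at the repeat boundaries so the maximal
                # match equals the implanted repeat exactly
                if dl > dr:
                    if att_seq[dr] == h_after:
                        att_seq = (att_seq[:dr] + _alt_base({h_after})
                                   + att_seq[dr + 1:])
                        seq_parts = (seq_parts[:a0] + att_seq
                                     + seq_parts[a0 + dl:])
                    if cargo and cargo[-1] == seq_parts[a0 - 1]:
                        cargo = cargo[:-1] + _alt_base({seq_parts[a0 - 1]})
                else:
                    if cargo and cargo[0] == h_after:
                        cargo = _alt_base({h_after}) + cargo[1:]
                    if cargo and cargo[-1] == seq_parts[a0 - 1]:
                        cargo = cargo[:-1] + _alt_base({seq_parts[a0 - 1]})
                att_r = att_seq[:dr]
                if config.repeat_mutation_rate > 0:
                    # noise over the duplicated copy exercises approximate
                    # repeat matching downstream
                    att_r = _mutate(att_r, config.repeat_mutation_rate, rng_div)
                seq_parts = (seq_parts[:a0 + dl] + cargo + att_r
                             + seq_parts[a0 + dl:])
            strain_records[strain].append(
                GenomeRecord(rep_name, seq_parts, topology))

            # coordinate shift: insertions strictly before a position
            inserts = sorted((a0 + spec.dr_left_len,
                              spec.size_bp - spec.dr_left_len)
                             for spec, a0 in my_atts)

            # ancestor -> strain coordinates: a start at an insertion point
            # moves past the insert, an end coordinate there does not
            def shifted_start(p):
                return p + sum(ln for ip, ln in inserts if ip <= p)

            def shifted_end(p):
                return p + sum(ln for ip, ln in inserts if ip < p)

            sid = f"syn{strain}"
            for k, (s, e, strand, ftype, product) in enumerate(host_feats):
                strain_features[strain].append(Feature(
                    feature_id=f"{sid}_{rep_name}_h{k}",
                    replicon_id=rep_name,
                    start=shifted_start(s), end=shifted_end(e),
                    strand=strand, ftype=ftype, product=product,
                ))
            for spec, a0 in my_atts:
                dl, dr = spec.dr_left_len, spec.dr_right_len
                start = shifted_start(a0)
                end = start + spec.size_bp
                _, cds_layout = cargo_store[spec.element_id]
                int_id = ""
                n_orfs = 0
                for j, (cs, ce, strand, product) in enumerate(cds_layout):
                    fid = f"{sid}_{spec.element_id}_c{j}"
                    strain_features[strain].append(Feature(
                        feature_id=fid, replicon_id=rep_name,
                        start=start + dl + cs, end=start + dl + ce,
                        strand=strand, ftype="CDS", product=product,
                    ))
                    n_orfs += 1
                    if product == MODULE_PRODUCTS["int"][0] and not int_id:
                        int_id = fid
                if spec.anticodon is not None:
                    label = _anticodon_label(spec.anticodon)
                else:
                    label = "srrA tmRNA"
                truth.append(TruthElement(
                    element_id=spec.element_id, strain=strain,
                    element_class=spec.element_class, replicon_id=rep_name,
                    start=start, end=end,
                    attl_start=start, attl_end=start + dl,
                    attr_start=end - dr, attr_end=end,
                    dr_left_len=dl, dr_right_len=dr,
                    att_label=label, modules=spec.modules,
                    integrase_id=int_id,
                    cargo_gc=spec.cargo_gc, n_orfs=n_orfs,
                ))

    proteome_a, proteome_b, ortho_truth = _simulate_proteomes(config, rng_prot)
    pair = StrainPair(
        config=config,
        genome_a=GenomeSet("A", strain_records["A"], strain_features["A"]),
        genome_b=GenomeSet("B", strain_records["B"], strain_features["B"]),
        proteome_a=proteome_a, proteome_b=proteome_b,
        truth_elements=truth, ortholog_truth=ortho_truth,
    )
    return pair


def _simulate_proteomes(config: SimConfig, rng: np.random.Generator):
    """Ortholog-plan proteomes with exact designed identities."""
    prot_a, prot_b = [], []
    below_cutoff = 0
    realized = []
    for i, spec in enumerate(config.orthologs):
        p = _random_protein(rng, spec.length_aa)
        q = _mutate_protein(p, spec.identity, rng)
        n_mut = sum(a != b for a, b in zip(p, q))
        real_id = (len(p) - n_mut) / len(p)
        realized.append(real_id)
        if real_id < 0.95:
            below_cutoff += 1
        prot_a.append(ProteinRecord(f"core{i:04d}", "A", p))
        prot_b.append(ProteinRecord(f"core{i:04d}", "B", q))
    for i in range(config.unique_a):
        prot_a.append(ProteinRecord(f"uniqA{i:04d}", "A",
                                    _random_protein(rng, 240)))
    for i in range(config.unique_b):
        prot_b.append(ProteinRecord(f"uniqB{i:04d}", "B",
                                    _random_protein(rng, 240)))
    truth = {
        "planted_unique_a": config.unique_a,
        "planted_unique_b": config.unique_b,
        "orthologs_below_cutoff": below_cutoff,
        "expected_unique_a": config.unique_a + below_cutoff,
        "expected_unique_b": config.unique_b + below_cutoff,
        "expected_pairs": len(config.orthologs) - below_cutoff,
        "realized_identities": realized,
    }
    return prot_a, prot_b, truth


def simulate_qpcr_table(efficiencies: dict[str, float],
                        quantities: dict[tuple[str, str], float],
                        noise_sd: float = 0.15, seed: int = 0,
                        replicates: int = 3, intercept: float = 20.0):
    """Simulate a dilution series and a sample Ct table.

    ``efficiencies``: target -> reaction efficiency E in (0, 1].
    ``quantities``: (target, condition) -> template amount (arbitrary
    units; 1.0 is the top of the dilution series).
    Ct values follow Ct = intercept + slope*log10(amount) with slope
    = -1/log10(1+E); Gaussian noise of ``noise_sd`` cycles is added.
    Returns (dilution_df, sample_df) matching :func:`mgescan.qpcr.analyze_qpcr`.
    """
    rng = np.random.default_rng(seed)
    dil_rows, sample_rows = [], []
    for target, eff in efficiencies.items():
        if not 0 < eff <= 1:
            raise ValueError(f"{target}: efficiency must be in (0, 1]")
        slope = -1.0 / np.log10(1.0 + eff)
        for ld in (0.0, -1.0, -2.0, -3.0, -4.0):  # 10 ng .. 1 pg, 10-fold steps
            ct = intercept + slope * ld
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            dil_rows.append({"target": target, "log10_dilution": ld,
                             "Ct": float(ct)})
    for (target, condition), q in quantities.items():
        if q <= 0:
            raise ValueError(f"{target}/{condition}: quantity must be > 0")
        slope = -1.0 / np.log10(1.0 + efficiencies[target])
        for rep in range(1, replicates + 1):
            ct = intercept + slope * np.log10(q)
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            sample_rows.append({"target": target, "condition": condition,
                                "replicate": rep, "Ct": float(ct)})
    return pd.DataFrame(dil_rows), pd.DataFrame(sample_rows)


def write_strain(genome: GenomeSet, outdir, prefix: str | None = None) -> dict:
    """Write one strain as FASTA + GFF3; returns the file paths."""
    from pathlib import Path

    from .genome_io import write_intervals

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or genome.strain_id
    fasta = outdir / f"{prefix}.fasta"
    with open(fasta, "w") as fh:
        for rec in genome.records:
            fh.write(f">{rec.replicon_id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i:i + 80] + "\n")
    gff = outdir / f"{prefix}.gff3"
    write_intervals(genome.features, gff, format="gff3")
    return {"fasta": fasta, "gff3": gff}


def write_truth(pair: StrainPair, path) -> None:
    pair.truth_df().to_csv(path, sep="\t", index=False)
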
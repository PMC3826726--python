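# Methods

This note documents the models, algorithms and numerical choices behind
`mgescan`, and what the synthetic-data validation does and does not show.

## Element model and detection

The detector assumes tyrosine-integrase-mediated site-specific
integration: an element inserts at an attachment site overlapping the 3'
end of a tRNA (or tmRNA) gene, duplicating the site into flanking direct
repeats (attL/attR) and leaving the integrase CDS within a few kb of one
repeat. Elements are **defined by this repeat/integrase geometry**;
composition (G+C, GC skew) is computed and reported as supporting
evidence but never gates a call, matching the order of operations in
integrase-anchored island detection generally.

**Anchoring.** Keyword mode treats a CDS as an integrase when its product
matches `integrase|recombinase` but not `transposase|retron`, or when a
qualifier carries COG4974. Similarity mode aligns translated CDS against
user-supplied integrase queries (≥30% identity over ≥50% of the query).
Keyword mode is the default because annotation product strings are the
only universally available signal; the exclusion list is what keeps IS
transposases and retron RTs from flooding the anchor set.

**Repeat search.** For each anchor, the ±10 kb flank is compared against
the sequence within ±250 kb (covering the largest observed elements,
~208 kb, with headroom) by seed-and-extend: exact 10-mer seeds grouped by
diagonal, then ungapped extension under a +1/−p score (p = id/(1−id), so
every maximal positive segment meets the identity floor, default 0.9).
Reported segments must additionally score ≥ ceil(m·id) − p·floor(m·(1−id))
(m = minimum length, default 14 bp); this floor only discards marginal
near-threshold segments a few bases over the minimum and is what keeps
the search linear-time on megabase replicons. Consequences of the
ungapped model: (i) for a 3'-truncated repeat pair such as 77/46 bp, the
detected attL and attR are both the 46-bp common core — element extents
are still exact because the core starts at the attL start and ends at the
attR end; (ii) repeats whose mismatches are spaced closer than the seed
length are invisible; (iii) indels split a repeat into separate segments.

**Selection.** One element per anchor, by total order: (1) pairs whose
repeat *contains* an RNA-gene 3' end — the 3' end must lie at or after
the repeat start, with 5 bp of end-side slack for cores truncated just
short of it; (2) pairs with any tRNA/tmRNA 3' end within 100 bp; (3)
more bases of the RNA gene covered by the repeat; (4) longer repeat; (5)
smaller span; (6) leftmost. Tiers (1) and (3) exist because on megabase
genomes chance 14–17-bp repeats occur near true att loci and can outrank
a short true repeat on length or span alone; a genuine att repeat both
contains the conserved RNA 3' end and maximizes its overlap with the
gene tail it preserves — the geometry integration actually produces.
Pairs with no RNA association at all must reach 18 bp (configurable):
an isolated short repeat on random sequence is not element evidence, and
without this guard a lone integrase on random sequence acquires spurious
~30-kb "elements" from chance 14-mers. Reported elements span 5–250 kb.
The detection floor of 14 bp is the practical limit for exact-repeat
methods at this genome size; 10-bp repeats are reachable by configuration
but cannot be distinguished from chance matches on megabase replicons.

**Junctions and excision algebra.** attB (empty site) = 200 bp upstream
of attL + one repeat copy + 200 bp downstream of attR; attI (circular
intermediate) = 200 bp of cargo end + repeat + 200 bp of cargo start.
Excision returns (empty site, circle) such that re-inserting the circle
immediately after the retained repeat reconstructs the replicon exactly,
with one repeat copy in each product — a string identity the tests check
for every recovered element. Cross-strain occurrence uses banded
edit-distance search of the attL/attR junctions (both found → `+`), else
the attB junction (`-, s`), else `-`, at ≥90% identity over the junction
(or its central 80%).

## Classification

Cargo modules are detected by case-insensitive product-string patterns
and COG ids from an editable catalog (T4SS mating-pair genes virB1–11 and
trb; relaxase VirD2; coupling VirD4/TraD; phage cI/cII/Cro/Xis and
structural genes; ParAB/ParB-ThiF/PRTRC partition; type II
toxin–antitoxin families). Rules apply in a fixed total order: phage set
(≥3 distinct phage tags) without T4SS → prophage; ≥4 distinct mating-pair
genes → ICE; relaxase + coupling protein → IME; ≥5 kb → GI; else
unclassified. The ≥4 threshold balances ICEs annotated with partial trb
operons against the IME exclusion; monotonicity (adding T4SS evidence
never demotes an ICE) is property-tested. Keyword matching stands in for
profile-HMM annotation; the catalog is a TSV so externally derived hits
can be injected. Toxin/antitoxin genes pair when ≤2 genes apart (greedy
nearest); families form when elements share ungapped blocks ≥5 kb summing
to ≥25 kb at ≥90% identity, and a family containing an ICE (or IME)
promotes its GI/unclassified members with a `by_family` flag — this is
how a T4SS-less element sharing a ~56-kb backbone with a conjugative
relative inherits the ICE label.

## Pangenome, ANI, qPCR

Protein comparison uses local BLOSUM62 alignment with BLAST-convention
affine gaps (a gap of length g costs 11+g); identity is counted over
aligned columns (gaps included, no end overhangs — the BLAST convention),
coverage is reported but not thresholded. The ortholog cutoff is
reciprocal 95% identity; an E-value criterion is approximated by a raw
score floor (50), which is never binding at 95% identity. A 5-mer
prefilter (≥10 shared, degrading for short proteins so near-identical
short pairs are never dropped) makes all-vs-all comparison tractable;
tests require exact agreement with the unfiltered oracle.

ANI is Goris-style: 1020-bp consecutive fragments (trailing remainder
kept if ≥100 bp, >20% N skipped), each aligned to the partner genome with
`blastn` (`-task blastn -evalue 1e-15 -dust no -xdrop_gap_final 150`),
best hit per fragment by bit score, retained at ≥30% identity over ≥70%
of the fragment; ANI is the mean retained identity, reported one-way and
as the symmetric mean. Self-ANI is exactly 100 by construction.

qPCR: ordinary least squares of Ct on log10(dilution) over a ≥3-point
series; E = 10^(−1/slope) − 1; amounts 10^((Ct−intercept)/slope);
replicates aggregate as arithmetic means of *quantities* (the curve is
linear in log quantity), and fold induction is the treated/control ratio
with a min/max spread over replicate combinations. A positive fitted
slope is rejected as an inverted dilution axis.

## Synthetic data: what it emulates, and what it does not

The generator builds a multi-replicon ancestor (defaults: 1.2-Mb linear
chromosome at 61% G+C, a 120-kb circular megaplasmid at 55%, two small
plasmids at 59%/50%) and derives two strains from it: strain B receives
i.i.d. substitutions at a configurable divergence (default 2%, the scale
at which closely related strains of one species sit), and each strain
receives its configured implants. Implants reproduce the observed element
geometry: sizes 9.9–208 kb, ~57% G+C cargo, direct repeats of 14–738 bp
with truncated right copies (the right repeat is a prefix of the left),
attL overlapping a generated tRNA 3' end (or a tmRNA for the prophage),
an integrase CDS within 5 kb inside attL, and class-defining cargo CDS
whose product strings are drawn from the classifier catalog — simulator
and classifier are deliberately contract-coupled. A strain lacking an
implant keeps the empty attachment site, so occurrence typing can return
`-, s`. Boundary bases at the repeat edges are forced to mismatch so that
the maximal match equals the implanted repeat and ground-truth
coordinates are exact rather than exact-up-to-chance-agreement. Proteomes
are generated as a separate channel with exactly controlled mutation
counts (identities 90–100% straddling the 95% cutoff, plus planted
strain-specific genes), because protein identities derived from diverged
genomic CDS would scatter around the cutoff and make exact partition
truth impossible. Everything derives from one seed through split
generators; the same seed gives byte-identical output.

Chromosome and element sizes are scaled to roughly half the real
multi-megabase setting to keep the validation suite fast; the detection
problem (repeat length vs replicon size, chance k-mer statistics) scales
linearly, so conclusions transfer, but three real-data features are *not*
emulated: codon structure and repeat families of natural genomes (IS
elements create repeat noise the simulator lacks), phylogenetically
structured divergence (real strains have indels and rearrangements, not
uniform substitutions — the ungapped repeat matcher and substitution-only
ANI calibration are tested only in that regime), and annotation noise
(product strings are drawn from the same vocabulary the classifier
matches; real annotations vary more). Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not recall on
arbitrary natural genomes.

## Degenerate inputs and tie-breaks

N bases count as mismatches everywhere, are excluded from G+C numerator
and denominator, and fragments >20% N are skipped in ANI. All-N
sequences, empty proteomes, empty catalogs, whole-replicon "elements" and
inverted dilution axes raise errors rather than returning numbers.
Best-hit ties break by identity then lexicographic subject id; element
selection and family numbering are fully ordered; every command is
deterministic given config + seed.

## Known limitations

Ungapped repeat detection (no indel tolerance within a repeat); keyword
classification is only as good as the product vocabulary; no IS-element
boundary detection, oriT finding, CRISPR array detection or transfer
prediction; cross-strain presence is junction-based and will call
`no_site` for loci lost to rearrangement; ANI requires the blastn
executable.
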
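# Methods

## Problem setting

Two parental genotypes are assembled independently from reduced-
representation (RAD) sequencing, so homologous loci live on differently
named contigs with no shared coordinates.  The pipeline identifies marker
loci in each assembly, decides which of them are the *same* locus in the
other parent, predicts which are polymorphic from sequence alone, removes
candidates already covered by published marker collections, and designs PCR
primers for the rest.  Every threshold below is exposed in
`PipelineConfig`; the stated values are the defaults.

## SSR mining

Perfect tandem repeats of primitive 2–8 bp motifs are detected per contig
with per-unit-length minimum repeat counts (2-mers: 7; 3-mers: 5; 4-mers: 4;
5–8-mers: 3).  A run is a maximal stretch of period-*k* self-matches,
truncated to whole motif units; runs whose motif is a power of a shorter
unit are left to the shorter period, so mononucleotide runs are never
reported.  When maximal runs of different periods overlap, the longer run
wins (ties: smaller start, then shorter unit).  Runs containing N are
discarded.  Consecutive loci separated by at most 500 interrupting bases
share a compound id; 500 matches the original parameterisation even though
100 is the more common default, and it is configurable.  Interrupted
("imperfect") repeats are not tolerated — no mismatch allowance is defined
for them here.

Motif classes are canonical under cyclic rotation and reverse complement:
the class label pairs the lexicographically smallest rotation over both
strands with the smallest rotation of its reverse complement
(`TA → AT/AT`, `TTC → AAG/CTT`, `TGA → ATC/ATG`).

## Flank alignment and E-values

Anchoring and redundancy both rest on local alignment of short, high-
identity sequences.  The aligner seeds on exact 11-mer words (either
strand); a seeded pair is then scored with a full affine-gap Smith–Waterman
(match +1, mismatch −2, a gap of length L costs 5 + 2L), so the reported
score is the exact local optimum whenever any seed exists and no hit is
reported otherwise — mimicking default nucleotide-BLAST behaviour on short
flanks without re-implementing BLAST's statistics.  The DP fill is
numba-compiled; the traceback reads the stored score matrices with a fixed
tie order (diagonal, then query-gap, then subject-gap), which makes spans
and identity counts deterministic.  E-values use the extreme-value form
E = K·m·n·exp(−λS) with the ungapped nucleotide constants K = 0.711,
λ = 1.37 applied to gapped scores as an approximation; n is the total
length of the search set, recomputed per search.  N scores as a mismatch
against everything and is excluded from seed words, so masked positions can
never contribute matched bases.

## Anchoring and partition

A marker's flanks are the up-to-200 bp of N-free sequence immediately
adjacent on each side (minimum 20 bp; markers without both flanks are
UNANCHORABLE and drop out of the candidate pool).  The 200 bp cap
stabilises E-values on short queries.  Marker *a* anchors to marker *b*
when both of *a*'s flanks hit flanks of the same *b* at E ≤ 1e−5 with a
consistent orientation (left↔left/right↔right on plus, swapped on minus)
and compatible geometry — the implied inter-flank gaps may disagree by at
most 50 bp, which tolerates short InDels while rejecting paralogous
anchors.  Among several qualifying partners the best is taken (smallest
worst-flank E-value, then most identities, then lexicographic id) and the
ambiguity is counted.  SHARED pairs are mutual best anchors in both
directions, which keeps anchoring symmetric; everything else anchorable is
parent-specific.  The partition is checked against the identity
`shared + a_only + b_only + unanchorable = |A| + |B| − shared` on every run.

In-silico polymorphism: an anchored SSR pair with equal canonical class and
different repeat counts (a class mismatch is flagged as an inconsistency,
not a polymorphism); an anchored variant-site pair where both directions
are homozygous and the two parents' alleles differ.  The screening
candidate set is the polymorphic pairs plus the parent-specific markers.

## Variant screening

Reciprocal variant tables ("AB": parent A's reads called on parent B's
contigs, and the converse) carry DP, MQ, MQ0, QUAL and the two allele
depths.  InDel records are removed when any one clause holds, evaluated in
order: (MQ0 ≥ 4 AND MQ0/DP > 0.1), MQ < 30, QUAL < 50, DP < 5 — the
bracketed ratio condition is read as a conjunction with the MQ0 count,
matching the hard-filter idiom it transcribes; DP = 0 short-circuits to the
depth clause so the ratio is never evaluated.  SNPs are kept at DP ≥ 8.
Zygosity is called from the minor-allele frequency of the two allele
depths: homozygous below 0.10, heterozygous above 0.25, unknown in between;
the boundary values go to unknown because the defining wording is strictly
"below"/"above".  Sites with a third supported allele are outside the
biallelic model and excluded.

## Redundancy rule

A candidate SSR is compared with a known-marker database (FASTA) after its
repeat is masked to N.  "Matched bases" is the identity count of the single
best local alignment against one record — the stricter reading of the rule;
summing across multiple HSPs is not done.  The decision is *redundant* as
soon as any record reaches 50 identities, which makes it monotone in
database content (adding records can only turn novel into redundant).
Masking uses the pipeline's own SSR coordinates, which for perfect repeats
is a superset of what an external repeat masker would shield.  Because the
pipeline anchors markers before primers exist, the region screened is the
marker's flank region (both anchoring flanks around the masked repeat) as
the inter-primer proxy; `interprimer_sequence` implements the primer-based
extraction for workflows that design primers first.

## Primer regions

Markers on one contig whose spans are separated by strictly less than
500 bp share one primer region; chains that no product under 800 bp can
span are split greedily at their largest gaps.  Candidate primers are
18–24 nt windows outside the region with GC 40–60 %, no N, and a
non-self-complementary 3′-terminal 4-mer (a minimal dimer/hairpin guard;
full thermodynamic checks are out of scope).  Melting temperature uses the
basic formula Tm = 64.9 + 41·(GC − 16.4)/len — only the 57 °C optimum is
prescribed, so the formula is a package choice and configurable.  Each
primer scores |len − 20| + |Tm − 57| + 0.2·|GC − 50|; singleton pairs add
0.01·|product − 300| and must fall in 100–500 bp, clustered pairs must stay
under 800 bp (read as a hard cap for clustered regions, with 100–500
remaining the singleton range; both bounds configurable).  The minimal-score
pair wins, ties broken by leftmost position then smallest product, so
design is deterministic.

## Statistics

Printed-style statistics (polymorphism rate, marker density `1/X kb`, mean
adjacent map distance = total cM / mapped loci) round half-up to two
decimals.  One published density (5,461 SSRs over 57,060 kb) recomputes to
10.45 against a printed 10.44 — the original rounding mode is unknown, so
agreement is asserted only to ±0.01.  Segregation screening is a Pearson χ²
against 1:2:1 (df 2) or 3:1 (df 1), distorted at P ≤ 0.05 per locus with no
multiple-testing correction.  Map construction itself (linkage grouping,
ordering, Kosambi distances, QTL scans) is out of scope; only the scalar
statistics are computed.

## Synthetic data generator

`generate_parents` draws i.i.d. contig sequence at GC 0.34 (contigs
200–800 bp) and plants, one feature per contig: shared-equal SSRs (same
repeat count, identical contigs in both parents), divergent SSRs (repeat
count changed in one parent inside identical ≥120 bp flanks — never the
motif, mirroring the in-silico polymorphism definition), parent-only SSRs,
and SNP/InDel contig pairs differing at exactly the planted site.  Motif
sizes follow the observed spectrum (pentanucleotides most frequent); SSR
spans are capped near 30 bp so primer products stay designable; SNP alleles
are transitions with probability r/(1+r) for a target ratio r = 1.76; InDel
lengths are geometric with mean 1.4 bp.  Every contig is rejection-sampled
until the miner sees exactly the planted loci, so accidental repeats in
random flanks cannot desynchronise the truth table.

`emit_variant_calls` writes reciprocal caller-style tables (swapped
ref/alt) with Poisson depth (mean 30, floor 10), MQ 60, MQ0 0, QUAL 200,
and allele depths matching the planted zygosity (homozygous: minor fraction
drawn below 0.10; heterozygous: binomial around 0.5 conditioned above 0.25;
grey-zone sites strictly inside (0.10, 0.25)).  Noise layers are
independently switchable fractions — per-clause filter failures, low-depth
SNPs, heterozygous or grey-zone sites — each of which updates the truth
row's expected outcome; all default to zero.  `known_db_fixture` copies the
100 bp flanks (repeat excised) of a designated fraction of
candidate-destined SSRs into database records, guaranteeing ≥50 matched
non-SSR bases, and pads the database with unrelated random records.

What the generator does **not** emulate: read-level errors, assembly
artefacts, paralogy/repeat families, multi-allelic sites, and covariance
between neighbouring markers (one feature per contig).  Passing the
full-recovery suite therefore demonstrates the correctness of the decision
logic under clean inputs, not robustness to misassembly or paralog
collapse on real data.

## Determinism and numerical choices

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical configs give byte-identical FASTA,
tables and reports (report rows have total sort keys).  Alignment
tie-breaks, primer tie-breaks and partition ordering are all fixed as
described above.  The default study conditions (the generator's defaults)
are 100 shared-equal, 50 divergent, 60 + 60 parent-only SSRs, 500 SNPs and
200 InDels with 30 background contigs per parent — large enough that every
status class is exercised many times, small enough that the full pipeline
runs in about a minute on one core; the ts/tv recovery check uses 10,000
SNPs for tight binomial concentration.

## Known limitations

- The Karlin–Altschul constants are the ungapped defaults applied to gapped
  scores; reported E-values are approximate (the anchoring decisions they
  gate are robust to this, since true anchors sit orders of magnitude below
  the cutoff).
- Queries shorter than the 11-mer word size can never seed and so never hit.
- Primer quality is scored with a basic Tm formula and a minimal 3′
  self-complementarity guard, not a thermodynamic model.
- Only two genotypes are compared; multi-parent designs and paralog-family
  clustering are out of scope.
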
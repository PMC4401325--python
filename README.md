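# radmarkers

In-silico molecular marker development from dual-parent RAD-seq contig
assemblies.

When two mapping parents of a crop (here modelled on upland cotton,
*Gossypium hirsutum*) are sequenced by reduced-representation (RAD)
sequencing and assembled de novo, each parent yields its own contig set with
no shared coordinate system.  `radmarkers` turns such a pair of assemblies,
plus the reciprocal variant-call tables from cross-mapping the reads, into a
screened list of candidate molecular markers with designed PCR primers:

1. **SSR mining** — perfect microsatellites of 2–8 bp motifs at the classic
   MISA thresholds (≥7 repeats for dinucleotides, ≥5 tri-, ≥4 tetra-, ≥3
   penta- through octanucleotides); runs ≤500 bp apart form compound SSRs;
   motifs are reported by canonical class (rotation + reverse complement,
   e.g. `AT/AT`, `AAG/CTT`).
2. **Cross-genotype anchoring** — two markers are the same locus when the
   immediate flanking sequences (≥20 bp each side) align between genotypes
   with E ≤ 1e−5 in a consistent orientation and geometry.  Alignment is a
   seeded (word size 11) affine-gap Smith–Waterman with Karlin–Altschul
   E-values.
3. **In-silico polymorphism calls** — anchored SSR pairs whose repeat counts
   differ; anchored variant sites at which both parents are homozygous
   (minor-allele frequency < 0.10; heterozygous > 0.25; unknown between) for
   different alleles.
4. **Variant hard filters** — InDels removed on any of
   {MQ0 ≥ 4 ∧ MQ0/DP > 0.1; MQ < 30; QUAL < 50; DP < 5}; SNPs kept at depth
   ≥ 8; transition/transversion bookkeeping.
5. **Redundancy screening** — a candidate SSR is redundant with a published
   marker collection when its marker region, with the SSR masked out, still
   shares ≥50 matched bases with a database record.
6. **Primer design** — markers within 500 bp share one primer region
   (product < 800 bp); singleton products 100–500 bp; primers 18–24 nt,
   GC 40–60 %, annealing optimum 57 °C, picked deterministically.
7. **Statistics** — polymorphism rates, marker densities (`1/X kb`), mean
   map distance, and the χ² segregation screen against 1:2:1 / 3:1 (P ≤ 0.05).

A synthetic dual-parent generator (`radmarkers.simulate`) plants SSR
repeat-count divergence, SNPs at a configurable ts/tv ratio, and short
InDels into ~34 % GC contigs with caller-style site metrics and a complete
truth table, so every stage is verifiable without any sequencing data.

## Worked example

```sh
radmarkers simulate --seed 7 --out-dir sim/
radmarkers run --fasta-a sim/parent_A.fasta --fasta-b sim/parent_B.fasta \
    --variants-ab sim/variants_AB.tsv --variants-ba sim/variants_BA.tsv \
    --db sim/known_db.fasta --out-dir out/
```

`out/stats.json` then contains (seed 7, default study conditions):

```json
{
  "ssr_shared": 150,
  "ssr_insilico_poly": 50,
  "ssr_a_only": 60,
  "ssr_b_only": 60,
  "ssr_candidates": 170,
  "ssr_redundant": 85,
  "variant_shared": 700,
  "variant_insilico_poly": 700
}
```

meaning: of the mined SSRs, 150 loci anchored between the parents, 50 of
those differ in repeat count (in-silico polymorphic), 60 + 60 are
parent-specific; the 170 screening candidates (50 + 60 + 60) were checked
against the known-marker database and 85 flagged redundant; all 700 planted
variant sites anchored and were called homozygous-different.  The report
(`out/markers.tsv`), primer table and filter audit accompany it.

Single statistics are available directly, e.g.

```sh
$ radmarkers stats --poly 83 --screened 1323
6.27
$ radmarkers stats --count 5158 --total-kb 55270
1/10.72 kb
```

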
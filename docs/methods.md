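# Methods

## The system being modelled

An allotetraploid genome (AACC) carries two homeologous families of 35S rDNA
units inherited from its diploid progenitors. Each unit is a tandem repeat of
a transcribed 18S–ITS1–5.8S–ITS2–26S region (5803 bp in the Brassica system
this package is calibrated to) plus an intergenic spacer (IGS). The two
parental unit families differ at a set of fixed substitutions — *diagnostic
sites* — and each family additionally carries low-level intragenomic
polymorphism of its own. Concerted evolution can overwrite units of one
subgenome with the other's sequence; the package measures how far that
homogenization has progressed from short-read data alone.

## Synthetic data generator

`SimConfig` encodes the study conditions; its defaults are the conditions the
analyses are run under, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `unit_length` | 5803 bp | transcribed unit length |
| `divergence` | 0.0124 | inter-progenitor divergence → 72 diagnostic sites |
| `n_A`, `n_C` | 1700, 1160 | 1C unit copies contributed by each progenitor (rounded published estimates 1709 and 1162) |
| `conversion_fraction` | 0 | fraction of C units overwritten by the A sequence |
| `unique_rate` | 0 | per-unit probability of joining an amplified novel-variant family |
| `n_unique_sites` | 3 | substitutions shared by that family |
| `n_intra_A`, `n_intra_C` | 10, 7 | intragenomic polymorphic sites per progenitor pool (the published per-species high-frequency SNP counts) |
| `intra_freq` | 0.4 | minor-haplotype share carrying those sites |
| `coverage` | 200× | read depth over the unit (the source data read most positions well above 130×) |
| `read_length` | 100 nt | Illumina-like single-end reads |
| `error_rate` | 0.005 | per-base substitution error |
| `target_genome_proportion` | 0.0139 | rDNA share of all reads (the published 1.39%) |
| `genome_size_mb` | 1182 | 1C genome size |

Design choices:

* **Gene conversion is whole-unit replacement.** Short reads cannot resolve
  whether converted and intact units are interspersed or blocked within
  arrays, and partial-unit conversion would make the conversion fraction
  unidentifiable from allele fractions. A converted unit is the complete
  A-genome sequence, labelled `C_converted`.
* **Intragenomic polymorphism is a two-haplotype model.** A fraction
  `intra_freq` of each progenitor's units carries the minor alleles at all of
  that progenitor's polymorphic sites. This reproduces the observed
  frequency classes with only two distinct sequences per subgenome; it does
  not model the full haplotype diversity of a real array.
* **Novel variants form one amplified family.** With probability
  `unique_rate` an A-derived unit instead belongs to a family sharing
  `n_unique_sites` novel substitutions at non-diagnostic, non-polymorphic
  positions (label `mutated`). This mimics a newly amplified variant family
  reaching high frequency; independent singleton mutations would never pass
  the frequency gates and would be invisible to every downstream readout.
* **Background genome is i.i.d. uniform DNA.** Only the mapped/unmapped split
  matters for genome-proportion estimation, so background reads are random
  sequence emitted in the deterministic ratio that makes the rDNA read share
  equal `target_genome_proportion` exactly (sampling error then comes only
  from mapping failures, which is what the method actually measures).
* Qualities are constant Phred-40 (the pipeline never uses them); strands are
  sampled 50/50; substitution errors only — no indel errors, no PCR chimeras,
  no quality decay. Reads are sampled entirely within the unit (no junction
  reads across the tandem repeat).

Everything is reproducible: a fixed `seed` yields byte-identical FASTQ.

## Read mapping

The mapper reproduces the acceptance behaviour of the workbench pipeline the
analysis is modelled on: costs mismatch 2 / insertion 3 / deletion 3, length
fraction ≥ 0.8 and similarity fraction ≥ 0.8. Alignment is *glocal*: the
whole read is aligned, reference flanks are free. The aligned read fraction
of an accepted read is therefore 1.0 and identity — matches over aligned
columns, with indel columns counting against — is the binding gate; reads
overhanging the reference ends pay insertion costs rather than being
clipped. Identity is not published by the original tool, so this definition
is the package's own and is used consistently everywhere, including the
exhaustive dynamic-programming oracle the tests compare against.

Candidate placements come from exact 15-mer seeds on both strands (at ≤ 1.5%
divergence plus ≤ 1% error a 90-nt read almost surely contains a clean
15-mer; a read with up to four substitutions provably does). Each candidate
diagonal is first evaluated ungapped; up to four mismatches no gapped path
within the band can be cheaper (an insertion/deletion pair plus a residual
mismatch already costs more), so the banded dynamic programme (band width 10)
runs only beyond that. Cost ties resolve to the lowest reference coordinate,
forward strand first, so pileups are deterministic. Multi-mapping across the
single reference resolves to the single best-cost location.

## Variant calling and frequency classes

The original probabilistic caller is replaced by the explicit gates it
reports: coverage ≥ 100, supporting count ≥ 10, frequency ≥ 5%. Variants at
≥ 20% form the *high* class; [5%, 20%) is *medium* — the published "5–20%"
range is taken half-open so the classes are disjoint. "Countable reads" are
reads contributing an aligned base at the position. Indels are not called
(the simulation regime is indel-free).

Two reference frames are used deliberately, and this is the load-bearing
design decision of the pipeline:

* **Intragenomic SNP profiles** (window profiles, the per-cultivar SNP
  counts) call variants against the *sample's own consensus*: they measure
  heterogeneity within one genome's rDNA pool. In a homogenized cultivar the
  minority parental alleles fall below the frequency gates and the profile
  collapses — which is exactly the published contrast between the additive
  and converted cultivars (at least three-fold fewer high-frequency SNPs in
  the converted one).
* **Provenance partitioning** calls the allopolyploid and both progenitors
  against the *virtual-hybrid consensus* — the consensus of a 1:1 in-silico
  mixture of the parental read sets, i.e. the additive null. All pileups
  share one coordinate frame (every read set is mapped to the same unit
  reference; the unit has no indel variation, so coordinates are common).
  Against this frame each diagnostic site contributes a variant carried by
  exactly one parent, so an additive allopolyploid shows near-equal
  A-inherited and C-inherited classes, while a converted one loses the
  C-inherited class and gains a unique class from its amplified novel
  family. Variant identity for the set comparison is (position, alt allele);
  the shared class is reported explicitly, with an optional merge flag for
  two-way Venn summaries.

Amplicon haplotype clustering maps reads to a region reference, takes the
positions whose minor-allele frequency reaches 5%, groups reads by their
calls at those positions, and reports groups at ≥ 10% of grouped reads.

## Copy number, diagnostics and elimination

Genome proportion is `100 · mapped/total` over post-filter reads; 1C copies
are `genome_size_bp · (GP/100) / unit_length`, with genome sizes supplied as
configuration (defaults 1182 / 630 / 530 Mb) and an optional ~1.6×
reporting factor for analyses that count the IGS as part of the repeat.
Integer copies use round-half-away-from-zero, which reproduces the published
integers within ±1 given their rounded genome proportions.

The diagnostic readout averages per-site C-allele read fractions
(unweighted by default, coverage-weighted optionally) over sites with
coverage ≥ 100. Elimination is plain arithmetic on that readout:
`observed_C = C_proportion · allo_copies_1C`, eliminated = progenitor 1C
copies − observed, floored at zero. With the published inputs (14% C share,
2832 allopolyploid and 1162 progenitor copies) this yields ≈ 766 eliminated
copies (≈ 66%); the package reports its own arithmetic and does not attempt
to reproduce the looser "~900 copies" narrative figure, whose basis is not
derivable from the printed values.

## In-silico assays

Digestion expands IUPAC motifs to regular-expression classes and scans both
strands, reconciling reverse-strand occurrences to forward-strand cut
coordinates; palindromic sites (RsaI GT^AC, BstNI CC^WGG) are cut once per
occurrence, overlapping occurrences are all cut, and partial digestion is
not modelled. Fragments within ±2 bp co-migrate into one band. Band
intensity is molecule count × fragment length (mass-proportional, as for a
radiolabelled blot), with a count-proportional flag. The Southern readout
reports the C-band share among probe-hybridizing bands; when A- and
C-derived fragments co-migrate the ratio is flagged unresolved rather than
guessed. CAPS co-dominance requires both subgenome-specific bands to exceed
a 5% detectability share.

## IGS repeat structure and trees

HOR detection scores each candidate period p (default 20–1000 bp, 1-bp
resolution) by the self-match fraction `base(i) == base(i+p)` over the best
contiguous run, found by a maximum-sum scan with the acceptance threshold
(0.7) as offset; the array must span at least 1.5 periods. Boundaries are
then snapped to the nearest run of 10 consecutive matches so lucky flank
matches cannot shift the copy frame. Copies are consecutive p-length blocks
(the last may be partial, giving fractional copy number); consecutive copies
are compared by a unit-cost global alignment (edlib), the partial terminal
copy over its available length. Random sequence (expected self-match 0.25)
returns a distinct "no HOR" result. The 0.7 threshold and 1.5-period minimum
are package choices — the original analysis used external repeat finders
without published parameters — set to detect the 421-bp structure while
rejecting random sequence.

p-distances exclude columns with a gap or N in either sequence of a pair.
Neighbour joining is delegated to scikit-bio (Saitou–Nei agglomeration;
negative branch lengths clamped to zero with the deficit moved to the
sibling edge), which recovers additive matrices exactly. Bootstrap support
resamples alignment columns with replacement after canonical (sorted) taxon
ordering — so supports are invariant to input order under a fixed seed — and
reports the percentage of replicates containing each internal bipartition.
Input alignments are accepted pre-aligned; no aligner is bundled.

## Problem sizes and what the tests show

The test-suite and acceptance-script simulations run at the defaults above
(5803-bp unit, 200× coverage, ~11 600 rDNA reads per condition; the
genome-proportion check uses a ~104 000-read mixture; conversion recovery
runs 6 conversion levels × 10 replicates). These sizes make every stochastic
check sit well inside its tolerance while keeping a full run to a few
minutes on one CPU.

Passing tests demonstrate internal consistency and parameter recovery under
the generator's assumptions: substitution-only errors, two-haplotype
intragenomic structure, whole-unit conversion, uniform background. They do
not establish robustness to features of real data the generator omits —
indel sequencing errors, PCR chimeras and recombinant reads, copy-number
variation along arrays, reference bias from a diverged mapping reference, or
IGS length polymorphism (IGS structure is analysed from provided clone
sequences, not reconstructed from short reads).

## Known limitations

* The conversion estimator assumes the progenitor copy ratio `n_A : n_C` is
  known; in real cultivars it must come from progenitor genome proportions.
* Diagnostic sites are treated as strictly fixed between progenitors;
  segregating diagnostic sites would bias the readout toward apparent
  conversion.
* The virtual-hybrid consensus picks a parental allele per diagnostic site
  by read majority; at exactly 1:1 mixing the choice is a coin flip per
  site, which splits diagnostic variants between the A- and C-inherited
  classes but does not change their sum.
* `total_read_count` is defined post-filter; published mapped/total
  accounting may differ in which filters precede the denominator.
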
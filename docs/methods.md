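# Methods

## The screen

A candidate SINEUP is an antisense transcript that could, by geometry
alone, act as a translation enhancer of its sense partner: it must be
transcribed from the opposite strand, overlap the mRNA where ribosome
loading is decided, and carry a SINE as a putative effector domain. The
screen is a deterministic conjunction of four predicates evaluated on
annotation coordinates only — no sequence, expression or structure model
is involved, and no p-values are produced.

**Coordinates.** Everything internal is 0-based half-open. GTF (1-based
closed) and RepeatMasker `.out` (1-based closed, `C` = minus strand) are
converted at the parser boundary; emitted BED stays 0-based, and genomic
columns of the candidate TSV are 1-based closed, labelled with a
`_1based` suffix.

**Stage 1 — antisense pairing.** An assembled transcript pairs with every
reference transcript on the opposite strand whose *exon chains* intersect
by ≥ `min_overlap` (default 1 bp; intron-only overlap does not count). A
`span_mode` switch relaxes this to genomic spans for comparison with
span-based interval tools. Pair geometry is classified from the genomic
spans: containment of either span in the other is *full-length* (ties
included); otherwise *divergent* when both 5′ ends lie in the overlap
(head-to-head), *convergent* when both 3′ ends do, *internal* otherwise.
`covers_tis` tests a single base: the first base of the sense start codon.

**Stage 2 — SINE containment.** A pair survives when the antisense exons
overlap ≥1 repeat of an allowed RepeatMasker class (default `{SINE}`) by
≥1 bp. The repeat may sit anywhere in the transcript, not only inside the
sense overlap — natural SINEUPs typically carry the element at their 3′
end, far from the binding region. All overlapping allowed-class repeats
are attached to the candidate.

**Stage 3 — TIS window.** The TIS-proximal window of a coding reference
transcript is the last `k` nt (default 5) of 5′-UTR *transcript* sequence
immediately upstream of the AUG, projected back to genomic intervals, so
it can split across an exon junction. When the UTR is shorter than `k`
the window truncates (width = min(k, UTR length)); transcripts without
CDS or UTR can never match. An alternative `per_exon_end` mode takes the
last `k` nt of every 5′-UTR exon instead; it is a config switch because
annotation-intersection workflows sometimes operate per exon.

**Stage 4 — CAGE.** A CAGE cluster supports an antisense transcript when
its distance to the 5′-end base is ≤ `halfwidth` (default 200 nt; distance
0 inside the cluster) and, by default, its strand matches. The stage
*annotates* rather than filters — independent expression evidence should
not silently delete geometric candidates — but `cage_filter` promotes it.
Best (max) tpm and minimal distance over supporting clusters are recorded.

The funnel counts distinct antisense transcripts per stage (a NAT
overlapping several mRNA isoforms yields one candidate row per isoform but
is counted once). Stages 2 and 3 are independent predicates, so their
order cannot change the surviving set — asserted as a commutation property
test. Output ordering is lexicographic in (antisense_id, sense_id), and
identical inputs give byte-identical outputs.

## Enrichment statistic

To ask whether candidates prefer particular SINE subtypes, the copy-number
weighted frequency vector of candidate-embedded repeats is compared
against the frequency vector of all annotated copies (the genomic
background), aligned over the union of identities with zero-imputation,
by Pearson correlation. Grouping is by repeat *name* (subfamily) by
default; family- and class-level aggregation are available. r near 1 means
candidate composition mirrors genomic abundance — no enrichment. With
fewer than two identities the statistic is undefined (error); a
zero-variance vector sets an `undefined_r` flag instead of crashing,
since a uniform composition gives Pearson no across-group variation to
correlate. Per-subfamily fold change (candidate/genome) is reported
alongside; no per-family significance testing is attempted.

## Construct designer

The binding domain is the reverse complement of the target window around
the AUG, with the −35/+4 default: positions −1 and +1 are adjacent (there
is no 0), so the window spans 35 UTR nt + 4 CDS nt = 39 nt. Shorter UTRs
truncate the window at the transcript 5′ end with a warning. The effector
domain is extracted from genome sequence in the orientation it has in the
antisense RNA: reverse-complemented when the repeat's annotated strand
opposes the NAT strand (the inverted-element case), verbatim otherwise,
with an explicit `invert` override. BD, spacer and ED concatenate 5′→3′
into the construct; the element coordinates tile the sequence without
gaps. ΔED (BD + spacer) and ΔBD (spacer + ED) deletion controls mirror
the standard functional controls for the two domains. Sequences are
handled as DNA (`U` mapped to `T`, alphabet `{A,C,G,T,N}` enforced). The
published spacer sequence is not printed anywhere authoritative, so the
shipped default is a neutral 20-nt linker (`GCTAGCACGCGTACTAGTCG`,
restriction-site-like, no homopolymers) and all length arithmetic is
parameterized; any spacer can be supplied as FASTA.

## Synthetic data generator

Each dataset is a single synthetic chromosome of independent loci. Every
locus holds one reference mRNA (5′ UTR 100–300 nt, CDS 300–900 nt, 60 nt
3′ UTR, single exon, random strand) and one assembled transcript of a
labelled class:

- **true_candidate** — antisense, exon covering the TIS window and start
  codon, extending 50–200 nt into the CDS, with one SINE (80–300 nt) at
  its 3′ end and a CAGE cluster (tpm 0.5–50) within 150 nt of its 5′ end
  on the same strand;
- **no_sine** — same geometry, but the planted repeat is a LINE/L1 decoy,
  so the class filter rather than mere repeat absence is exercised;
- **no_tis_overlap** — antisense overlapping CDS only, starting ≥50 nt
  downstream of the TIS window, SINE and CAGE present;
- **same_strand** — overlaps the mRNA on the same strand, SINE present;
- **intergenic** — overlaps nothing, SINE present.

Negatives each fail exactly one predicate (the classes before their
failing stage are satisfied), so the funnel drops them at predictable
stages and final-stage recovery of the planted positives is an exact
set-equality check against the truth table.

Background repeat copies (default 200) and CAGE noise clusters (default
10) live in a tail region no transcript touches. Plantable SINE
subfamilies (FRAM, AluY, MIRb, AluSx, ... up to 8) are drawn from a
**geometric abundance distribution** (each family half as abundant as the
previous) unless explicit probabilities are given. This skew is
deliberate: real genomic SINE subfamily spectra are strongly uneven (Alu
subfamilies dwarf MIR), and the Pearson statistic is only informative
when there is across-family variation to track — under a uniform
distribution both vectors are flat and the statistic degenerates toward
its undefined regime. Enrichment scenarios draw candidate families i.i.d.
from the background distribution (null) or from a distorted distribution
(`enrich=(family, fold)`) to recreate both the no-enrichment and the
enriched regime.

Genomic sequence is uniform random A/C/G/T except that every reference
CDS genuinely starts with ATG on its own strand; repeat intervals carry
no consensus sequence (the screen is coordinate-driven, and designer
tests use their own sequence fixtures). All randomness flows from one
seeded generator; the FASTA content uses a second stream derived from the
seed so coordinates are identical whether or not sequence is emitted.
Every planted constraint is re-verified by independent per-base checks
before files are written, and same-seed runs are byte-identical.

What a green test establishes — and what it does not: the synthetic world
has single-exon transcripts at generation time (multi-exon and
junction-spanning cases are covered by direct unit fixtures and fuzzed
transcripts, not by the generator), no overlapping genes, no isoform
ambiguity, no annotation noise, and planted classes that fail exactly one
filter each. Recovery of planted truth therefore validates the coordinate
logic of the cascade, not its behaviour on messy real annotation.

## Numerical and degenerate-input choices

- Interval intersection is a linear sweep over sorted exon chains,
  validated against per-base set-intersection oracles on fuzzed loci.
- Boundary semantics are half-open everywhere: a transcript ending 1 bp
  before a window does not overlap it; a CAGE cluster at distance exactly
  `halfwidth` supports, `halfwidth + 1` does not.
- Identical sense/antisense spans classify as full-length.
- An empty assembly yields an all-zero funnel, not an error; a reference
  set with no CDS-bearing transcript warns and empties the TIS stage.
- Requesting a repeat class absent from the annotation is a configuration
  error naming the known classes (likely a typo, not an empty result).
- The funnel report validates its own monotonicity at construction.

## Known limitations

Single-chromosome simulation by default; no read-level or expression
simulation; no RNA secondary-structure assessment of effector domains; no
ranking of candidates by predicted activity; GFF3 and compressed inputs
are out of scope.
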
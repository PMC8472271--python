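# Methods

`mirddr` implements a two-library small-RNA-seq analysis of the kind used to
profile miRNAs responding to a genotoxic treatment (e.g. bleomycin-induced
double-strand breaks in rice roots): read QC, tag annotation, novel-miRNA
hairpin discovery, exact-test differential expression, family summaries,
target prediction, term enrichment and RT-qPCR quantification. This note
records the models, the parameters that matter, and the design choices made
where the methodology was genuinely open.

## Read QC

Reads are adapter-trimmed at the leftmost exact occurrence of the first 8 nt
of the 3' adapter (default: the Illumina TruSeq small-RNA adapter,
`TGGAATTCTCGGGTGCCAAGG`). Reads with no adapter, or beginning with the
adapter (empty insert), are discarded. Trimmed inserts are then filtered in a
fixed order — N fraction, base quality, nucleotide composition — so that each
read lands in exactly one accounting category:

| filter | rule | default | note |
|---|---|---|---|
| N content | count(N)/length > `max_n_fraction` | 0.10 | strict inequality: a 20-nt read with 2 N passes |
| low quality | > `max_low_quality_fraction` of bases below `min_phred` | 0.50 / Q20 | the source protocol never defines "low quality"; this standard rule is adopted and exposed |
| poly-X | any single nucleotide ≥ `polyx_fraction` of the read | 0.80 | likewise undefined at the source; exposed |

Analysis then keeps inserts of 18–30 nt inclusive. Percentages are reported
to 2 decimals, rounded half-up, matching the presentation convention of the
reference study's QC table.

## Annotation cascade

Clean reads are collapsed to unique tags with per-library counts and mapped
to the genome by exact full-length search on both strands (all hits kept).
Each mapped tag receives exactly one class, in fixed priority:

known_miRNA → rRNA → tRNA → snRNA → snoRNA → repeat → NAT →
exon (sense, antisense) → intron (sense, antisense) → other.

Placing known miRNAs first prevents miRNA counts from being cannibalised by
incidental overlaps with ncRNA fragments; the order is configurable. Known
miRNA matching allows ≤ 2 substitutions and ≤ 2 nt of summed 5'/3' offset
(no indels), admitting cross-species variants the way miRBase-style screens
do; ties resolve by fewest substitutions, smallest offset, then name. The
miRNA family is the maximal `miR<digits>` token after stripping the species
prefix (`ath-miR166a-3p` → miR166).

## Novel-miRNA hairpin screen

Tags that map but match nothing ("other") with ≥ 2 supporting reads are
hairpin candidates. Around each genome hit two windows are excised (tag plus
120 nt upstream, tag plus 120 nt downstream, clipped at contig ends) and
folded by base-pair maximisation (Nussinov-style dynamic programming over
A:U, G:C and G:U pairs, minimum hairpin loop 3 nt). Pair maximisation stands
in for a thermodynamic folding energy: the screening criteria are structural
rather than energetic, and a pairing-fraction threshold plays the role of a
free-energy cut-off. A configuration hook is left for substituting a true
energy model.

Traceback is deterministic: ends that can stay unpaired without losing a pair
are consumed first, pairing (i, j) is preferred over bifurcation, and
bifurcations split at the leftmost optimal point. The unpaired-ends-first
rule matters: among the many co-optimal max-pairing structures it selects a
local, stem-like one rather than structures enclosing the window ends, which
is what the duplex criteria below assume.

A candidate passes when (a) the mature tag and its star partner lie on
opposite arms of a single stem, (b) at most 4 mature bases are unpaired in
the duplex, (c) no asymmetric bulge in the duplex exceeds 2 nt, (d) the
precursor pairing fraction is ≥ 0.55, and (e) the mature length is 20–24 nt.
Star support is called when an independently sequenced tag maps onto the star
arm with miRNA/miRNA* duplex geometry — its 5' end within ±2 nt of the
pairing partner of the mature 3' end (the 2-nt 3'-overhang convention).
Overlapping passing windows on a contig are merged into one locus,
represented by its most abundant tag.

## Differential expression

With one pooled library per condition, significance comes from the
Audic–Claverie exact test. Conditional on count x in library 1 (N1 total
clean reads), the count y in library 2 (N2 total) follows

    p(y | x) = (N2/N1)^y · (x+y)! / (x! y!) / (1 + N2/N1)^(x+y+1),

evaluated in log space via log-gamma. Both tails include the observed count;
the two-sided p-value is 2·min(lower, upper), capped at 1. The test runs on
raw integer counts: the factorials require integers, so normalised values
enter only the fold change. This is the standard reading of the method even
where a source describes x and y as "normalized expression levels".

Normalisation is reads-per-million ("TPM"): count/total × 10^6, at full
precision internally and 2 decimals half-up in reports. Exact zeros are
floored to 0.01 before fold changes; entries with both libraries below 1 TPM
are excluded as too lowly expressed ("both" rather than "either", which would
discard exactly the strong on/off cases the method is meant to find).
log2FC = log2(treated/control). A miRNA is UP when log2FC > 1 and
Benjamini–Hochberg q < 0.05, DOWN for the mirror image; both inequalities are
strict. BH is the default FDR procedure (Benjamini–Yekutieli available).
Family summaries sum member counts; a family is ND when its summed reads are
below 5 in both libraries.

The bundled reference family-abundance table reproduces its printed fold
changes through these operations. Rows with small normalized values can
differ in the second decimal because the printed inputs are themselves
rounded to 2 decimals (and were averaged over replicates upstream); the
reproduction therefore carries, per row, the interval-arithmetic bound that
±0.005 on each input propagates to the fold change, and the bundled loader
reports both the exact 2-decimal comparison and that bound.

## Target prediction

A miRNA is aligned antiparallel against every transcript window (at most one
single-nucleotide gap on either strand) and penalised per position: mismatch
1.0, G:U wobble 0.5, gap 2.0, with penalties doubled at miRNA positions 2–13
counted from the 5' end. Sites with total expectation ≤ 4.0 are reported —
the canonical plant-miRNA scoring scheme; every parameter is exposed.
Additional structural constraints (on by default) reject sites with any
non-pair at positions 10–11, more than two consecutive non-pairs, or more
than one non-pair within positions 2–12; for these rules a wobble or gap
counts as a mismatch. All reported sites are cleavage-style; central-bulge
(translational-inhibition) classification is not implemented. Genes are
collapsed through the transcript→gene map when gene models provide one, else
per transcript.

## Enrichment

Per term: hypergeometric upper tail P(X ≥ k) with N background genes, K in
the term, n query genes, k hits (one-sided Fisher equivalent — no source
statistic was specified, this is the field default). q-values are BH within
each annotation category; the rich factor is k/K. The annotation map is
taken as given: no GO-graph ancestor propagation is performed (a documented
limitation), and the background defaults to all annotated genes.

## RT-qPCR

2^−ΔΔCt with ΔCt = mean Ct(target) − mean Ct(reference) per group and
ΔΔCt = ΔCt(treated) − ΔCt(control). Replicates pair by index for the
dispersion estimate (SD of per-replicate 2^−ΔΔCt, SE = SD/√n); no
primer-efficiency correction. Direction concordance between sequencing and
qPCR uses a ±0.1 dead zone on the log2 scale, below which the call is NULL.

## Synthetic validation data

All quantitative guarantees are established on synthetic libraries whose
ground truth is planted, at a deliberately scaled-down problem size: two
libraries of 200,000 reads each, 20 known miRNAs (five planted at
|log2FC| = 2), five novel hairpin loci (three with star reads), eight
contaminant tags per ncRNA class, plus exon/intron, unannotated and unmapped
tags. Dataset-scale absolute outcomes of a real experiment — how many
hundred known miRNAs, how many dozen novel loci, how many thousand target
genes a full ~15-million-read library pair yields against full reference
databases — depend on those data and database snapshots and are exercised
here only in this scaled-down synthetic form; the pipeline's arithmetic, not
those totals, is what the test suite pins down.

The generator emulates: adapter-ligated exact tag copies; per-tag
negative-binomial counts (Poisson at dispersion 0, matching the sampling
model the exact test assumes — the dispersion knob exists precisely to probe
the test beyond its assumptions); log-uniform mean abundances (known miRNAs
50–2000, contaminants 100–5000, novel loci 5–40 expected reads, stars at 30%
of their mature); forced dropouts; and optional non-overlapping defect reads
(N-rich, homopolymer, adapterless) at configured rates. For the type-I-error
calibration, tags draw log-uniform mean counts on [10, 200] — moderately
expressed tags, the regime where a two-library exact test is normally
applied; an operating-characteristic calculation during design put the null
rejection rate near 0.04–0.05 across this and neighbouring ranges, so the
choice is not delicate. It does not emulate: sequencing substitution errors,
quality-score error profiles, isomiR heterogeneity, multimapping repeat
structure, or cross-mapping between families — so passing tests demonstrate
the pipeline's statistics and bookkeeping, not robustness to those artefacts.

Novel loci are embedded on dedicated contigs as perfect inverted repeats
(60-nt arms, 8-nt loop) with 2-nt genomic flanks. The short flank is
deliberate: under pair maximisation, stray flank bases inside the fixed
excision window can displace stem pairs and manufacture duplex bulges larger
than real; 2 nt bounds that artefact to the tolerated bulge size. A
thermodynamic folder would not need this, which is a fair summary of the
limits of the max-pairing proxy.

## Numerical conventions

Phred+33 only; U→T at ingest, RNA alphabet restored only in hairpin reports;
ambiguity codes other than N rejected. Coordinates are 0-based half-open
internally, 1-based inclusive in every emitted file. Reported percentages,
TPM and fold changes round half-up to 2 decimals; all statistics are
computed at full precision. All randomness flows through explicitly threaded
seeds; identical configurations reproduce byte-identical outputs (gzip
streams are written with a zeroed timestamp for this reason).
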
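# Methods

## Variant identity

All coordinates are 1-based and fully closed, as in VCF. A variant's
identity is the normalized tuple (chrom, pos, ref, alt, type). Chromosome
labels are canonicalized at ingest (any `chr` prefix stripped, `M` mapped
to `MT`; vocabulary 1–22, X, Y, MT). Allele normalization trims the shared
suffix first, then the shared prefix, always retaining at least one base
per allele so indels stay anchored VCF-style, and advances the position
past trimmed prefix bases. Trimming suffix-first means that, within the
allele strings provided, the anchor lands as far left as possible — in a
homopolymer run, a representation padded with upstream context normalizes
to the leftmost anchor that context allows. Full left-alignment across a
repeat tract would require the reference sequence, which the normalizer
deliberately does not take: catalogue confrontation only needs a canonical
form, and both sides of a comparison are normalized by the same rule.

Equal-length multi-nucleotide substitutions (e.g. `AT>GC` after trimming)
are rejected: the engine's scope is SNVs and simple indels, and every
downstream classification (functional class, frameshift test, Ti/Tv) is
defined only for those. Multi-allelic VCF records are split into one
observation per alternate allele before normalization.

## Taxonomy

Coding SNVs are classified from their reference/alternate codon pair under
the standard nuclear genetic code (translation table 1): synonymous (same
residue — including stop→stop), nonsense (residue→stop), stop loss
(stop→residue), missense (otherwise). The codons must differ at exactly one
position. Coding indels are frameshift when `|len(alt) − len(ref)| mod 3 ≠ 0`,
non-frameshift otherwise; non-coding indels carry no class.

Genic regions distinguish CDS, UTR5/UTR3 (decided by CDS bounds and
strand), the splice dinucleotide (intronic distance 1–2 bp from the
nearest exon boundary) and the intron flank (3–20 bp, the deepest intronic
positions exome capture annotation retains). Positions deeper than 20 bp
into an intron, or outside the locus span, raise an out-of-capture error.
Exon and intron ordinals are numbered along the direction of transcription.

When an input file already carries a functional class, the classifier
validates rather than recomputes: discordances are reported with the
offending key, and the file's value wins. Recomputation from gene models
exists primarily so the simulator and tests can build fully consistent
annotations.

## Filter recipes

A recipe is a conjunction; empty fields are inactive. Catalogue exclusion
is presence/absence on the normalized key and/or rsID (policy `key`,
`rsid` or `either` per catalogue — `either` by default, because public
catalogues mix positional and rsID-only records); the catalogued entry's
zygosity or frequency is never consulted. `min_quality`/`min_coverage` are
inclusive lower bounds on the Phred-scaled site quality and read depth.

Region and class constraints are evaluated per transcript annotation
*jointly*: an annotation qualifies only if it satisfies both, and a variant
passes when any annotation qualifies (`annotation_match="any"`, switchable
to `"all"`). Any-transcript matching maximizes sensitivity, appropriate for
a screening tool; the joint evaluation keeps region and class coherent on
one transcript (a variant that is synonymous on one transcript and splice
on another cannot pass a "missense CDS" request by mixing the two).

The primary screen is the stringent first-pass recipe: exclude every
supplied catalogue, keep heterozygous variants whose molecular type is
presumed deleterious — missense/nonsense/stop-loss CDS SNVs, frameshift
CDS indels, and splice-dinucleotide variants. Because splice-site
annotations carry no coding class, the screen's class set includes NONE
alongside the four deleterious classes; CDS annotations always carry a
real class, so NONE admits splice-site annotations only.

Recipes execute on two interchangeable paths: an in-memory evaluation over
the project and a compilation to a single parameterized SQL query against
the embedded SQLite store (tables individual / variation / observation /
annotation / catalogue_*). The two paths are cross-checked on random
recipes in the test suite. Output order is deterministic: karyotype
chromosome order, position, alleles, individual.

## Inheritance strategies

*Recurrence* counts, per gene, the distinct selected individuals carrying
at least one qualifying variant in that gene — any variant, not the same
allele — and bins each gene at its exact carrier count, so levels are
mutually exclusive and sum to the number of distinct genes hit. A
`zygosity_mode="recessive"` variant of the carrier test requires a
homozygous variant or ≥2 distinct heterozygous keys (potential compound
heterozygote) instead of any single variant.

*Intra-familial sharing* returns keys present in **all** selected
relatives with zygosity matching HOM, HET or EITHER, grouped by gene.
*Compound heterozygotes* are genes with ≥2 distinct HET keys in one
individual; without parental genotypes this unphased superset is reported
as-is, and when both parents are supplied, genes whose candidate keys all
trace to a single parent are removed (two keys transmitted through one
chromosome cannot be in trans). *De novo* retains child keys absent from
both parents at any zygosity — a parent carrying the key at all
contradicts de novo origin — and is symmetric in the parents. Over the 27
(child, father, mother) combinations of {absent, HET, HOM}, exactly the 2
child-carrier/parents-absent combinations are retained.

## Statistics

Ti/Tv classifies each SNV's ordered base pair (transitions A↔G, C↔T);
the ratio is undefined (None) when no transversion was seen, and
ti + tv equals the number of SNVs summarized by construction. Count
distributions include zero-count labels for fixed vocabularies
(chromosomes, regions, classes) and observed labels for open ones
(individuals, signed indel lengths); records not carrying the requested
axis are counted and reported in the frame's metadata. The amino-acid
matrix is 21×21 (20 residues + stop) over coding SNVs, one cell per
variant from its first coding annotation (residues if present, else
translated codons); the diagonal collects synonymous changes. Both
project-wide and per-individual groupings are available by pre-filtering
the variant list. All summaries are plain tables; no plotting is required
to compute or test them.

## Synthetic cohorts

The simulator emulates a multi-individual rare-disease exome study over
toy gene models: by default 200 genes × 10 exons (150 bp exons, 300 bp
introns, 100 bp terminal UTRs) laid across chromosomes 1–22/X, 14
unrelated affected index cases with Poisson(15,000) variants each, 93.4%
drawn from a shared catalogued site pool (so ~6.6% unknown), 80/20
HET/HOM, 95% SNVs, and a class mix dominated by synonymous and missense
changes. Functional classes are controlled exactly by sampling codon
substitutions from the pre-enumerated genetic-code combinations of the
requested class. Tests and the acceptance script run the same generator at
roughly 100× reduced variant counts (tens to a few thousand variants per
individual), which exercises every code path while keeping the default
suite fast.

Plants bypass all stochastic choices: each carrier receives its own
distinct unknown CDS SNV of the requested class and zygosity, and planted
genes receive no background variants, so a plant's recurrence level equals
its carrier count deterministically. Trio children are built by
transmitting each parental variant with probability 0.5 (sites inherited
from both parents become HOM), so only planted variants can be de novo.
Identical config and seed give byte-identical output trees: writers emit
no timestamps and all iteration orders are fixed.

What the simulator does **not** model: mutation-rate heterogeneity,
linkage disequilibrium, allele-frequency spectra, sequencing error,
strand-specific gene models (all simulated genes are `+` strand; strand
handling is exercised by unit tests on hand-built models), or realistic
Ti/Tv (codon substitutions are uniform within a class). Passing tests on
simulated cohorts therefore demonstrate the correctness of the set
algebra, not calling or annotation quality on real data.

## Numerical and design notes

- Quality values re-read from VCF are rounded to 4 decimals to cancel
  float32 representation noise from htslib, so the VCF and TSV dialects
  decode to identical observations.
- VCF records failing FILTER are kept but flagged; exclusion is left to
  the recipe's quality threshold.
- XLS input is not supported (TSV and VCF only); VCF writing, BAM/FASTQ
  reading, pathogenicity prediction and structural variants are out of
  scope.
- The overview table displays the six exonic classes and the ±2 bp splice
  column, counting each variant once (coding classes take precedence over
  splice; among coding SNV classes the most severe transcript annotation
  decides: nonsense > stop loss > missense > synonymous). UTR and
  intron-flank variants are not displayed but remain filterable.
- The CLI is a thin shell over the library and the store; exit codes are
  0 (ok), 1 (usage), 2 (data/config error).
- Store schema version is recorded in the database and checked on open;
  re-loading identical inputs replaces content wholesale (idempotent).
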
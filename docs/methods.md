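# Methods

## Annotation model and geometry

Genomes are circular; coordinates are 1-based and inclusive on both ends,
matching the convention of published mitogenome organization tables, and
are converted to 0-based half-open indices only when a sequence is sliced.
Features may not span the origin — the records this package targets start
their coordinate system at *cox1* position 1, so no gene crosses the
junction — and an annotation that would need an origin-spanning feature is
rejected rather than modeled.

The signed spacer between consecutive genes is
`downstream.start − upstream.end − 1` (negative = overlap); the junction
spacer between the last and first gene is
`(genome_length − upstream.end) + (downstream.start − 1)`. The
"intergenic nucleotides" column of an organization table is interpreted as
the spacer *before* each gene, from the previous gene circularly; on the
bundled tables this is the only reading consistent with the first-row
values given where the last gene ends. With one spacer per adjacent pair
(junction included) the tiling identity

    Σ gene lengths + Σ signed spacers = genome length

holds exactly on every valid circular annotation; it is asserted on the
bundled tables and on randomly generated genomes, and is invariant under
coordinate rotation.

Amino-acid counts are `span/3 − 1` per protein gene, excluding the
terminator. One bundled table cell disagrees with its own span (atp6,
printed 232 aa for 696 nt); the formula value (231) is used, which makes
both bundled genomes total 3,744 aa. Spans not divisible by 3 are flagged
and excluded from totals rather than rounded.

Validation returns machine-readable findings (out-of-range coordinates,
unsorted features, duplicate names, frame violations, missing codons,
overlaps longer than a partner gene, deviations from the 13 PCG / 22 tRNA /
2 rRNA census) instead of raising, so a pipeline can report a questionable
annotation without dying on it.

## Composition

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C) from base occurrences;
A+T content is a percentage of unambiguous bases. IUPAC ambiguity codes are
tolerated, counted separately, and excluded from every denominator; a skew
whose denominator is zero is undefined (None/NaN), never coerced to 0. All
per-region statistics are computed on the (+) strand regardless of gene
strand, matching how such tables are conventionally reported; a
`gene_native_strand` flag switches to reading-orientation sequences for
exploration. Multi-gene classes concatenate subsequences in annotation
order, and bases shared by overlapping genes count once per region that
contains them (rows are per-region, not a partition of the genome). Report
output rounds to 2 decimals; full precision stays available in the
underlying frame.

## Codon usage

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp), under which there are
62 sense codons; the code id is configurable and synonymous families are
derived from the table, so switching codes changes every downstream
statistic consistently. Codons are read gene-strand (minus-strand genes
reverse-complemented), terminators are excluded from counts, and an
internal stop is a reported finding, not a fatal error.

RSCU(c) = n(c) · |family| / Σ family counts. A family with zero total has
undefined RSCU (reported as missing, not zero). RSCU is computed over all
PCGs pooled by default, with a per-gene option.

"A+T-rich codon" is defined here by majority rule: a codon with ≥ 2 of its
3 positions in {A,T} is A+T-rich, otherwise G+C-rich (no ties are possible
with three positions). The reported ratio divides *occurrences*, not codon
types. Both choices are this package's resolutions of terms that the
comparative-mitogenomics literature uses without definition, and they are
flagged as such here.

## Divergence

P and Q are the transition (A↔G, C↔T) and transversion proportions over
sites that carry an unambiguous base in both sequences (pairwise deletion;
complete deletion would discard more signal than the data warrant, and the
choice is stated because published methods sections often leave it
implicit). The K2P distance is −½ ln(1−2P−Q) − ¼ ln(1−2Q); its standard
error uses the standard delta-method variance
(c₁²P + c₃²Q − (c₁P + c₃Q)²)/n with c₁ = 1/(1−2P−Q), c₂ = 1/(1−2Q),
c₃ = (c₁+c₂)/2. A pair whose log arguments are non-positive is saturated:
the distance is undefined (NaN in matrices) with P and Q retained, never a
clamped large number that would silently corrupt a matrix. Inputs must be
pre-aligned; alignment itself is out of scope, and simulated data are
indel-free hence aligned by construction.

## Gene order

Orders are circular signed permutations. Equality is judged on a canonical
form: rotate the circle so a reference gene (*cox1*) comes first, flipping
the whole molecule (reverse order, all strands inverted) first if the
reference sits on the minus strand. Breakpoint distance counts adjacencies
of one order absent from the other; adjacencies are signed by default
(an adjacency x→y equals −y→−x, stored under a canonical representative),
with an unsigned mode for coarse comparison. Signed distance 0 is
equivalent to canonical-form equality. The implementation is checked
against an independent adjacency-enumeration oracle over every signed
circular permutation of up to 6 genes.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
defaults chosen to match the gastropod genomes this package was built
around: 37 genes (13 PCG / 22 tRNA / 2 rRNA) in the Littorinimorpha
consensus order, template gene sizes near the observed ones (tRNAs drawn
62–72 bp), short geometric spacers (p = 0.18, capped at 30 bp), one large
45–55 bp gap upstream of *cox3* modeling the putative control region, four
small fixed overlaps, whole-genome A+T target 66.2% with AT skew −0.13 and
GC skew +0.02 on the (+) strand. Realized genome length lands near 15.3–
15.5 kb. All randomness flows from a single config seed; equal configs
give byte-identical genomes.

Coding sequence is built codon-wise (fixed ATG start, TAA/TAG stop, sense
codons only), with the codon sampling distribution moment-matched so that
coding regions hit the same target base composition despite the exclusion
of the A+T-rich stop codons; `codon_bias_strength` exponentiates the
sampling weights to strengthen usage bias. The four default overlaps are
placed only where the downstream partner is an RNA gene, whose sequence is
unconstrained, so protein reading frames and terminal codons survive
overlap construction; real genomes also show a PCG–PCG overlap
(*nad4l*→*nad4*), which the generator does not emulate. The generator also
makes no attempt at tRNA secondary structure, realistic rRNA sequence, or
a functional control region — passing tests show the analysis stack is
correct on data with the assumed composition, geometry and order
statistics, not that it has been exercised on every quirk of real
mitogenomes.

Divergent pairs are produced by evolving two descendants, each half the
requested tip-to-tip distance, under the K2P substitution process with
rate ratio κ (default 2), using the exact per-site transition
probabilities; substitutions are indel-free so the pair stays aligned.
Start/stop codons of protein genes are masked (held invariant) by default
so descendant annotations remain valid — 78 of ~15,300 sites, a < 1%
perturbation well inside estimator error — and a free mode disables the
mask. An optional `codon_position_rates` triple assigns relative rates to
the three codon positions of protein genes (renormalized to genome-wide
mean 1), which emulates purifying selection by concentrating change at
synonymous third positions; the default is homogeneous. The truth record
carries the parameters, the analytically expected P and Q between the
tips, and a practical-saturation flag raised when an expected log argument
falls below 1e−3 (exact expectations never reach zero at finite distance,
but beyond that point finite sequences routinely yield undefined
estimates).

## Numerical and testing choices

Stochastic tests are derandomized with fixed seeds; the K2P recovery check
uses 10 kb sequences at distances 0.05/0.15/0.3 and requires the estimate
within 2 standard errors of truth. Property suites run at sizes that keep
the default test run fast (100 generated genomes for the tiling identity,
200 random draws for RSCU/skew properties, exhaustive signed permutations
to n = 6 for the breakpoint oracle). Report tables round percents and
skews to 2 decimals and distances to 4–6; rounding is display-only.

## Known limitations

- Sequence-level statistics for the two bundled real genomes need the
  user-supplied GenBank records; the bundled fixtures are geometry-only.
- No alignment, no tree inference, no divergence dating, no rearrangement
  scenario reconstruction — inputs are annotated/aligned, outputs are
  descriptive statistics and distances.
- Origin-spanning features are rejected; annotations whose coordinate
  system does not start inside a gene-free region near *cox1* must be
  rotated first (`GenomeAnnotation.rotated`).
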
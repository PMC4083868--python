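# Methods

## Data model

A haplotype matrix is subjects × SNVs × allele-columns. Phased data has two
allele columns per SNV; column 0 is the allele left of the VCF `|`
separator and is displayed as "P", column 1 the right allele, displayed
"M". True parental origin is not recoverable from a VCF, so P/M is a
display convention, applied consistently across IO, aggregation and
rendering. Unphased diploid data keeps two columns (the genotype encoding
collapses them at render time); a one-column matrix models haploid views.

Calls are packed at 2 bits per cell with the fixed alphabetical code
A=0, C=1, G=2, T=3, four cells per byte, most significant pair first. The
code space has no room for a fifth state, so missingness is a separate
packed bit mask (one bit per cell) and masked cells carry payload code 0 to
keep the payload defined. Size reports therefore distinguish the payload —
exactly 2·n·m·p bits, 4 bits per subject and SNV when p = 2 — from the
mask's n·m·p bits. The naive baseline used for the 8× compression ratio is
2 bytes per character, the in-memory cost of one UTF-16 character
primitive.

Matrices are immutable; filters, sorts and aggregation return new objects,
and `calls(subject_indices, variant_indices)` decodes only the requested
sub-block, so no global decompressed copy is ever materialized. Variants
are sorted by (chromosome, position) at construction, ties broken by ID;
chromosome order is lexicographic, which is stable and format-agnostic even
though it places "10" before "2" (a cosmetic matter for display, since
region queries compare names exactly).

## Input formats

VCF reading is backed by pysam; only CHROM, POS, ID, REF, ALT and
FORMAT/GT are consulted. Records that are not biallelic SNVs
(multi-allelic, INDELs, symbolic alleles) are skipped with a logged count.
`.` GT sub-fields become MISSING; a ploidy-1 call leaves the second column
MISSING; a record is phased when every informative diploid call uses `|`,
and a file mixing separators is loaded but marked unphased with a warning.
Plain-gzip inputs are inflated to a temporary file first because htslib
only seeks in plain or BGZF streams. The IMPUTE2 reader maps hap-file
token 0 to the legend's a0 allele and 1 to a1 (`?` to MISSING); the legend
carries no chromosome, so loaded triples use chromosome "1", matching the
writer. The meta dialect is tab-delimited with two header lines (names,
then CATEGORICAL/NUMERICAL declarations, case-insensitive); empty cells and
`NA` are absent values.

## Filtering and sorting

The frequency filter uses the per-allele non-reference frequency over
non-missing calls of all subjects and both allele columns — the reading
consistent with a single threshold applied across all individuals of
phased data. A subject-level genotype frequency would be a different
statistic; it was considered and not implemented because every use of the
threshold here concerns allele counts. Thresholds are strict inequalities
in both directions, so a variant exactly at the threshold is excluded by
both the `above` and the `below` filter. All-missing variants have
undefined frequency and are dropped with a logged count. ID-regex
filtering uses full-match semantics, not substring search, to make filters
predictable.

Sorting is a stable sort on one key; categorical labels order
lexicographically, numerical values ascending, and rows absent from the
annotation sort last in their prior order. Stability is what makes
consecutive sorts compose into compound keys.

## Aggregation

Within a group, each (SNV, allele-column) cell tallies the members'
non-missing calls. `maximum` keeps the modal base and its relative
frequency; `minimum` keeps the least frequent *observed* base. Ties break
by A < C < G < T, deterministically. MISSING is excluded from tallies
rather than treated as a fifth category; the informative count is stored so
rendering can distinguish a confident consensus from one based on few
calls, and a cell with no informative calls renders white. A mean is
undefined for categorical base data, so for haplotype cells only maximum
and minimum are offered; meta columns aggregate with minimum / maximum /
mean (numerical) or mode with lexicographic tie-break (categorical).
Stored frequencies are always the consensus frequency f; the "rarity" view
of minimum-method aggregations is a rendering flag that draws bar heights
as 1 − f rather than a different stored value.

## Rendering

The canvas is a plain RGB raster whose dimensions are exact affine
functions of the matrix shape: grid = rows·cell_h by
display-columns·cell_w, plus fixed label margins (72 px left, 30 px top,
only when identifiers are shown), a 2 px gap before each meta panel, and
meta_cell-sized annotation columns/rows. Cell sizes are the zoom level;
1×1-pixel cells are valid.

Default colors are qualitative ColorBrewer-style picks (Set1 for bases:
A = #4DAF4A green, C = #377EB8 blue, T = #E41A1C red, G = #FFFF33 yellow;
the same blue/yellow for the reference encoding and green/yellow/red for
the genotype encoding; a Set3-like cycle for categorical annotations).
They are this package's documented defaults — the words "green/blue/red/
yellow" fix the hues, not exact RGB values, and no pixel parity with any
other implementation is claimed. All colors are overridable in code or
via a YAML options file.

Saturation-mode aggregate cells scale the base color's HSV saturation by
0.15 + 0.85·f; the floor keeps low-frequency cells visible and the mapping
is monotone in f, which is the property that matters. Bar-mode cells draw
a bottom-anchored bar of height round(f·cell_h) in the fully saturated
base color on white. Selection highlighting draws a black (configurable)
outline around chosen rows or columns. Raster export goes through Pillow
(deterministic bytes for PNG on one platform; identifier text uses
Pillow's built-in bitmap font so no system font enters the output); SVG
and PDF wrap the raster in a vector container via matplotlib.

## Synthetic cohorts

The generator mirrors a world-wide phased panel in miniature: 14
populations in 4 super-populations by default, subject counts per
population configurable. Each variant gets a per-population alternate
frequency: common variants draw from Uniform(0.05, 0.5), a configurable
fraction (default 0.3, echoing the large rare-variant share of modern
resequencing panels) are rare with all per-population frequencies below
the 0.005 threshold. Alleles are i.i.d. Bernoulli draws per allele column
— there is deliberately no linkage-disequilibrium, demography or
recombination model, so passing tests demonstrate the correctness of
storage, filtering, aggregation and rendering, not realism of haplotype
structure; real panels also show correlated missingness and
population-specific rare-variant patterns the generator does not emulate.
Calls go missing independently at rate 0.01, enough to exercise every
missing-data path without distorting frequencies. One designated site can
be fixed (frequency 1.0) for one population, giving a known
differentiating site for aggregation demonstrations. All draws come from
one seeded generator, so a spec is fully reproducible.

## Pipeline

The CLI executes stages in a fixed order — load, filters in declared
order, row sorts, column sorts, aggregation, render — because a
reproducible batch tool needs a deterministic composition even though the
operations themselves would commute only partially. Every stage appends a
line with before/after dimensions to the transformation log. Validation
(thresholds, region syntax, regex compilation, format names) runs before
any file is read.

## Verification scale

The test suite and `scripts/acceptance.py` run the oracle comparisons at
desk scale, chosen to finish in seconds while covering every code path:
codec round trips on 10⁴ random arrays, filters against linear-scan
oracles on a 504-subject × 2000-variant cohort, aggregation against
per-cell tally oracles on a 14-population cohort (70 subjects × 120
variants, both methods, plus singleton groups), the stable-sort law on 100
random two-column tables, and the full workflow on 84 subjects × 200
variants. The memory model is checked analytically at the full
10³ × 4·10⁶ scale since it is arithmetic, not simulation.

## Known limitations

No BCF, no INFO-field parsing, no phasing (inputs are assumed phased
upstream), no polyploid support (the two-column design extends naturally
but is not implemented), no LD-aware filtering or plots, and no
interactive features — the renderer produces static figures only.
Aggregation replaces member rows in the rendered view; the un-aggregated
matrix remains available programmatically.
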
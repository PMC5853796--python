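# Methods

## The model

The unit of analysis is the canonical hexamer: the equivalence class of a
6-mer and its reverse complement, represented by the lexicographically
smaller member. This collapse is exact — 4096 hexamers partition into 2016
complementary pairs and 64 palindromes, 2080 classes — and makes every
downstream count strand-invariant, so peak and promoter sequences can be
read on whichever strand they come in.

Scanning slides a 6-bp window over every start position; overlapping
occurrences all count. Windows containing `N` are invalid and are removed
from both the occurrence counts and the denominator of possible positions,
which keeps the two proportions of every enrichment test comparable.
Lowercase (repeat-masked) letters are valid by default and become invalid
under `respect_mask=True`; this supports re-running the analysis on
RepeatMasker output without the package running RepeatMasker itself. The
choice of "valid by default" is deliberate: masking conventions vary
between sources, and the masked variant is a sensitivity analysis, not the
primary run.

Association is a 2×2 contingency per (hexamer, dataset, status): presence
of the hexamer in the gene's upstream window against the gene being up-
(down-) regulated, over the dataset's measured gene universe, scored with
the one-sided Fisher exact test (upper hypergeometric tail; enrichment
only, depletion is out of scope). Per status, the k per-dataset p-values
combine via Fisher's method, χ² = −2 Σ ln Pᵢ on 2k degrees of freedom. The
two statuses are combined separately by default because reported biology is
status-specific; a pooled `("both",)` mode exists for completeness.
Bonferroni multiplicity defaults to (features tested) × (statuses tested),
i.e. 2 × 2080 = 4160 for a full hexamer run; selection threshold 0.005 on
the corrected meta p.

## The permutation test and the staged selection

Fisher's method assumes the Pᵢ are independent. Real compendia share
responsive genes across experiments, so the per-dataset p-values are
positively correlated and the analytic meta p-value is anti-conservative —
measurably so: in synthetic nulls with persistent DEG status, null meta
p-values reach 10⁻⁹ orders of magnitude more often than the nominal rate.
The permutation test supplies the honest null: each iteration draws one
uniform bijection mixing promoters between genes (each promoter used
exactly once), shared by all hexamers and all datasets, which preserves
both the inter-hexamer presence correlations (overlapping words) and the
inter-dataset status correlations. Permuting the presence-matrix rows is
mathematically identical to re-scanning shuffled sequences and O(1) per
iteration in sequence length. "Not greater than" is implemented inclusively
(ties count toward m), with observed and permuted statistics computed by
the same table arithmetic so ties compare exactly; P = (m+1)/(M+1).

Selection is staged, mirroring the sequential procedure the method
describes: the Bonferroni-corrected meta screen (< 0.005 over 4160 tests)
nominates candidates, and the permutation stage then confirms or rejects
them. Two permutation-null variants are implemented. The per-feature null
(default of `permutation_test`) compares each observed meta p only with its
own feature's M permuted values; it is the directly worded reading, but its
resolution floor 1/(M+1) means a desk-scale M cannot clear a corrected
threshold — with the 4160-fold correction one needs M ≳ 10⁶, the scale the
method was originally run at. The pooled null (used by
`two_stage_selection`, the pipeline, and `state_association`) compares each
observed value against the permuted values of *all* features and statuses —
defensible because all features share the same margins-and-correlation
structure and identical degrees of freedom — giving M × 4160 null draws and
a corrected-p floor of 4160/(200·4160+1) ≈ 0.0049999 at M = 200. The full
family-wise multiplicity is kept at the permutation stage; correcting only
over the screened candidates was considered and rejected as a screening
fallacy (it demonstrably passes null screen hits whose pooled quantiles are
~10⁻⁵, far from family-wise significant).

A consequence worth stating plainly: with correlated datasets and M = 200,
planted-motif replicates whose observed meta p lands above roughly 10⁻¹²
are *genuinely* not family-wise significant under the permutation null, and
the pipeline will (correctly) decline to select them. Recovery of a motif
planted at p_fg = 0.5 vs p_bg = 0.1 over three correlated datasets of 2000
genes is therefore ranked-first essentially always but
permutation-confirmed in only ~80% of replicates at M = 200; raising M (the
`permutations` knob) restores power, at the published scale (10⁶)
comfortably.

## Region and chromatin-state enrichment

Positional occupancy — 6-bp start positions occupied per possible positions
— is compared between a foreground and a background with the same one-sided
Fisher test. Peaks are merged before counting (overlapping peaks would
otherwise double-count positions); peak sequences are taken from the genome
as given, canonical matching making strand irrelevant; peaks running past a
chromosome end are truncated with a warning; segments shorter than 6 bp
contribute zero windows. For chromatin states, promoter windows are
intersected with a BED segmentation (state labels "1"–"9" in the name
column), sub-sequences reported in promoter-strand orientation, and two
designs run: genome-wide (state segments vs all promoters) and
responsive-vs-control (the state's segments in the positive gene set vs the
same segments in the control set). FWER control is Bonferroni across the
(hexamer × state) family, significance below 0.05. The state indicators can
also replace the hexamers as the features of the association + permutation
machinery (9 × statuses multiplicity).

## Fisher tail and numerical choices

`fisher_one_sided` is the exact hypergeometric survival function
(`scipy.stats.hypergeom.sf`), verified against an integer-arithmetic tail
oracle for every 2×2 table with total ≤ 60 (agreement ≤ 10⁻¹²) and against
`scipy.stats.fisher_exact(alternative="greater")`. The permutation engine
precomputes log-tail lookup tables with vectorised log-gamma binomials
(valid whenever every dataset universe equals the promoter set, since the
presence margins are then permutation-invariant); observed and permuted χ²
both go through these tables so the inclusive comparison is exact at ties,
and datasets with restricted universes fall back to direct re-scoring.
p = 0 inputs to Fisher's method are clamped to the smallest positive float
with a warning (they cannot arise from exact Fisher p-values, only from
user-supplied lists). Benjamini–Yekutieli adjustment is delegated to
statsmodels (`fdr_by`) and cross-checked against the step-up formula.

## Synthetic data: what it emulates, and what it does not

The generator produces a single toy chromosome with alternating-strand
genes laid out as spacer / window / gene-body slots, so promoter extraction
from genome + GFF3 round-trips exactly; the [-1500; +1] window is a
1501-bp window whose 3'-most base is the TSS base (`window_len` is a
parameter, since the bracket notation is ambiguous about one transcribed
base). Defaults, chosen once as realistic for the target setting:
GC content 0.36 (Arabidopsis-like upstream regions), three datasets at 1, 2
and 6 h treatment (exercising the early ≤ 2 h / late > 2 h grouping, with
the boundary inclusive on the early side and configurable), 5% up- and 5%
down-regulated genes per dataset, and cross-dataset status persistence 0.6
implemented as a Markov copy of a latent responsive label — emulating the
empirical recurrence of responsive genes across experiments that makes a
"DE in ≥ 3 datasets" positive set meaningful. Motif planting replaces
window bases at a uniform offset (lengths stay fixed) with probability
p_fg in genes carrying the target status in at least one dataset, p_bg
otherwise; peaks of stated width are centred on a stated fraction of
planted instances; chromatin states tile each window in geometric-length
blocks with stated frequencies and optional per-state GC bias (an A/T-rich
state 4 reproduces the qualitative A/T-hexamer-in-distal-promoter
enrichment pattern).

What passing tests on this generator do **not** show: real promoters are
not i.i.d. nucleotides (no TATA/CpG structure, no repeats unless masked
input is supplied), microarray/RNA-seq noise is not modelled (DEG tables
are consumed, not produced), and the toy chromosome has none of the real
genome's length or composition heterogeneity. Recovery and calibration
results transfer to real data only insofar as the contingency/meta/
permutation machinery is input-agnostic.

## Problem sizes used in the checks

The shipped tests and the acceptance script run the recovery scenario at
2000 genes × 1501 bp × 3 datasets with M = 200 (about a second per
replicate end-to-end), peak/state analyses at 300–400 genes × 300–400 bp,
and the exhaustive Fisher-oracle sweep over all ~6.4 × 10⁵ tables with
total ≤ 60. These sizes are the package's chosen desk-scale defaults; every
stage accepts larger inputs unchanged.

## Known limitations

Only k = 6 words (the constant is parameterised internally but untested for
k ≠ 6); no IUPAC degenerate matching; no motif extension or alignment; no
FDR-style alternative to Bonferroni at the meta stage; no adaptive or
early-stopping permutation schemes; depletion (under-representation) is not
tested anywhere.
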
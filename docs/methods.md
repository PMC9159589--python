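# Methods

## Scope and data model

The pipeline consumes peak calls (BED6 / ENCODE narrowPeak, 0-based
half-open everywhere internally), raw per-peak read-count matrices with a
sample sheet (assay, genotype, replicate, library size), a 4-column TSS
table, a differential-expression table, a FASTA genome and JASPAR-style
PWMs. Counts must be raw integers; all normalization is computed inside the
package so RPKM has a single source of truth. Peak names are the join key
across matrices and classifications and must be unique per file.

## Differential signal

Counts are normalized to RPKM, `count × 10⁹ / (library_size ×
peak_length)`. For a contrast (KO group, WT group), the reported fold
change is `log2((mean_KO + c) / (mean_WT + c))` on mean RPKM with
pseudocount `c = 1` RPKM unit (avoids ±∞ at zero counts; configurable).
Three two-sided tests are available, all requiring ≥ 2 replicates per
group:

* **moderated_t (default).** Pooled t on log2(RPKM + c) with
  empirical-Bayes variance moderation: per-peak pooled variances s² are
  shrunk toward a prior s0² with weight d0, both estimated from the
  distribution of log s² across peaks by the method of moments (trigamma
  inversion), and the statistic uses d + d0 degrees of freedom. This is
  the standard treatment for replicate-level designs (n ≈ 2–4 per group),
  where per-peak variances are too noisy to use alone; it has no free
  parameter. In null simulations (negative-binomial counts, 4 vs 4,
  dispersion 0.1) its type-I error at p < 0.05 is 0.040–0.058.
* **logratio_t.** Welch's unequal-variance t on log2(RPKM + c). Slightly
  conservative at n = 4 (type-I ≈ 0.035–0.041) and substantially less
  powerful than the moderated test; kept as the assumption-light option.
* **nb_wald.** Delta-method Wald test on library-size-normalized group
  means with a per-peak method-of-moments NB dispersion (variance = mean +
  dispersion·mean²), referred to a t with n1+n2−2 df; type-I ≈ 0.048–0.058
  in the same simulations.

Zero-variance degeneracies never crash: identical groups give p = 1, and
under `logratio_t` a zero-variance peak with unequal means falls back to
the smallest positive variance observed in the contrast (conservative).

P-values are Benjamini–Hochberg adjusted per contrast. A peak's status is
**down** iff significant and log2FC < −fc_thresh, **up** iff significant
and log2FC > fc_thresh, else **unchanged** — failing *either* gate makes a
peak "unchanged", so the three statuses partition every peak set and
subcategory counts always sum to their parents. Significance is the
adjusted p in `fdr` mode (α = 0.05 default) or the raw p in `raw_p` mode
(α = 1e-5 default, mirroring pooled-sample caller conventions). The
pipeline default is `fdr` for every contrast, because the element taxonomy
is defined on adjusted p-values and a replicate-level test cannot reach
raw p < 1e-5 at n = 4 for realistic effects; `raw_p` is selectable per
assay in the CLI config.

## Interval algebra and gene association

Overlap is unstranded, same-chromosome, and requires ≥ `min_bp` shared
bases (default 1 bp) between half-open intervals. An element's reference
point is its summit when present, else the interval midpoint (integer
floor); this single point anchors both TSS distances and motif windows.
TSS distance is unstranded |point − TSS|. Elements within 3 kb of a TSS
are promoter-proximal; within 100 kb, distal, with the nearest gene
assigned (equidistant ties break to the lexicographically smallest gene id
for reproducibility); beyond 100 kb, orphan, with no gene. Only the
single-nearest-gene-within-100 kb rule is implemented — no basal-plus-
extension regulatory domains.

## Taxonomies

Element categories (per TF-bound element, KO-vs-WT statuses):

| category | requires |
| --- | --- |
| pioneered_activated | open & active in WT, H3K27Ac down, ATAC down |
| nonpioneered_activated | open & active in WT, H3K27Ac down, ATAC unchanged |
| pioneered_inhibited | H3K27Ac up, ATAC up |
| nonpioneered_inhibited_candidate | H3K27Ac up, ATAC unchanged (flagged) |
| quiescent | H3K27Ac unchanged, ATAC unchanged |
| unclassified_atac_discordant | anything else |

"Open and active in WT" is a ≥ 1 bp overlap against the WT ATAC and
H3K27Ac peak calls, not a signal threshold. Inhibited categories do not
require WT openness (such elements sit in closed, inactive chromatin).
Discordant combinations (e.g. H3K27Ac down with ATAC up, or an
activated-like response at an element not open/active in WT) are reported
as unclassified rather than forced, so summary sums stay exact. H3K4Me3
status is carried as an annotation and never gates a category. Orphan
elements are excluded from both scopes because the 100 kb association rule
cannot apply to them.

Dependency categories (per second-TF peak, in the primary TF's KO):
co-bound peaks with binding **down** are *activated*, subdivided by ATAC
status (down → activated_pioneered, unchanged → activated_nonpioneered,
up → activated_atac_up); binding **up** → *inhibited_pioneered /
inhibited_nonpioneered* by ATAC; unchanged → *independent*. If the primary
TF's own binding is down in the second factor's knockout, an activated
peak is relabelled *mutually_dependent* (the ATAC status field is
preserved). Without a reciprocal contrast the field reads `not_tested` and
mutual dependence is never assigned (a warning is emitted). Peaks not
overlapping any primary-TF peak are `not_cobound` and are excluded from
the dependency denominator in summaries.

Summaries report integer percentages rounded half away from zero, which
reproduces printed splits such as 3,083/5,443 → 57%; the parent
denominator is named in every row.

## Enrichment statistics

All 2×2 enrichment tests share one kernel: the upper hypergeometric tail
P(X ≥ a) with X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b) (scipy);
two-sided Fisher is available. The odds ratio is the sample (a·d)/(b·c),
+∞ when b·c = 0 with a·d > 0. The empty table returns p = 1 with a
warning. For category↔DEG association the table is gene-level: a gene is
"near" a category if ≥ 1 element of that category has it as nearest gene
(multiplicity ignored), and the default universe is the genes present in
the DEG table — genes never measured cannot be "unchanged", and this
choice makes the permutation null exact. Grid p-values are reported raw by
default (BH optional), and the default direction is one-sided enrichment.

Motif enrichment uses the same kernel on ZOOPS hit counts. A PWM is read
as a JASPAR count matrix, converted to probabilities with a pseudocount of
1 per cell; scores are log2 odds against a uniform background (overridable)
and a sequence is a hit if any offset on either strand reaches the
threshold, 80% of the maximum attainable score by default (motif-specific
published thresholds do not exist for this scanner; fraction-of-max is
transparent and configurable). Ambiguous bases contribute a log-odds of 0.
Windows are summit-centered, ±100 bp, clipped at chromosome ends. Known
motifs only — de novo discovery is a different algorithm class and out of
scope. The background sequence set is always explicit; the package imposes
no default foreground/background pairing.

## Synthetic data generator

The generator emulates the contrast design the analysis assumes: WT vs
TF-knockout (and a second knockout for the reciprocal contrast), 4
replicates per genotype per assay, negative-binomial counts with
variance = mean + dispersion·mean² (mean 300, dispersion 0.1 — typical of
replicate-level sequencing counts), per-sample log-normal(0, 0.1²)
library-size factors so RPKM normalization is actually exercised, and a
planted |log2FC| of 2 for every affected category × assay. Defaults plant
40 elements per category.

Geometry: one 50 kb territory per element (or per unlinked background
gene); the element sits 5 kb into its territory, its target gene's TSS
0.2–2.8 kb away (promoter elements) or 3.5–20 kb away (distal elements) —
inside the (3 kb, 100 kb] distal band while keeping the intended gene
provably nearest and the toy genome ~35 Mb at the default scale. Elements
never overlap by construction. Each element targets exactly one gene;
genes may host several elements.

The DEG table is internally consistent rather than assigned: a linked
gene's log2FC is Normal(planted effect, 0.25) with planted effect ±2
(sign by category: activated elements depress their gene in the KO),
p-values follow from the known z-score, and adjusted p-values go through
the same BH routine the pipeline uses, so DEG status thresholds are
meaningful. Linkage probability is 0.9 per eligible element. Sequences
are i.i.d. uniform with the PWM consensus written at the summit of
motif-flagged elements (plant fraction 0.5 for pioneered-activated, 0.05
background). WT peak files contain an element iff its planted WT state is
open/active for that assay. Everything is reproducible from the seed:
identical configs yield byte-identical bundles.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: fragment-level read placement and peak-calling
artifacts, correlated signal between assays at the same locus beyond the
planted effects, GC/mappability bias, realistic chromatin domain
structure, spike-ins, and genes regulated by multiple elements with
conflicting directions. Recovery rates on synthetic truth are an upper
bound on real-data performance.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale: 520
elements (40 per category) for recovery, 2,000 peaks for null
calibration, 1,000 permutations for the association null, 200 + 200
sequences for motif enrichment — sizes at which every check completes in
seconds while the binomial error on the measured rates stays well inside
the asserted bands. Deterministic tie-breaks (lexicographic gene ids,
mergesort row ordering) make all outputs byte-stable; the CLI `run`
command is a pure function of (inputs, config).

## Known limitations

* No dispersion trend or shrinkage toward a mean–dispersion curve in
  `nb_wald`; the moderated t operates on log-RPKM instead.
* No spike-in normalization; library size is taken from the sample sheet.
* The H3K27Me3 differential status is computable but no spreading
  statistic over gene bodies is implemented.
* GO/ontology enrichment is out of scope (external annotation databases);
  the generic `set_overlap_test` covers gene-set Venn logic.
* Fisher p-values in the association grid are raw by default; with many
  categories × gene sets, enable the BH option.
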
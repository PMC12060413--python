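# Methods

## Problem and model

A locus that expresses several transcript isoforms can respond to
transformation in opposite directions at once: an RTE-derived isoform
(an exonised Alu terminal exon, an ERV-initiated antisense RNA, …) is
induced while the canonical isoform is repressed, or vice versa. `rteshift`
classifies this situation from transcript-level quantifications alone. All
statements below are about what the package computes; every number quoted is
produced by the test suite or `scripts/acceptance.py` at run time.

### Coordinates

All internal coordinates are 0-based half-open on explicit strands.
RepeatMasker `.out` and GTF are 1-based inclusive and are converted at the
I/O boundary only. The complement strand marker `C` in `.out` files maps to
`-`.

### Repeat elements

RepeatMasker annotates ERV proviruses as separate LTR and internal (`-int`)
fragments. `merge_elements` reassembles element-level features using two
rules, both transitive: (a) fragments sharing the `.out` fragment-linking ID
merge with no distance limit; (b) same-strand fragments within `max_gap` bp
merge when they share a family name or form an LTR/internal pair. `max_gap`
defaults to 100 bp — small enough not to chain unrelated neighbouring
elements, large enough to bridge typical assembly gaps between fragments of
one insertion; it is configurable because no canonical value exists.
Internal fragments are recognised by the `-int` suffix or by an ERV class
with a non-LTR family name. A merged element containing both an internal and
an LTR member is flagged a provirus and named by the internal family with
`-int` stripped (LTR2B + HERVE-int + LTR2B → "HERVE").

Families map to coarse subgroups (Alu, MIR, L1, L2, ERV/LTR, SVA, other) by
name prefix with an LTR/ERV class fallback; unknown families are labelled
`other`, never rejected. The mapping is data, not code, and can be replaced.

### Loci and RTE usage

Loci default to strand-agnostic single-linkage clustering of transcript
spans (≥ 1 bp overlap), because an RTE-initiated antisense transcript must
share a locus with the sense gene it disrupts; `by_gene_id` grouping is
available for annotated assemblies. Locus identifiers are the cluster span
(`chrom:start-end`), making them deterministic and comparable across runs on
one annotation.

A transcript's relationship to an overlapping merged element is: `exonised`
if any exon overlaps the element by ≥ `min_overlap` (default 10 bp — below
that, an overlap is more plausibly annotation jitter than a true exonised
segment); `initiated_in_rte` / `terminated_in_rte` if the TSS/TES falls
inside the element; `antisense_initiated` if RTE-initiated on the strand
opposite the host locus.

### Differential expression and discordance

For groups A (tumour) and B (normal), per transcript:
`fc = (mean_A + pc)/(mean_B + pc)` on linear TPM with pseudocount
`pc = 0.01` TPM; two-sided Welch t on `log2(TPM + pc)`;
Benjamini–Hochberg q across all tested transcripts. Direction `up` iff
`fc ≥ 1.5 ∧ p ≤ 0.05 ∧ q ≤ 0.05`, `down` symmetrically with `1/fc`.
Zero-variance rows: equal means give p = 1, unequal means give p = 0 and are
flagged `degenerate` rather than silently called. A locus is discordant iff
its DE members include both directions; discordant transcript counts include
both directions and are also reported per direction. Cross-cancer sharing of
a type's discordant loci is measured against the union of the other types'
discordant loci.

### Enrichment

Per subgroup, the 2×2 table (discordant vs not) × (subgroup vs not) over the
whole-transcriptome universe is tested with a two-sided Fisher exact test
(minimum-likelihood criterion with relative tie tolerance 1e−7, the
MATLAB/R convention), Holm-corrected across subgroups. Fold-enrichment is
the subgroup frequency among discordant transcripts over its frequency in
the universe. Units are transcripts: a transcript counts once per subgroup
no matter how many elements of that subgroup it touches. (Instance-level
counting was considered and rejected as the default because a single
transcript crossing an Alu-dense intron would otherwise dominate a cell.)

### Statistics

Mann–Whitney U, Kruskal–Wallis (+ Dunn), Student/Welch t and simple linear
regression are implemented in the package with mid-rank tie handling
throughout. `mann_whitney(mode="auto")` enumerates all C(n_x+n_y, n_x)
assignments exactly when that count is ≤ 20 000 and the data are tie-free,
otherwise it uses the tie-corrected normal approximation with continuity
correction. Dunn's pairwise z uses the pooled-variance form with the tie
term Σ(t³−t)/(12(N−1)); the default adjustment is Holm (Bonferroni and none
are available — some standard software uses a plain Bonferroni family here,
so the choice is explicit and recorded in the output). These are authored
rather than delegated so the test suite can hold them to enumeration oracles
and null calibration; scipy supplies only the reference distributions, and
scipy/statsmodels/lifelines appear in tests as independent cross-checks.

### Survival

Kaplan–Meier uses the product-limit estimator with events processed before
censorings at tied times. The two-group log-rank statistic is
(O−E)²/V with hypergeometric variance per distinct event time. Cox
regression maximises the partial likelihood by Newton iteration with
step-halving (convergence when max |score| < 1e−8, cap 50 iterations),
Efron tie handling by default (Breslow available; with Breslow ties and
tie-free data the score test at β = 0 equals the log-rank statistic, which
the tests assert to 1e−6). Constant covariates are flagged
non-identifiable; non-convergence or |log HR| > 15 (monotone likelihood /
perfect separation) is flagged with infinite CIs rather than reported
silently.

## Synthetic data

The generator emulates the statistical structure of a tumour/normal
transcript-quantification study; its defaults are the standard conditions
used throughout the tests: 2000 loci, 30 tumour + 30 normal samples,
discordant fraction `p_disc = 0.3`, true fold-changes `fc_up = 4` /
`fc_down = 0.25`, log2 noise σ = 0.25, Alu enrichment fold φ = 2.5, true
hazard ratio 2.0 with 20% censoring.

Each locus carries a canonical two-exon isoform and one RTE isoform —
an exonised-terminal-exon isoform, or (for a configurable 30% of loci) an
antisense transcript initiated inside the element. One repeat element per
locus is emitted; ERV/LTR elements are written as LTR/internal/LTR fragment
triples sharing an ID so the merge step is exercised for real. In
discordant loci the RTE isoform's tumour mean is multiplied by `fc_up` and
the canonical's by `fc_down`; a further 20% of loci are concordantly
upregulated so the DE universe is not purely discordant; the rest are null.
Expression is log-normal: TPM = 2^(μ + ε), ε ~ N(0, σ²), with canonical
baselines uniform on log2 TPM ∈ [3, 7] and RTE baselines on [2, 5]. Values
are written at fixed precision so identical seeds give byte-identical files.

Subgroup placement is solved analytically: with background frequencies
q_n (Alu 0.10, MIR 0.10, L1 0.15, L2 0.10, ERV/LTR 0.45, SVA 0.10), the
frequency inside discordant loci that yields an expected measured fold φ is

    q_d = φ (1 − p_disc) q_n / (1 − φ p_disc),

with the remaining subgroups scaled to fill the residual mass. For
φ = 2.5, p_disc = 0.3 this gives q_d(Alu) = 0.7, so the expected
transcript-level fold equals the configured 2.5 exactly; the configuration
is rejected as infeasible when φ·p_disc ≥ 1.

Each tumour sample has a latent RTE activity z ~ N(0,1); its stratum is
`high` iff z > 0, and RTE isoforms of discordant loci gain
`rte_coupling · z` (default 2) on the log2 scale, so the per-sample RTE
score recovers the stratum from expression. In `antisense_suppression` mode
the canonical isoform loses `antisense_coupling · z` as well, producing the
anti-correlated sense/antisense pattern. Survival times are exponential with
hazard `h0 · HR^{1[high]}` (h0 = 0.1 per time unit) under independent
exponential censoring calibrated so baseline subjects are censored with the
configured probability. Time units are arbitrary; only ratios matter.

What the generator does **not** emulate: compositional coupling between
transcripts (TPM columns are not renormalised to 10⁶, so transcripts are
independent given their means), read-level noise and mapping ambiguity,
transcript-length effects, tumour purity, batch effects, and realistic
genome architecture (loci are evenly spaced and non-overlapping except for
their own isoforms). Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated generative model,
not robustness to those real-data complications.

## Problem sizes and tolerances

The standard recovery dataset is 2000 loci × 60 samples; the survival
recovery simulation uses n = 500 subjects with near-complete follow-up and
200 replicate fits for CI coverage; null calibrations use 2000 replicates
per test, judged against the two-sided 99% binomial band around α = 0.05.
Exactness sweeps cover every 2×2 table with N ≤ 40 and every Mann–Whitney
configuration with both groups ≤ 7. Recovery tolerances: discordant-locus
fraction ±0.05 of the configured 0.3; Alu fold ±0.4 of 2.5 with Holm p ≤
0.05; Cox HR point estimate in [1.6, 2.5] with ≥ 90% CI coverage of the true
2.0.

## Known limitations

- Exact Mann–Whitney with ties uses mid-rank enumeration; no exact
  conditional-on-ties distribution beyond that.
- The Welch-on-log-TPM test is a generic two-group test; count-based DE
  models (negative binomial) are out of scope because the pipeline operates
  on TPM.
- Cox: no time-varying covariates, competing risks, or proportionality
  diagnostics.
- Numeric parity with any one vendor implementation (Prism, MATLAB, R) is
  not promised — only agreement with the definitions above and
  with the enumeration oracles.
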
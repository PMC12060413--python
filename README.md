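# rteshift

Detection of **discordant transcript isoforms** — loci that simultaneously
produce significantly up- and downregulated transcripts in a tumour-vs-normal
comparison — and quantification of **retrotransposable element (RTE)**
involvement in the resulting isoform-balance shifts.

Cancer transcriptomes frequently co-opt RTEs (Alu, MIR, L1/L2, ERV/LTR, SVA)
as alternative promoters, exons and polyadenylation sites. When an
RTE-derived isoform is induced while the canonical protein-coding isoform of
the same locus is repressed, the two differential-expression calls point in
opposite directions at one locus. `rteshift` implements that locus-level
classification and the statistics around it, for analysts working with
transcript-level quantifications (TPM), transcript models (GTF) and repeat
annotations (RepeatMasker `.out`).

## What it computes

Given a transcripts × samples TPM matrix, per-transcript differential
expression between two sample groups uses a Welch t-test on
log2(TPM + pc) with linear fold-change
`fc = (mean_A + pc) / (mean_B + pc)` and Benjamini–Hochberg q-values; a
transcript is called **up** when `fc ≥ 1.5`, `p ≤ 0.05` and `q ≤ 0.05`
(**down** symmetrically with 1/fc). A locus ℓ with up-set *U*ℓ and down-set
*D*ℓ is **discordant** iff *U*ℓ ≠ ∅ and *D*ℓ ≠ ∅; the discordant transcripts
are all DE members of discordant loci and the discordant fraction is
their share of all DE transcripts.

Around that core:

- **Repeat layer** — RepeatMasker `.out` parsing; merging of fragmented
  LTR/internal annotations into provirus-level elements (shared fragment ID,
  or same-strand adjacency within 100 bp between an internal `-int` fragment
  and its flanking LTR); family → subgroup mapping (Alu, MIR, L1, L2,
  ERV/LTR, SVA, other).
- **Transcript layer** — GTF reading, strand-agnostic overlap clustering
  into loci, and per-transcript RTE-usage calls (exonised, RTE-initiated,
  RTE-terminated, antisense-initiated).
- **Enrichment** — Fisher's exact test per subgroup on
  (discordant ∧ subgroup) 2×2 tables against the entire transcriptome, with
  Bonferroni–Holm correction and fold-enrichment
  `(a/(a+b)) / ((a+c)/N)`.
- **Isoform balance** — canonical fraction, alternative/canonical ratios,
  low/high stratification rules.
- **Statistics** — self-contained Mann–Whitney U (exact or tie-corrected
  normal approximation), Kruskal–Wallis with Dunn's post hoc,
  Student/Welch t, linear regression; all validated against enumeration
  oracles and calibrated under nulls.
- **Survival** — Kaplan–Meier, log-rank, and Cox proportional hazards via
  Newton iteration on the partial likelihood (Efron/Breslow ties), with Wald
  CIs and an exposed score test.
- **Synthetic data** — a generator that emits GTF + RepeatMasker + TPM +
  metadata files with a ground-truth ledger (which loci are discordant, the
  true enrichment fold per subgroup, per-sample survival strata and the true
  hazard ratio), used to exercise the pipeline end-to-end.

## Worked example

Run the full pipeline on a 500-locus synthetic cohort (30 tumour + 30 normal
samples, 30% of loci truly discordant, true Alu enrichment fold 2.5):

```python
from rteshift.pipeline import run

config = {
    "synthetic": {"n_loci": 500},
    "comparisons": [{"name": "tumour_vs_normal",
                     "group_a": {"condition": "tumour"},
                     "group_b": {"condition": "normal"}}],
    "stratification": {"rule": "median"},
}
results = run(config, "out/", seed=42)
```

This prints (from `results["tumour_vs_normal"]` and `results["survival"]`):

```
n_de: 440
n_disc: 300
discordant_fraction: 0.682
n discordant loci: 150 of 500
Alu fold: 2.61  p_holm: 1.13e-34
logrank p: 0.480
cox HR: 0.97  CI: [0.37, 2.50]
```

Reading: 440 transcripts pass the DE thresholds; 300 of them (68.2%) come
from the 150 loci (exactly the configured 30%) that produce both up- and
downregulated isoforms; Alu elements are 2.61-fold enriched among discordant
transcripts relative to the whole transcriptome (Holm-adjusted p ≪ 0.05,
true fold 2.5). The survival fit on only 30 tumour samples is uninformative
(wide CI straddling 1) — hazard-ratio recovery needs the larger survival
simulation (see below). The same run is available from a shell:

```sh
rteshift run --config config.yaml --outdir out/ --seed 42
rteshift simulate --outdir sim/ --seed 1     # data + truth ledger only
rteshift report --outdir out/
```

The output bundle contains the DE table, the per-locus discordance report,
the enrichment table, strata, Kaplan–Meier/log-rank/Cox tables, and a
manifest (seed, config hash, versions) sufficient to re-run identically.

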
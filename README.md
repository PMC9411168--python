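# kinoflow

Upstream kinase activity inference from peptide-microarray (kinome chip)
data, plus phosphosite-based pathway ranking.

## The problem

Kinome arrays expose a lysate to a grid of phosphorylatable peptide spots
(typically 144 peptides in a 12×12 grid) and image the phosphorylation
signal at increasing camera exposures (10, 20, 50, 100, 200 ms). The
biological question is which *upstream kinases* are differentially active
between two conditions — e.g. a knockout cell line versus its scrambled
control. `kinoflow` implements that inference chain as a tested, scriptable
pipeline:

1. **Signal reduction** — per (sample, peptide) series, fit an OLS slope of
   signal vs exposure; the per-peptide value is `log2(100 · slope)`.
   Peptides with poor fits (r² < 0.90 in any sample) or non-positive slopes
   are excluded.
2. **Kinase mapping** — candidate peptide→kinase assignments (homology
   scores and per-peptide ranks, PhosphoNET-style) are filtered: retain a
   candidate iff it is in-vitro confirmed (rank 0) or its score is
   strictly above 300 with rank in the top 12.
3. **Mean Kinase Statistic** — for each kinase with retained peptides
   *i* = 1..*n*,

   τ = (1/n) Σᵢ ( P̄ᵢ₁ − P̄ᵢ₂ ) / √( s²ᵢ₁ + s²ᵢ₂ )

   where P̄ᵢⱼ and s²ᵢⱼ are the mean and unbiased variance of peptide *i*'s
   value in group *j*. τ > 0 means higher activity in group 1 (the
   condition of interest).
4. **Permutation scores** — a *significance* score permutes sample labels
   (exact enumeration when the design allows, e.g. all C(8,4)=70
   assignments at 4 vs 4) and a *specificity* score redraws random peptide
   sets of the same size from the QC-passing pool; both are −log10 of a
   two-sided permutation p-value on |τ|. The Mean Final Score (MFS) is
   their sum (specificity alone for singlicate designs). A kinase is
   called **activated** when τ > 0 and MFS > 0.5.
5. **Network expansion** — activated kinases seed sub-networks on a
   user-supplied interaction graph, grown by connectivity preference and
   halted on intersection, at n < 50 nodes, or exhaustion; the network is
   named by its most interconnected node.
6. **Pathway ranking** — differential phosphosites (two-sample test on
   log reporter intensities) are tallied per pathway by their annotated
   catalyzing kinases; pathways are sorted by supporting-site count.

A synthetic-data module generates array experiments, candidate tables,
interaction graphs and phosphosite tables with known ground truth, so the
whole chain is testable without any proprietary vendor software or
downloads.

## Worked example

```bash
kinoflow all --seed 11 --out demo_run
# activated 25 kinases; network 'K007'; report -> demo_run/report.json
```

The run simulates the default design (144 peptides, 4 vs 4 samples, 50
candidate kinases of which K001–K005 carry a planted activity shift of
1.5 pooled SD), then processes, maps, scores, expands and ranks. From
`demo_run/report.json`:

* 5760 signal records reduce to 144 QC-passing peptide values per sample;
* 473 candidate rows filter down to 175 retained peptide→kinase pairs;
* 25 of 50 kinases are called activated — the five planted kinases
  (`K003, K001, K005, K004, K002`) lead the list by MFS;
* the seed network stops at 49 members (`size_limit`, the bound n < 50 is
  exclusive) and is named after its most interconnected node;
* pathway `PW01` (one of the two planted pathways) ranks first with 40
  supporting phosphosites.

A scored kinase row from `demo_run/scores.tsv` — here the planted K001:
5 retained peptides, τ = 1.24, significance p = 0.0286 (the minimum
attainable with exact 4v4 enumeration, score 1.54), specificity
p = 0.002 (score 2.70), MFS = 4.24, activated:

```text
kinase_id  n_peptides  mks    significance_p  significance_score  specificity_p  specificity_score  mfs   activated
K001       5           1.243  0.02857         1.544               0.001998       2.699              4.243 True
```

Note the deliberately permissive published decision rule: MFS > 0.5 means
the *product* of the two permutation p-values is below 10^−0.5 ≈ 0.32, so
a fair number of unplanted kinases also cross it. The activated list is a
sensitive screen, ordered by MFS; see `docs/methods.md` for the
calibration analysis.

Every stage is also available separately (`kinoflow simulate | process |
map | score | network | pathways`), reading and writing plain TSV / SIF /
GMT / JSON, and as library functions (`kinoflow.process_signals`,
`kinoflow.score_kinases`, ...).

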
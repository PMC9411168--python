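# Methods

This note records the statistical model behind `kinoflow`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Signal model and reduction

A kinome-array spot is imaged at exposures t = 10, 20, 50, 100, 200 ms.
The reduction fits, per (sample, peptide) series, an ordinary
least-squares regression of signal on exposure and reports the slope and
the coefficient of determination r². The per-peptide, per-sample value is

    value = log2(100 · slope).

**Intercept.** The regression includes an intercept by default. The
vendor pipeline that this procedure emulates is opaque on this point; an
intercept absorbs camera background and costs one degree of freedom out
of five points. A `through_origin` variant is available by flag.

**One slope per series.** Arrays are read after repeated pumping cycles;
whether the vendor fits a slope per cycle or only on the final read is
not documented. `kinoflow` fits one slope per (sample, peptide) over the
supplied exposures.

**QC.** "Acceptable curve fit and signal" is quantified as r² ≥ 0.90 and
slope strictly > 0 in *every* sample (both configurable). The rule is
per-peptide — a peptide is analyzed in all samples or none — because the
kinase statistic needs a mean and variance per group per peptide; an
unbalanced peptide would distort group comparisons. Non-positive slopes
become missing values (log of a non-positive rate is undefined); any
missing value fails the peptide. Replicate spots of one peptide are
averaged before fitting, with a log notice.

## Kinase mapping

Candidate peptide→kinase rows carry a homology/prediction score, a
per-peptide rank, and an in-vitro flag. Retention: peptide passes QC AND
(in-vitro, OR score > 300 with 1 ≤ rank ≤ 12). Both comparisons are
strict/inclusive exactly as stated: score 300 is out, rank 12 is in.
In-vitro rows carry rank 0 and bypass the score filter. "Top 12" is read
per peptide (the candidate table is built by querying scores per
phosphorylatable residue); the rank column is taken as given, never
recomputed. The upstream >90%-homology sequence matching that produces
the candidate table queries a proprietary database and is out of scope —
the table is an input.

## Mean Kinase Statistic and permutation scores

For a kinase with retained peptides i = 1..n,

    τ = (1/n) Σᵢ (P̄ᵢ₁ − P̄ᵢ₂) / sqrt(s²ᵢ₁ + s²ᵢ₂),

with group means P̄ and unbiased (n−1) variances s². Group 1 is the
condition of interest, so τ > 0 means higher activity there; the
orientation is echoed in all outputs. Peptides with zero pooled variance
are dropped from the sum with a logged warning (the term is undefined
there); n counts peptides actually used.

**Significance** permutes group labels across all samples and recomputes
τ. When the number of distinct assignments C(n₁+n₂, n₁) is at most
`n_perm`, exact enumeration replaces sampling and
p = #{|τ_perm| ≥ |τ_obs|} / #assignments (the observed assignment is
included, so p > 0). Otherwise `n_perm` sampled assignments are used with
the add-one rule p = (1 + #{≥}) / (n_perm + 1), so p = 0 is impossible.

**Specificity** redraws, `n_perm` times, n peptides uniformly without
replacement from the QC-passing pool and recomputes τ with the true
labels; p uses the add-one rule. A kinase whose peptide set is the whole
pool gets p = 1 by construction. The permutation redraws per-kinase sets
rather than permuting the whole peptide→kinase mapping jointly; the two
readings coincide marginally per kinase, and per-kinase draws keep
results independent of which other kinases are scored.

Both p-values are two-sided on |τ| — the direction requirement enters
separately through τ > 0. Scores are −log10(p), chosen so the published
decision threshold "MFS > 0.5" is expressible on the same scale; the
Mean Final Score is significance + specificity, or specificity alone for
singlicate designs (any group of size 1, auto-detected, where label
permutation is impossible). A kinase is **activated** iff τ > 0 and
MFS > 0.5 (both strict). No multiple-testing correction enters this call;
a BH-adjusted significance q-value is emitted for information only.

**Calibration of the activated call.** The MFS > 0.5 rule is a sensitive
screen, not a conservative test: it requires p_sig · p_spec < 10^−0.5 ≈
0.316, and the two p-values are strongly positively correlated (both are
driven by |τ_obs|; measured r ≈ 0.95 on null simulations). The package's
null simulations (144 peptides, 50 kinases, 4 vs 4, n_perm = 1000)
measure a per-kinase null call rate of ≈ 0.29, below the ≈ 0.335 implied
by independent uniform p-values on the attainable grids. Consequently,
in the planted-recovery benchmark (5 of 50 kinases at 1.5 pooled SD) the
call attains recall ≈ 1.0 but precision ≈ 0.22: the threshold admits
many unplanted kinases, some of which genuinely share shifted peptides
with planted ones. Users wanting a selective list should rank by MFS (the
planted kinases dominate the top of the ranking) or raise `--mfs-min`.

**Numerical conventions.** Variances from sums of squares are clipped at
zero before division; permuted-|τ| comparisons use an absolute tolerance
of 1e−9 so the label-swapped twin of the observed assignment (an exact
tie in real arithmetic) is never lost to floating-point rounding. The
per-kinase RNG stream derives from the master seed and a CRC32 of the
kinase id, so per-kinase results do not depend on scoring order. With a
4v4 design and n_perm ≥ 70, significance p-values live on the discrete
grid {k/35: k = 1..35} (each assignment ties exactly with its
complement); calibration checks therefore compare against the grid's own
CDF rather than a continuous uniform.

## Seed-network expansion

Activated kinases seed per-kinase sub-networks on an undirected
interaction graph. Admission prefers "objects with more connectivity":
the non-member with most edges to current members, ties broken by edges
to seeds (a `seeds`-primary ordering is available by flag — the source
procedure's phrasing is ambiguous between the two), then the
lexicographically smallest id. Sub-networks merge when they come to share
a member; expansion halts when all have merged into one (`intersected`),
when admitting a node would bring membership up to `max_nodes`
(`size_limit`; the bound is exclusive, n < 50 by default), or when no
candidate touches a member (`exhausted`). The network is named by its
highest-degree member in the induced subgraph, ties preferring seeds.
Candidates are not restricted to kinases: literature interaction networks
contain adapters and substrates, and the expansion rule is agnostic to
node type. Interaction-type edge labels (positive / negative /
context-dependent) are carried through for reporting and never affect
expansion.

## Differential phosphosites and pathway ranking

Phosphosite log reporter intensities are compared per site with a
two-sample t-test — Welch by default (real reporter data rarely have
equal variances), Student optional — and BH-adjusted q-values are
reported. The calling criterion is configurable (q < α or raw p < α)
because the emulated study does not state its rule; no fold-change gate
is imposed. Degenerate sites (zero variance in both groups) get p = 1
when the means agree and p = 0 otherwise. Pathways are ranked by the
number of distinct differential sites having at least one annotated
catalyzing kinase in the pathway: counting is set-valued, a site supports
each of its kinases' pathways once, and unannotated sites support
nothing. Ties share a dense rank and are listed lexicographically.

## Synthetic-data generator

The generator emulates the *structure* of the study design — a 12×12
peptide grid (144 peptides), exposures {10, 20, 50, 100, 200} ms, two
groups of four samples, a candidate table with scores straddling the
300/rank-12 retention boundary and ~15% in-vitro rows, a connected
interaction graph, and a phosphosite table with kinase and pathway
annotations. No distributional description of real spot signals is
published for this array class, so the generative model is a documented
stand-in:

    signal(t) = intercept + slope · t + Normal(0, noise_sd · t),

i.e. noise proportional to exposure, which makes the noise homoscedastic
on the slope scale and keeps long exposures from being artificially
over-weighted. Defaults: baseline slopes uniform on 0.05–0.5 signal
units/ms, noise_sd = 0.005 (relative slope error ≤ ~10% at the smallest
slopes, so QC passes essentially everywhere at r² ≥ 0.9), intercept 0,
no saturation (an optional ceiling is deliberately absent — saturation
handling is undocumented in the emulated pipeline).

Planted kinase activity multiplies group-1 slopes of all *retained*
peptides of planted kinases by 2^(effect_size · sd_value), where
sd_value = sd(slope-hat)/(slope · ln 2) is the delta-method SD of the
reduced value under the noise model — so the per-peptide value shifts by
`effect_size` pooled SD in expectation, and the effect acts jointly on a
kinase's substrate set, matching the premise that kinase activity drives
its substrates together. Every planted kinase is guaranteed at least one
retained candidate (asserted at generation time). Each generator
operation draws from its own RNG stream keyed off the master seed, so
adding one generator never perturbs another.

The phosphosite generator plants a fixed positive shift (default 3
within-group SD) on sites catalyzed by kinases of planted pathways;
~80% of sites carry 1–2 kinase annotations, kinases belong to 1–2
pathways.

**What passing tests do and do not show.** The generator's linear,
Gaussian, saturation-free signals and its independent peptides are an
idealization: real arrays have spot-level artifacts, saturation at long
exposures, correlated peptides (shared motifs), and heavier-tailed
noise. Tests against the generator validate the *procedure* — filters,
statistics, permutation machinery, bookkeeping — at a known truth; they
do not certify performance on real lysates.

## Problem sizes used in the automated checks

Calibration and recovery studies run at the study design (144 peptides,
50 kinases, 4 vs 4, n_perm = 1000) with 200 replicate datasets for null
calibration, 50 for planted recovery, and 2000 replicates of 200 sites
for the differential-site null rate; the acceptance script uses 20
replicates per condition. These sizes put Monte-Carlo error well below
each check's decision band.

## Known limitations

* The numeric behaviour of the proprietary vendor scorer is not
  reproduced — only the documented procedure; scores will differ from
  vendor output on the same data.
* Singlicate designs (one replicate in a group) make per-group variances
  unobservable in that group; such variance terms are set to 0, and a
  fully 1v1 design leaves τ undefined (all peptides dropped).
* The pathway stage depends entirely on the supplied kinase→site and
  pathway→kinase annotations; no live database queries are made.
* The activated call inherits the permissiveness of the published
  MFS > 0.5 threshold (see calibration above).
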
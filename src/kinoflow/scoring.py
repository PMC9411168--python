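"""Per-kinase activity statistics.

For each kinase with retained peptides i = 1..n the Mean Kinase Statistic
(MKS, written tau or T) standardizes and averages the per-peptide group
differences of the reduced values:

    tau = (1/n) * sum_i (P_bar_i1 - P_bar_i2) / sqrt(s2_i1 + s2_i2)

where P_bar_ij and s2_ij are the sample mean and (unbiased) variance of
peptide i in group j.  Group 1 is the condition of interest, so tau > 0
means higher activity there.

Two permutation scores accompany tau:

* significance — how much tau depends on the experimental grouping:
  group labels are shuffled across all samples and tau recomputed; when
  the number of distinct label assignments is small enough, exact
  enumeration replaces sampling.
* specificity — how much tau depends on the peptide->kinase mapping:
  random peptide sets of the same size are drawn from the QC-passing pool
  with the true labels kept.

Both p-values are two-sided on |tau| and transformed to scores as
-log10(p), so the published decision rule "MKS positive and MFS > 0.5"
is expressible; the Mean Final Score (MFS) is the specificity score alone
for singlicate designs, otherwise significance + specificity.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "peptide_group_stats",
    "mean_kinase_statistic",
    "significance_score",
    "specificity_score",
    "mean_final_score",
    "score_kinases",
    "call_activated",
]

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_MKS_MIN = 0.0  # exclusive
DEFAULT_MFS_MIN = 0.5  # exclusive

#: absolute tolerance when counting permuted |tau| >= observed |tau|, so the
#: label-swapped twin of the observed assignment (an exact tie in real
#: arithmetic) is never lost to the last floating-point ulp
_TIE_TOL = 1e-9


def _as_group_mask(values: pd.DataFrame, groups: Mapping[str, int]) -> np.ndarray:
    labels = np.array([int(groups[s]) for s in values.columns])
    bad = set(labels) - {1, 2}
    if bad:
        raise ValueError(f"group labels must be 1 or 2, got {sorted(bad)}")
    if (labels == 1).sum() == 0 or (labels == 2).sum() == 0:
        raise ValueError("each group needs >= 1 sample")
    return labels == 1


def peptide_group_stats(values: pd.DataFrame, groups: Mapping[str, int]) -> pd.DataFrame:
    """Per-peptide group means and unbiased variances.

    ``values`` is peptides x samples; ``groups`` maps sample -> {1, 2}.
    A group of size 1 gets variance 0 (its spread is unobservable); a
    group of size 0 is an error.
    """
    mask1 = _as_group_mask(values, groups)
    v = values.to_numpy(dtype=float)
    m1, v1 = _mean_var(v, mask1)
    m2, v2 = _mean_var(v, ~mask1)
    return pd.DataFrame(
        {
            "mean_g1": m1,
            "mean_g2": m2,
            "var_g1": v1,
            "var_g2": v2,
            "n_g1": int(mask1.sum()),
            "n_g2": int((~mask1).sum()),
        },
        index=values.index,
    )


def _mean_var(v: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = int(mask.sum())
    sub = v[:, mask]
    m = sub.mean(axis=1)
    if n < 2:
        return m, np.zeros_like(m)
    return m, sub.var(axis=1, ddof=1)


def mean_kinase_statistic(stats: pd.DataFrame, peptides: Sequence[str]) -> tuple[float, int]:
    """Eq-style MKS for one kinase: mean of standardized group differences
    over its retained peptides.

    Peptides whose pooled variance s2_g1 + s2_g2 is zero are dropped (the
    standardized difference is undefined there); ``n`` counts the peptides
    actually used.  Returns (nan, 0) with a logged reason when every
    peptide is dropped.
    """
    if len(peptides) == 0:
        raise ValueError("kinase has no retained peptides")
    sub = stats.loc[list(peptides)]
    denom = (sub["var_g1"] + sub["var_g2"]).to_numpy(dtype=float)
    diff = (sub["mean_g1"] - sub["mean_g2"]).to_numpy(dtype=float)
    usable = denom > 0
    n_used = int(usable.sum())
    if n_used < len(peptides):
        log.warning(
            "dropped %d zero-variance peptide(s) from an MKS of %d",
            len(peptides) - n_used,
            len(peptides),
        )
    if n_used == 0:
        return float("nan"), 0
    return float(np.mean(diff[usable] / np.sqrt(denom[usable]))), n_used


# ---------------------------------------------------------------------------
# permutation machinery


def _tau_for_masks(v: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """tau of the peptide set ``v`` (peptides x samples) under each group-1
    membership mask (rows of ``masks``).  Zero-pooled-variance peptides are
    dropped per assignment; all-dropped assignments yield NaN."""
    n1 = int(masks[0].sum())
    n2 = masks.shape[1] - n1
    fmask = masks.T.astype(float)  # samples x A
    s1 = v @ fmask
    q1 = (v**2) @ fmask
    m1 = s1 / n1
    m2 = (v.sum(axis=1, keepdims=True) - s1) / n2
    var1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1) if n1 > 1 else np.zeros_like(m1)
    q_tot = (v**2).sum(axis=1, keepdims=True)
    var2 = np.maximum((q_tot - q1) - n2 * m2**2, 0.0) / (n2 - 1) if n2 > 1 else np.zeros_like(m2)
    denom = var1 + var2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (m1 - m2) / np.sqrt(denom)
    terms[denom <= 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(terms, axis=0)


def _exact_masks(n: int, n1: int) -> np.ndarray:
    """All distinct assignments of n1 of n samples to group 1."""
    out = np.zeros((comb(n, n1), n), dtype=bool)
    for i, idx in enumerate(combinations(range(n), n1)):
        out[i, list(idx)] = True
    return out


def _kinase_rng(seed: int, kinase_id: str, stream: int) -> np.random.Generator:
    """Per-kinase stream derived from the master seed and a stable hash of
    the kinase id, so results do not depend on scoring order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(kinase_id).encode()), stream])
    )


def significance_score(
    values: pd.DataFrame,
    groups: Mapping[str, int],
    peptides: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    kinase_id: str = "",
) -> tuple[float, float]:
    """Permutation-of-samples p-value and -log10 score for one kinase.

    Group labels are shuffled across all samples (group sizes preserved)
    and tau recomputed.  When the number of distinct label assignments is
    <= ``n_perm``, exact enumeration over all of them replaces sampling
    and p = #{|tau_perm| >= |tau_obs|} / #assignments (the observed
    assignment is one of them, so p > 0).  Otherwise ``n_perm`` random
    assignments are drawn and p = (1 + #{>=}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    mask_obs = _as_group_mask(values, groups)
    n, n1 = mask_obs.size, int(mask_obs.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("degenerate grouping: all samples in one group")
    v = values.loc[list(peptides)].to_numpy(dtype=float)
    tau_obs = _tau_for_masks(v, mask_obs[None, :])[0]
    if np.isnan(tau_obs):
        return 1.0, 0.0

    n_exact = comb(n, n1)
    if n_exact <= n_perm:
        masks = _exact_masks(n, n1)
        tau_perm = _tau_for_masks(v, masks)
        count = int(np.sum(np.abs(tau_perm) >= np.abs(tau_obs) - _TIE_TOL))
        p = count / n_exact
    else:
        rng = _kinase_rng(seed, kinase_id, stream=1)
        masks = rng.permuted(np.tile(mask_obs, (n_perm, 1)), axis=1)
        tau_perm = _tau_for_masks(v, masks)
        count = int(np.nansum(np.abs(tau_perm) >= np.abs(tau_obs) - _TIE_TOL))
        p = (1 + count) / (n_perm + 1)
    return float(p), float(-np.log10(p))


def specificity_score(
    values: pd.DataFrame,
    groups: Mapping[str, int],
    peptides: Sequence[str],
    peptide_pool: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    kinase_id: str = "",
) -> tuple[float, float]:
    """Permutation-of-peptides p-value and -log10 score for one kinase.

    Each permutation draws |peptides| peptides uniformly without
    replacement from the QC-passing pool and recomputes tau with the true
    group labels.  p uses the add-one rule, so a kinase whose peptide set
    is the whole pool gets p = 1.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    pool = list(peptide_pool)
    n = len(peptides)
    if n > len(pool):
        raise ValueError(f"kinase has {n} peptides but the pool holds only {len(pool)}")
    mask_obs = _as_group_mask(values, groups)

    # standardized per-peptide differences under the true labels, reused
    # for every draw
    v_pool = values.loc[pool].to_numpy(dtype=float)
    d_pool = _standardized_diffs(v_pool, mask_obs)
    d_obs = d_pool[[pool.index(p) for p in peptides]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tau_obs = np.nanmean(d_obs)
    if np.isnan(tau_obs):
        return 1.0, 0.0

    rng = _kinase_rng(seed, kinase_id, stream=2)
    # uniform draws without replacement via random-key order statistics
    draws = np.argpartition(rng.random((n_perm, len(pool))), n - 1, axis=1)[:, :n]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tau_perm = np.nanmean(d_pool[draws], axis=1)
    count = int(np.nansum(np.abs(tau_perm) >= np.abs(tau_obs) - _TIE_TOL))
    p = (1 + count) / (n_perm + 1)
    return float(p), float(-np.log10(p))


def _standardized_diffs(v: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    m1, var1 = _mean_var(v, mask1)
    m2, var2 = _mean_var(v, ~mask1)
    denom = var1 + var2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m1 - m2) / np.sqrt(denom)
    d[denom <= 0] = np.nan
    return d


def mean_final_score(significance: float, specificity: float, singlicate: bool) -> float:
    """MFS: specificity alone for singlicate designs (sample-label
    permutation is impossible there), otherwise significance + specificity."""
    if significance < 0 or specificity < 0:
        raise ValueError("scores must be >= 0")
    return float(specificity) if singlicate else float(significance + specificity)


def score_kinases(
    matrix_values: pd.DataFrame,
    groups: Mapping[str, int],
    kinase_map: Mapping[str, Sequence[str]],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    singlicate: bool | None = None,
    mks_min: float = DEFAULT_MKS_MIN,
    mfs_min: float = DEFAULT_MFS_MIN,
) -> pd.DataFrame:
    """Full per-kinase score table.

    ``matrix_values`` is the QC-passing peptide x sample value matrix (the
    peptide pool for specificity is its row set).  ``singlicate`` is
    auto-detected (any group of size 1) unless forced.  Returns one row
    per kinase: n_peptides, mks, significance_p/score, specificity_p/score,
    mfs, activated, plus a BH-adjusted significance q-value reported for
    information only (no correction enters the activated call).
    """
    mask1 = _as_group_mask(matrix_values, groups)
    if singlicate is None:
        singlicate = min(int(mask1.sum()), int((~mask1).sum())) < 2
    stats = peptide_group_stats(matrix_values, groups)
    pool = list(matrix_values.index)

    rows = []
    for kid in sorted(kinase_map):
        peptides = [p for p in kinase_map[kid] if p in stats.index]
        if not peptides:
            log.warning("kinase %s has no QC-passing peptides; skipped", kid)
            continue
        mks, n_used = mean_kinase_statistic(stats, peptides)
        if n_used == 0:
            log.warning("kinase %s: all peptides had zero pooled variance; scored as missing", kid)
            rows.append((kid, 0, np.nan, np.nan, 0.0, np.nan, 0.0, np.nan, False))
            continue
        if singlicate:
            sig_p, sig_s = np.nan, 0.0
        else:
            sig_p, sig_s = significance_score(
                matrix_values, groups, peptides, n_perm=n_perm, seed=seed, kinase_id=kid
            )
        spe_p, spe_s = specificity_score(
            matrix_values, groups, peptides, pool, n_perm=n_perm, seed=seed, kinase_id=kid
        )
        mfs = mean_final_score(0.0 if singlicate else sig_s, spe_s, singlicate)
        activated = (mks > mks_min) and (mfs > mfs_min)
        rows.append((kid, n_used, mks, sig_p, sig_s, spe_p, spe_s, mfs, activated))

    scores = pd.DataFrame(
        rows,
        columns=[
            "kinase_id",
            "n_peptides",
            "mks",
            "significance_p",
            "significance_score",
            "specificity_p",
            "specificity_score",
            "mfs",
            "activated",
        ],
    ).set_index("kinase_id")
    ok = scores["significance_p"].notna()
    scores["significance_q"] = np.nan
    if ok.any():
        scores.loc[ok, "significance_q"] = multipletests(
            scores.loc[ok, "significance_p"], method="fdr_bh"
        )[1]
    return scores


def call_activated(
    scores: pd.DataFrame,
    mks_min: float = DEFAULT_MKS_MIN,
    mfs_min: float = DEFAULT_MFS_MIN,
) -> pd.DataFrame:
    """Kinases with MKS strictly above ``mks_min`` and MFS strictly above
    ``mfs_min``, sorted by MFS descending, ties by MKS descending, then
    kinase id."""
    hits = scores[(scores["mks"] > mks_min) & (scores["mfs"] > mfs_min)].copy()
    return hits.sort_values(
        by=["mfs", "mks", "kinase_id"], ascending=[False, False, True], kind="stable"
    )
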
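"""Differential phosphosites and pathway ranking.

Phosphosite log-intensities (corrected reporter-ion scale) are compared
between two groups site by site; significantly increased sites are those
whose group-1 mean exceeds group-2.  Pathways are then ranked by the
number of distinct differential sites known to be catalyzed by at least
one of their member kinases — a site catalyzed by a kinase in two
pathways supports both; a site with no annotated catalyzing kinase
supports none (it still counts in totals).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["differential_phosphosites", "rank_pathways"]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def differential_phosphosites(
    table: pd.DataFrame,
    groups: Mapping[str, int],
    test: str = "welch",
    alpha: float = DEFAULT_ALPHA,
    correction: str = "fdr_bh",
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Two-sample comparison of every site's log-intensities.

    ``table`` is sites x samples; ``groups`` maps sample -> {1, 2}.
    ``test`` is "welch" (unequal variances, default) or "student";
    ``correction`` is "fdr_bh" (call on q < alpha) or "none" (call on raw
    p < alpha; the emulated study does not state its criterion, so both
    are exposed).  Returns (increased site set, decreased site set,
    per-site statistics with raw p and BH q).

    A site with zero variance in both groups and equal means gets p = 1 by
    convention; zero variance with unequal means gets p = 0 (an infinite
    t statistic).
    """
    if test not in ("welch", "student"):
        raise ValueError(f"test must be 'welch' or 'student', got {test!r}")
    if correction not in ("fdr_bh", "none"):
        raise ValueError(f"correction must be 'fdr_bh' or 'none', got {correction!r}")
    labels = np.array([int(groups[s]) for s in table.columns])
    n1, n2 = int((labels == 1).sum()), int((labels == 2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples for a variance-based test, got {n1} vs {n2}")
    v = table.to_numpy(dtype=float)
    v1, v2 = v[:, labels == 1], v[:, labels == 2]
    m1, m2 = v1.mean(axis=1), v2.mean(axis=1)
    s1, s2 = v1.var(axis=1, ddof=1), v2.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = sps.ttest_ind(v1, v2, axis=1, equal_var=(test == "student"))
    degenerate = (s1 == 0) & (s2 == 0)
    with np.errstate(invalid="ignore"):
        p = np.where(degenerate & (m1 == m2), 1.0, p)
        p = np.where(degenerate & (m1 != m2), 0.0, p)
        t_stat = np.where(degenerate, np.sign(m1 - m2) * np.inf, t_stat)
        t_stat = np.where(degenerate & (m1 == m2), 0.0, t_stat)
    q = multipletests(p, method="fdr_bh")[1]

    called = (q < alpha) if correction == "fdr_bh" else (p < alpha)
    per_site = pd.DataFrame(
        {
            "mean_g1": m1,
            "mean_g2": m2,
            "t": t_stat,
            "p": p,
            "q": q,
            "significant": called,
            "direction": np.where(m1 > m2, "increased", np.where(m1 < m2, "decreased", "flat")),
        },
        index=table.index,
    )
    increased = set(per_site.index[called & (m1 > m2)])
    decreased = set(per_site.index[called & (m1 < m2)])
    return increased, decreased, per_site


def rank_pathways(
    differential_sites: Iterable[str],
    site_kinases: pd.DataFrame | Mapping[str, Iterable[str]],
    pathway_sets: Mapping[str, Iterable[str]],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Sort pathways by the number of differential sites catalyzed by
    their member kinases.

    ``site_kinases`` is either a table with columns (site_id, kinase_id)
    or a mapping site -> kinases; ``pathway_sets`` maps pathway -> member
    kinases (GMT-style).  Counting is set-valued: duplicated annotation
    rows change nothing, and a site supports each pathway at most once.
    Pathways are ordered count-descending with lexicographic ties and get
    dense ranks (equal counts share a rank).
    """
    diff = set(differential_sites)
    if isinstance(site_kinases, pd.DataFrame):
        pairs = site_kinases[["site_id", "kinase_id"]].drop_duplicates()
        by_site: dict[str, set[str]] = {
            s: set(g["kinase_id"]) for s, g in pairs.groupby("site_id")
        }
    else:
        by_site = {s: set(ks) for s, ks in site_kinases.items()}
    if not diff:
        log.info("no differential sites; pathway ranking is empty")
        return pd.DataFrame(columns=["pathway", "n_kinases", "supporting_sites", "rank"])

    rows = []
    for pw in sorted(pathway_sets):
        members = set(pathway_sets[pw])
        count = sum(1 for s in diff if by_site.get(s, set()) & members)
        rows.append((pw, len(members), count))
    ranking = pd.DataFrame(rows, columns=["pathway", "n_kinases", "supporting_sites"])
    ranking = ranking.sort_values(
        ["supporting_sites", "pathway"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ranking["rank"] = (
        ranking["supporting_sites"].rank(method="dense", ascending=False).astype(int)
    )
    if top_k is not None:
        ranking = ranking.head(top_k)
    return ranking
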
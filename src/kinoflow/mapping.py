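"""Peptide->kinase map construction.

Candidate kinase-substrate assignments come from a homology-based
prediction table (one row per kinase x peptide with a prediction score and
a per-peptide rank; in-vitro-confirmed substrates carry rank 0).  The
retention rule keeps a candidate iff its peptide passed QC and it is
either in-vitro confirmed or its score is strictly above ``score_min``
with rank in 1..``max_rank``.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

__all__ = ["build_map", "validate_candidates"]

log = logging.getLogger(__name__)

DEFAULT_SCORE_MIN = 300.0
DEFAULT_MAX_RANK = 12

_REQUIRED = ("kinase_id", "peptide_id", "score", "rank", "in_vitro")


def validate_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of a candidate table."""
    missing = set(_REQUIRED) - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    if (candidates["rank"] < 0).any():
        raise ValueError("candidate rank must be >= 0")
    iv = candidates["in_vitro"].astype(bool)
    if not (iv == (candidates["rank"] == 0)).all():
        raise ValueError("in_vitro flag must hold exactly when rank == 0")
    return candidates


def build_map(
    candidates: pd.DataFrame,
    qc_passing_peptides: Iterable[str],
    score_min: float = DEFAULT_SCORE_MIN,
    max_rank: int = DEFAULT_MAX_RANK,
    known_peptides: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Retained peptide->kinase map.

    A candidate is retained iff its peptide passes QC AND
    (in_vitro OR (score > score_min AND 1 <= rank <= max_rank)).
    Both threshold comparisons follow the strict reading: score exactly at
    ``score_min`` is excluded, rank ``max_rank`` is the last one in.

    Candidates referencing peptides outside ``known_peptides`` (when given,
    e.g. the array layout) are skipped with a logged count.  Retention of a
    row never depends on other rows.  Returns a table with provenance
    columns (score, rank, in_vitro), sorted by (kinase_id, peptide_id),
    with kinases that keep zero peptides absent.
    """
    validate_candidates(candidates)
    qc_set = set(qc_passing_peptides)
    if not qc_set:
        raise ValueError("qc_passing_peptides is empty; nothing can be mapped")
    cands = candidates
    if known_peptides is not None:
        known = set(known_peptides)
        unknown = ~cands["peptide_id"].isin(known)
        if unknown.any():
            log.warning(
                "skipping %d candidate rows referencing unknown peptides (e.g. %s)",
                int(unknown.sum()),
                cands.loc[unknown, "peptide_id"].iloc[0],
            )
            cands = cands[~unknown]

    score_ok = (cands["score"] > score_min) & cands["rank"].between(1, max_rank)
    keep = cands["peptide_id"].isin(qc_set) & (cands["in_vitro"].astype(bool) | score_ok)
    retained = (
        cands[keep]
        .drop_duplicates(["kinase_id", "peptide_id"])
        .sort_values(["kinase_id", "peptide_id"], kind="stable")
        .reset_index(drop=True)
    )
    if retained.empty:
        raise ValueError(
            "no candidates retained; review score_min/max_rank thresholds or QC settings"
        )
    return retained[list(_REQUIRED)]


def map_as_dict(retained: pd.DataFrame) -> dict[str, list[str]]:
    """Retained map as kinase -> sorted peptide list."""
    return {
        kid: sorted(grp["peptide_id"].tolist())
        for kid, grp in retained.groupby("kinase_id")
    }
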
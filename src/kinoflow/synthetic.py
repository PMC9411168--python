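"""Synthetic kinome-array experiments with known ground truth.

Emulates the design of a porous 3D peptide microarray ("kinome chip"):
144 peptide spots in a 12x12 grid, fluorescence read at increasing camera
exposures (10, 20, 50, 100, 200 ms), two comparison groups of lysate
samples, a candidate peptide->kinase table in the style of homology-based
kinase-substrate prediction databases, a literature-style protein
interaction network, and a phosphosite reporter-intensity table with
kinase and pathway annotations.

The generative signal model is a linear-in-exposure ramp,

    signal(t) = intercept + slope * t + Normal(0, noise_sd * t),

i.e. additive noise whose standard deviation is proportional to exposure,
so the noise on the *slope* scale is homoscedastic.  No published
distributional description of spot signals exists for this array class;
this model is a documented stand-in (see docs/methods.md).

Planted kinase activity acts multiplicatively on the slopes of all
*retained* peptides of the planted kinases in group 1 (the condition of
interest), calibrated so that the reduced per-peptide value
log2(100*slope) shifts by ``effect_size`` pooled standard deviations in
expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_kinase_map",
    "generate_array_experiment",
    "generate_interaction_network",
    "generate_phosphosite_table",
    "retention_filter",
]

# Fixed stream keys: each generator op draws from its own RNG stream derived
# from the master seed, so adding/reordering generators never perturbs others.
_STREAM_KINASE_MAP = 1
_STREAM_ARRAY = 2
_STREAM_NETWORK = 3
_STREAM_PHOSPHO = 4

#: default retention thresholds of the candidate filter (see mapping module)
DEFAULT_SCORE_MIN = 300.0
DEFAULT_MAX_RANK = 12


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(key)]))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated array experiment.

    Defaults mirror the emulated study: a 12x12 spot grid (144 peptides),
    exposures of 10/20/50/100/200 ms, and a 4 vs 4 group comparison.
    """

    n_peptides: int = 144
    exposure_times: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)
    group_sizes: tuple[int, int] = (4, 4)
    n_kinases: int = 50
    peptides_per_kinase: tuple[int, int] = (6, 12)
    planted_kinases: frozenset[str] = frozenset()
    effect_size: float = 0.0  # in units of per-peptide pooled SD of the value
    noise_sd: float = 0.005  # additive noise SD on the slope scale
    baseline_slope_range: tuple[float, float] = (0.05, 0.5)  # signal units / ms
    intercept: float = 0.0
    in_vitro_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError(f"n_peptides must be >= 1, got {self.n_peptides}")
        t = np.asarray(self.exposure_times, dtype=float)
        if t.size < 2 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError(
                "exposure_times must be >=2 strictly positive, strictly "
                f"increasing values, got {self.exposure_times}"
            )
        if len(self.group_sizes) != 2 or min(self.group_sizes) < 1:
            raise ValueError(f"group_sizes must be a pair of counts >= 1, got {self.group_sizes}")
        if self.n_kinases < 1:
            raise ValueError(f"n_kinases must be >= 1, got {self.n_kinases}")
        lo, hi = self.peptides_per_kinase
        if not (1 <= lo <= hi):
            raise ValueError(f"peptides_per_kinase must satisfy 1 <= lo <= hi, got {self.peptides_per_kinase}")
        if hi > self.n_peptides:
            raise ValueError(
                f"peptides_per_kinase upper bound {hi} exceeds peptide pool size {self.n_peptides}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 < self.baseline_slope_range[0] <= self.baseline_slope_range[1]):
            raise ValueError(f"baseline_slope_range must be positive and ordered, got {self.baseline_slope_range}")
        unknown = set(self.planted_kinases) - set(self.kinase_ids)
        if unknown:
            raise ValueError(f"planted_kinases not in the kinase pool: {sorted(unknown)}")

    # identifier pools ----------------------------------------------------
    @property
    def peptide_ids(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_peptides)]

    @property
    def kinase_ids(self) -> list[str]:
        return [f"K{i + 1:03d}" for i in range(self.n_kinases)]

    @property
    def sample_ids(self) -> list[str]:
        n1, n2 = self.group_sizes
        return [f"G1S{i + 1}" for i in range(n1)] + [f"G2S{i + 1}" for i in range(n2)]

    @property
    def groups(self) -> dict[str, int]:
        """sample_id -> group label (1 = condition of interest, 2 = control)."""
        n1, _ = self.group_sizes
        return {s: (1 if i < n1 else 2) for i, s in enumerate(self.sample_ids)}


@dataclass
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    kinase_shift: dict[str, float]  # per-kinase value-scale shift multiplier exponent
    peptide_baseline_slope: dict[str, float]
    assignments: dict[str, list[str]]  # kinase -> retained (true) peptides
    shifted_peptides: list[str]
    peptide_value_sd: dict[str, float]  # analytic SD of the reduced value

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def retention_filter(
    candidates: pd.DataFrame,
    score_min: float = DEFAULT_SCORE_MIN,
    max_rank: int = DEFAULT_MAX_RANK,
) -> pd.Series:
    """Boolean mask of candidate rows that survive the retention rule
    (in-vitro confirmed, or score strictly above ``score_min`` with rank in
    1..``max_rank``)."""
    score_ok = (candidates["score"] > score_min) & candidates["rank"].between(1, max_rank)
    return candidates["in_vitro"].astype(bool) | score_ok


def generate_kinase_map(config: SimConfig) -> pd.DataFrame:
    """Candidate peptide->kinase table with homology scores, ranks and
    in-vitro flags.

    Scores straddle the retention threshold (some above and some below 300)
    and ranks span 1..20, so the downstream filter has real work to do.
    In-vitro rows carry rank 0.  Every planted kinase is guaranteed at
    least one retained candidate.
    """
    rng = _rng(config.seed, _STREAM_KINASE_MAP)
    peptides = config.peptide_ids
    lo, hi = config.peptides_per_kinase
    rows = []
    for kid in config.kinase_ids:
        n_pep = int(rng.integers(lo, hi + 1))
        pep_idx = rng.choice(config.n_peptides, size=n_pep, replace=False)
        for j in np.sort(pep_idx):
            in_vitro = bool(rng.random() < config.in_vitro_rate)
            if in_vitro:
                rank = 0
                score = float(np.round(rng.uniform(0, 500), 1))
            else:
                rank = int(rng.integers(1, 21))
                score = float(np.round(rng.uniform(100, 500), 1))
            rows.append((kid, peptides[j], score, rank, in_vitro))
    cands = pd.DataFrame(rows, columns=["kinase_id", "peptide_id", "score", "rank", "in_vitro"])

    # guarantee planted kinases have >=1 retained candidate
    retained = retention_filter(cands)
    for kid in sorted(config.planted_kinases):
        k_rows = cands.index[cands["kinase_id"] == kid]
        if not retained[k_rows].any():
            i = k_rows[0]
            cands.loc[i, ["score", "rank", "in_vitro"]] = (
                float(np.round(rng.uniform(301, 500), 1)),
                int(rng.integers(1, DEFAULT_MAX_RANK + 1)),
                False,
            )
    retained = retention_filter(cands)
    for kid in config.planted_kinases:
        assert retained[cands["kinase_id"] == kid].any(), f"planted kinase {kid} has no retained peptide"
    return cands


def _slope_sd_factor(exposure_times: Sequence[float]) -> float:
    """SD of the OLS (with-intercept) slope estimate per unit ``noise_sd``
    under Normal(0, noise_sd*t) signal noise."""
    t = np.asarray(exposure_times, dtype=float)
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    return float(np.sqrt(np.sum(tc**2 * t**2)) / sxx)


def generate_array_experiment(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one two-group array experiment.

    Returns a long-format signal table (sample_id, group, peptide_id,
    exposure_ms, signal) and the :class:`GroundTruth`.  The candidate map
    drawn by :func:`generate_kinase_map` under the same config determines
    which peptides carry the planted shift.
    """
    rng = _rng(config.seed, _STREAM_ARRAY)
    t = np.asarray(config.exposure_times, dtype=float)
    peptides = config.peptide_ids
    samples = config.sample_ids
    groups = config.groups
    n_s, n_p, n_t = len(samples), len(peptides), len(t)

    baseline = rng.uniform(*config.baseline_slope_range, size=n_p)

    # which peptides belong (via retained candidates) to planted kinases
    cands = generate_kinase_map(config)
    retained = cands[retention_filter(cands)]
    assignments = {
        kid: sorted(grp["peptide_id"].unique())
        for kid, grp in retained.groupby("kinase_id")
    }
    shifted = sorted(
        {p for kid in config.planted_kinases for p in assignments.get(kid, [])}
    )
    shifted_mask = np.isin(np.array(peptides), np.array(shifted)) if shifted else np.zeros(n_p, bool)

    # analytic SD of the reduced value log2(100*slope) by the delta method:
    # sd(value) = sd(slope_hat) / (slope * ln 2)
    slope_se = config.noise_sd * _slope_sd_factor(t)
    value_sd = slope_se / (baseline * np.log(2.0))

    # group-1 slopes of shifted peptides are multiplied by 2^(effect * sd)
    log2_shift = np.where(shifted_mask, config.effect_size * value_sd, 0.0)

    group_arr = np.array([groups[s] for s in samples])
    slope = np.tile(baseline, (n_s, 1))  # samples x peptides
    slope[group_arr == 1] = slope[group_arr == 1] * 2.0 ** log2_shift

    noise = rng.normal(0.0, 1.0, size=(n_s, n_p, n_t)) * (config.noise_sd * t)
    signal = config.intercept + slope[:, :, None] * t + noise

    frame = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, n_p * n_t),
            "group": np.repeat(group_arr, n_p * n_t),
            "peptide_id": np.tile(np.repeat(peptides, n_t), n_s),
            "exposure_ms": np.tile(t, n_s * n_p),
            "signal": signal.ravel(),
        }
    )
    truth = GroundTruth(
        kinase_shift={
            kid: (config.effect_size if kid in config.planted_kinases else 0.0)
            for kid in config.kinase_ids
        },
        peptide_baseline_slope=dict(zip(peptides, baseline.tolist())),
        assignments=assignments,
        shifted_peptides=shifted,
        peptide_value_sd=dict(zip(peptides, value_sd.tolist())),
    )
    return frame, truth


def generate_interaction_network(
    n_nodes: int,
    density: float,
    seed: int,
    kinase_ids: Iterable[str] = (),
) -> nx.Graph:
    """Connected, self-loop-free interaction graph containing all kinase
    identifiers plus filler nodes.

    A random spanning tree guarantees connectivity; extra edges are added
    uniformly at random until ``round(density * n(n-1)/2)`` edges exist.
    Edges carry an ``interaction`` label used for reporting only.
    """
    kinase_ids = list(kinase_ids)
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    if len(kinase_ids) > n_nodes:
        raise ValueError("more kinase_ids than n_nodes")
    m_target = int(round(density * n_nodes * (n_nodes - 1) / 2))
    if m_target < n_nodes - 1:
        raise ValueError(
            f"density {density} yields {m_target} edges, fewer than the "
            f"{n_nodes - 1} needed for a spanning tree"
        )
    rng = _rng(seed, _STREAM_NETWORK)
    nodes = kinase_ids + [f"N{i + 1:03d}" for i in range(n_nodes - len(kinase_ids))]
    order = rng.permutation(n_nodes)
    labels = np.array(["positive", "negative", "context-dependent", "unspecified"])
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(1, n_nodes):
        parent = order[int(rng.integers(0, i))]
        g.add_edge(nodes[order[i]], nodes[parent], interaction=str(rng.choice(labels)))
    while g.number_of_edges() < m_target:
        u, v = rng.integers(0, n_nodes, size=2)
        if u == v or g.has_edge(nodes[u], nodes[v]):
            continue
        g.add_edge(nodes[u], nodes[v], interaction=str(rng.choice(labels)))
    return g


@dataclass
class PhosphoTruth:
    differential_sites: list[str]
    planted_pathways: list[str]


def generate_phosphosite_table(
    n_sites: int,
    n_kinases: int,
    n_pathways: int,
    planted_pathways: Iterable[str] = (),
    seed: int = 0,
    group_sizes: tuple[int, int] = (4, 4),
    effect_sd: float = 3.0,
    frac_annotated: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], PhosphoTruth]:
    """Phosphosite log-intensity table with kinase and pathway annotations.

    Sites catalyzed by kinases of planted pathways receive a positive
    group-1 shift of ``effect_sd`` within-group standard deviations.
    Returns (intensity sites x samples, site->kinase annotation table,
    pathway->kinases gene sets, truth).
    """
    if min(n_sites, n_kinases, n_pathways) < 1:
        raise ValueError("n_sites, n_kinases and n_pathways must all be >= 1")
    pathways = [f"PW{i + 1:02d}" for i in range(n_pathways)]
    planted = sorted(set(planted_pathways))
    if not set(planted) <= set(pathways):
        raise ValueError(f"planted_pathways must be a subset of {pathways[0]}..{pathways[-1]}")
    rng = _rng(seed, _STREAM_PHOSPHO)
    kinases = [f"PK{i + 1:02d}" for i in range(n_kinases)]
    sites = [f"S{i + 1:04d}" for i in range(n_sites)]
    n1, n2 = group_sizes
    samples = [f"G1S{i + 1}" for i in range(n1)] + [f"G2S{i + 1}" for i in range(n2)]

    # kinase -> pathways (1-2 each); every pathway gets >=1 kinase
    gene_sets: dict[str, list[str]] = {p: [] for p in pathways}
    for i, k in enumerate(kinases):
        chosen = {pathways[i % n_pathways]}
        if rng.random() < 0.4:
            chosen.add(pathways[int(rng.integers(0, n_pathways))])
        for p in chosen:
            gene_sets[p].append(k)

    # site -> kinases (0-2 each)
    ann_rows = []
    site_kin: dict[str, list[str]] = {}
    for s in sites:
        if rng.random() < frac_annotated:
            ks = rng.choice(n_kinases, size=int(rng.integers(1, 3)), replace=False)
            site_kin[s] = [kinases[j] for j in np.sort(ks)]
            for k in site_kin[s]:
                ann_rows.append((s, k))
        else:
            site_kin[s] = []
    annotation = pd.DataFrame(ann_rows, columns=["site_id", "kinase_id"])

    planted_kin = {k for p in planted for k in gene_sets[p]}
    diff_sites = [s for s in sites if set(site_kin[s]) & planted_kin]

    base = rng.uniform(18.0, 24.0, size=n_sites)
    values = base[:, None] + rng.normal(0.0, 1.0, size=(n_sites, n1 + n2))
    if diff_sites:
        diff_mask = np.isin(np.array(sites), np.array(diff_sites))
        values[np.ix_(diff_mask, np.arange(n1))] += effect_sd * 1.0
    intensity = pd.DataFrame(values, index=pd.Index(sites, name="site_id"), columns=samples)
    truth = PhosphoTruth(differential_sites=diff_sites, planted_pathways=planted)
    return intensity, annotation, gene_sets, truth
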
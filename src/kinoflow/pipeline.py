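"""End-to-end driver: simulate -> process -> map -> score -> network -> pathways.

``RunConfig`` gathers every threshold and seed; :func:`run_pipeline`
executes the stages in dependency order, writes each stage's table next
to the output directory, and returns a machine-readable run report.
Identical config (including seed) reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as kio
from . import __version__
from .mapping import build_map, map_as_dict
from .network import expand_network
from .pathways import differential_phosphosites, rank_pathways
from .scoring import call_activated, score_kinases
from .signals import process_signals
from .synthetic import (
    SimConfig,
    generate_array_experiment,
    generate_interaction_network,
    generate_kinase_map,
    generate_phosphosite_table,
)

__all__ = ["RunConfig", "run_pipeline", "analyze_experiment"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    # simulation
    n_peptides: int = 144
    exposure_times: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)
    group_sizes: tuple[int, int] = (4, 4)
    n_kinases: int = 50
    peptides_per_kinase: tuple[int, int] = (6, 12)
    n_planted: int = 5
    effect_size: float = 1.5
    noise_sd: float = 0.005
    # signal processing
    model: str = "with_intercept"
    r2_min: float = 0.90
    min_slope: float = 0.0
    # mapping
    score_min: float = 300.0
    max_rank: int = 12
    # scoring
    n_perm: int = 1000
    mks_min: float = 0.0
    mfs_min: float = 0.5
    condition_label: str = "group1"
    control_label: str = "group2"
    # network
    network_nodes: int = 120
    network_density: float = 0.04
    max_nodes: int = 50
    tiebreak: str = "members"
    # phospho / pathways
    n_sites: int = 400
    n_phospho_kinases: int = 30
    n_pathways: int = 10
    n_planted_pathways: int = 2
    phospho_effect_sd: float = 3.0
    test: str = "welch"
    alpha: float = 0.05
    correction: str = "fdr_bh"
    top_k: int = 5

    def sim_config(self) -> SimConfig:
        planted = frozenset(f"K{i + 1:03d}" for i in range(self.n_planted))
        return SimConfig(
            n_peptides=self.n_peptides,
            exposure_times=tuple(self.exposure_times),
            group_sizes=tuple(self.group_sizes),
            n_kinases=self.n_kinases,
            peptides_per_kinase=tuple(self.peptides_per_kinase),
            planted_kinases=planted,
            effect_size=self.effect_size,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(names)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(kio.read_yaml(path) or {})

    def to_yaml(self, path) -> None:
        kio.write_yaml(self.to_dict(), path)


def analyze_experiment(
    signals: pd.DataFrame,
    candidates: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, "pd.DataFrame"]:
    """Process signals, build the kinase map, and score kinases.

    Returns (scores, activated, retained map).  This is the analysis core
    shared by the CLI, the pipeline driver, and the calibration studies.
    """
    matrix = process_signals(
        signals, model=config.model, r2_min=config.r2_min, min_slope=config.min_slope
    )
    values = matrix.passing_values()
    retained = build_map(
        candidates,
        qc_passing_peptides=values.index,
        score_min=config.score_min,
        max_rank=config.max_rank,
    )
    groups = matrix.groups.astype(int).to_dict()
    scores = score_kinases(
        values,
        groups,
        map_as_dict(retained),
        n_perm=config.n_perm,
        seed=config.seed,
        mks_min=config.mks_min,
        mfs_min=config.mfs_min,
    )
    activated = call_activated(scores, mks_min=config.mks_min, mfs_min=config.mfs_min)
    return scores, activated, retained


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write all artifacts under ``outdir``.

    Emits the stage tables, the resolved config, and ``report.json`` with
    versions, seeds, thresholds, per-stage record counts, the activated
    kinase list, the network name, and the top pathways.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()

    # simulate
    signals, truth = generate_array_experiment(sim)
    candidates = generate_kinase_map(sim)
    kio.write_signals(signals, out / "signals.tsv")
    kio.write_table(candidates, out / "candidates.tsv")
    truth.to_json(out / "ground_truth.json")

    # process
    matrix = process_signals(
        signals, model=config.model, r2_min=config.r2_min, min_slope=config.min_slope
    )
    values = matrix.passing_values()
    kio.write_table(matrix.value.reset_index(), out / "values.tsv")
    qc = pd.DataFrame(
        {
            "peptide_id": matrix.qc_pass.index,
            "qc_pass": matrix.qc_pass.to_numpy(),
            "min_r2": matrix.r2.min(axis=1).to_numpy(),
            "min_slope": matrix.slope.min(axis=1).to_numpy(),
        }
    )
    kio.write_table(qc, out / "qc_report.tsv")

    # map + score
    scores, activated, retained = analyze_experiment(signals, candidates, config)
    kio.write_table(retained, out / "kinase_map.tsv")
    kio.write_table(scores.reset_index(), out / "scores.tsv")
    kio.write_table(activated.reset_index(), out / "activated.tsv")

    # network
    graph = generate_interaction_network(
        config.network_nodes,
        config.network_density,
        seed=config.seed,
        kinase_ids=sim.kinase_ids,
    )
    kio.write_sif(graph, out / "interactions.sif")
    net = None
    if len(activated):
        net = expand_network(
            list(activated.index), graph, max_nodes=config.max_nodes, tiebreak=config.tiebreak
        )
        kio.write_sif(net.subgraph, out / "network.sif")
        kio.write_table(net.membership_table(), out / "network_members.tsv")

    # phospho + pathways
    pathways_all = [f"PW{i + 1:02d}" for i in range(config.n_pathways)]
    intensity, annotation, gene_sets, ph_truth = generate_phosphosite_table(
        n_sites=config.n_sites,
        n_kinases=config.n_phospho_kinases,
        n_pathways=config.n_pathways,
        planted_pathways=pathways_all[: config.n_planted_pathways],
        seed=config.seed,
        group_sizes=tuple(config.group_sizes),
        effect_sd=config.phospho_effect_sd,
    )
    kio.write_table(intensity.reset_index(), out / "phosphosites.tsv")
    kio.write_table(annotation, out / "site_kinases.tsv")
    kio.write_gmt(gene_sets, out / "pathways.gmt")
    ph_groups = {s: (1 if s.startswith("G1") else 2) for s in intensity.columns}
    increased, decreased, per_site = differential_phosphosites(
        intensity, ph_groups, test=config.test, alpha=config.alpha, correction=config.correction
    )
    kio.write_table(per_site.reset_index(), out / "site_stats.tsv")
    ranking = rank_pathways(increased, annotation, gene_sets, top_k=None)
    kio.write_table(ranking, out / "pathway_ranking.tsv")

    config.to_yaml(out / "config_resolved.yaml")
    report = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "r2_min": config.r2_min,
            "min_slope": config.min_slope,
            "score_min": config.score_min,
            "max_rank": config.max_rank,
            "mks_min": config.mks_min,
            "mfs_min": config.mfs_min,
            "alpha": config.alpha,
            "max_nodes": config.max_nodes,
        },
        "orientation": {"group1": config.condition_label, "group2": config.control_label},
        "counts": {
            "signal_records": int(len(signals)),
            "peptides": int(config.n_peptides),
            "qc_passing_peptides": int(matrix.qc_pass.sum()),
            "candidate_rows": int(len(candidates)),
            "retained_rows": int(len(retained)),
            "kinases_scored": int(len(scores)),
            "activated_kinases": int(len(activated)),
            "phosphosites": int(len(intensity)),
            "increased_sites": int(len(increased)),
            "decreased_sites": int(len(decreased)),
        },
        "activated": list(activated.index),
        "network": {
            "name": net.name if net else None,
            "n_members": len(net.members) if net else 0,
            "halt_reason": net.halt_reason if net else None,
        },
        "top_pathways": ranking.head(config.top_k).to_dict(orient="records"),
    }
    kio.write_json(report, out / "report.json")
    return report
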
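"""File I/O, study configuration, and the end-to-end pipeline.

The pipeline runs the full analysis chain in order — behavior statistics,
expression normalization and comparison, brain-behavior correlation,
network construction, centrality/hub analysis, bootstrap and shuffled-null
inference, and Louvain module detection with resolution selection — and
emits one JSON report plus per-stage CSV/GraphML artifacts.  The report is
a pure function of (input tables, configuration): all resampling seeds are
derived deterministically from the single configured seed, and the JSON is
serialized with sorted keys so identical inputs give byte-identical
output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import expression as ex
from . import inference as inf
from . import metrics as gm
from . import modules as md
from . import network as nw
from .tables import BehaviorTable, CountTable, TableValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "read_count_table",
    "read_behavior_table",
    "write_count_table",
    "write_behavior_table",
    "run_pipeline",
    "run_pipeline_from_tables",
]


@dataclass(frozen=True)
class StudyConfig:
    """All file paths, thresholds and flags for one pipeline run.

    Thresholds default to the analysis family's conventions: alpha=0.05
    two-sided edges, B=100 bootstrap replicates, N=100 null replicates,
     100 Louvain repetitions per resolution on a 0.5-1.5 grid.
    """

    counts_a: str
    counts_b: str
    behavior_a: str
    behavior_b: str
    condition_a: str = "LI"
    condition_b: str = "HI"
    alpha: float = 0.05
    B: int = 100
    null_N: int = 100
    resolution_grid: tuple[float, ...] = md.DEFAULT_RESOLUTION_GRID
    reps: int = 100
    seed: int = 42
    adjust: str | None = None            # 'bh' for BH-corrected edges
    transitivity_variant: str = "binary"  # or 'onnela'
    hub_top_k: int = 2
    normalize: bool = True
    use_wilcoxon_behavior: bool = False
    stability_criterion: str = "modal_count"  # or 'rand'

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load from YAML (JSON is valid YAML and accepted too)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if "resolution_grid" in raw:
            raw["resolution_grid"] = tuple(float(g)
                                           for g in raw["resolution_grid"])
        return cls(**raw)


def read_count_table(path, condition: str) -> CountTable:
    """CSV with a subject-id first column and region-name header."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise TableValidationError(f"{path}: empty count table")
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    return CountTable(condition=condition, data=df)


def write_count_table(table: CountTable, path) -> None:
    table.data.rename_axis("subject").to_csv(path)


def read_behavior_table(path, condition: str) -> BehaviorTable:
    """CSV with columns subject, t_old, t_recent (d2 is derived)."""
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"subject", "t_old", "t_recent"}
    if not needed.issubset(df.columns):
        raise TableValidationError(
            f"{path}: behavior CSV needs columns {sorted(needed)}")
    return BehaviorTable.from_times(
        condition, df["subject"].astype(str).tolist(),
        df["t_old"].to_numpy(float), df["t_recent"].to_numpy(float))


def write_behavior_table(table: BehaviorTable, path) -> None:
    out = table.data[["t_old", "t_recent"]].rename_axis("subject")
    out.to_csv(path)


def _derived_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([int(seed), stage]).generate_state(1)[0]
               % (2 ** 31))


def _behavior_stage(beh_a: BehaviorTable, beh_b: BehaviorTable,
                    config: StudyConfig) -> dict:
    summary_a = bh.condition_summary(beh_a, config.use_wilcoxon_behavior)
    summary_b = bh.condition_summary(beh_b, config.use_wilcoxon_behavior)
    between = bh.compare_conditions_d2(beh_a.d2, beh_b.d2)
    return {
        config.condition_a: summary_a,
        config.condition_b: summary_b,
        "between_conditions": between.to_dict(),
    }


def _expression_stage(counts_a: CountTable, counts_b: CountTable,
                      beh_a: BehaviorTable, beh_b: BehaviorTable,
                      config: StudyConfig) -> tuple[dict, dict]:
    if config.normalize:
        norm_a, norm_b = ex.normalize_counts(counts_a, counts_b)
    else:
        norm_a, norm_b = counts_a, counts_b
    comparisons = ex.region_group_comparison(norm_a, norm_b,
                                             adjust=config.adjust)
    corr = {
        config.condition_a:
            ex.brain_behavior_correlation(beh_a, counts_a),
        config.condition_b:
            ex.brain_behavior_correlation(beh_b, counts_b),
    }
    stage = {
        "normalized": config.normalize,
        "region_comparisons": [c.to_dict() for c in comparisons],
        "brain_behavior_correlation": {
            cond: {region: {k: (None if isinstance(v, float) and np.isnan(v)
                                else v)
                            for k, v in row.items()}
                   for region, row in df.to_dict(orient="index").items()}
            for cond, df in corr.items()
        },
    }
    return stage, {"norm_a": norm_a, "norm_b": norm_b}


def _network_stage(counts: CountTable, config: StudyConfig
                   ) -> tuple[dict, nw.CorrelationNetwork, list]:
    net = nw.build_network(counts, alpha=config.alpha, adjust=config.adjust)
    nodes = gm.node_centralities(net, hub_top_k=config.hub_top_k)
    glob = gm.global_metrics(net,
                             transitivity_variant=config.transitivity_variant)
    stage = {
        "condition": counts.condition,
        "n_edges_pos": net.n_edges_pos,
        "n_edges_neg": net.n_edges_neg,
        "edges": net.edges.to_dict(orient="records"),
        "node_metrics": [m.to_dict() for m in nodes],
        "hubs": sorted(gm.identify_hubs(nodes)),
        "global_metrics": glob.to_dict(),
    }
    return stage, net, nodes


def _inference_stage(counts_a: CountTable, counts_b: CountTable,
                     net_a: nw.CorrelationNetwork,
                     net_b: nw.CorrelationNetwork,
                     config: StudyConfig) -> dict:
    boot_a = inf.bootstrap_metrics(counts_a, B=config.B, alpha=config.alpha,
                                   seed=_derived_seed(config.seed, 1))
    boot_b = inf.bootstrap_metrics(counts_b, B=config.B, alpha=config.alpha,
                                   seed=_derived_seed(config.seed, 2))
    null_a = inf.shuffled_null(net_a.rho, net_a.p, alpha=config.alpha,
                               N=config.null_N,
                               seed=_derived_seed(config.seed, 3))
    null_b = inf.shuffled_null(net_b.rho, net_b.p, alpha=config.alpha,
                               N=config.null_N,
                               seed=_derived_seed(config.seed, 4))
    chance = {}
    for cond, nulls in ((config.condition_a, null_a),
                        (config.condition_b, null_b)):
        chance[cond] = {
            d.metric_name: inf.metric_vs_chance(d.observed, d,
                                                direction="greater").to_dict()
            for d in nulls
        }
    comparisons = {}
    for da, db in zip(boot_a, boot_b):
        res = inf.compare_conditions(da, db, label_a=config.condition_a,
                                     label_b=config.condition_b)
        comparisons[da.metric_name] = res.to_dict()
    return {
        "bootstrap": {
            config.condition_a: [d.to_dict() for d in boot_a],
            config.condition_b: [d.to_dict() for d in boot_b],
        },
        "shuffled_null": {
            config.condition_a: [d.to_dict() for d in null_a],
            config.condition_b: [d.to_dict() for d in null_b],
        },
        "vs_chance": chance,
        "between_conditions": comparisons,
        "interpretation_flags": {
            "bootstrap_unit": "subjects_with_replacement",
            "null_scheme": "offdiagonal_pair_permutation_diagonal_fixed",
        },
    }


def _modules_stage(net_a: nw.CorrelationNetwork, net_b: nw.CorrelationNetwork,
                   config: StudyConfig) -> tuple[dict, dict]:
    selected, report = md.select_resolution(
        net_a, net_b, grid=config.resolution_grid, reps=config.reps,
        seed=_derived_seed(config.seed, 5),
        criterion=config.stability_criterion)
    partitions = {}
    assignments = {}
    for cond, net, tag in ((config.condition_a, net_a, "a"),
                           (config.condition_b, net_b, "b")):
        part = md.louvain_partition(net, resolution=selected,
                                    seed=_derived_seed(config.seed, 6))
        row = report.loc[report["resolution"] == selected].iloc[0]
        part = md.Partition(
            condition=cond, assignment=part.assignment,
            n_communities=part.n_communities, resolution=part.resolution,
            modularity=part.modularity,
            stability=float(row[f"stability_{tag}"]))
        partitions[cond] = part.to_dict()
        partitions[cond]["modal_communities"] = int(
            row[f"modal_communities_{tag}"])
        assignments[cond] = part.assignment
    return {
        "selected_resolution": selected,
        "per_resolution": report.to_dict(orient="records"),
        "partitions": partitions,
    }, assignments


def run_pipeline_from_tables(counts_a: CountTable, counts_b: CountTable,
                             beh_a: BehaviorTable, beh_b: BehaviorTable,
                             config: StudyConfig,
                             out_dir=None) -> dict:
    """Run every analysis stage on in-memory tables; see ``run_pipeline``."""
    if counts_a.regions != counts_b.regions:
        raise TableValidationError(
            "region sets differ between condition count tables")
    report: dict = {"config": _config_dict(config)}
    report["behavior"] = _behavior_stage(beh_a, beh_b, config)
    report["expression"], _norm = _expression_stage(
        counts_a, counts_b, beh_a, beh_b, config)
    stage_a, net_a, _ = _network_stage(counts_a, config)
    stage_b, net_b, _ = _network_stage(counts_b, config)
    report["network"] = {config.condition_a: stage_a,
                         config.condition_b: stage_b}
    report["inference"] = _inference_stage(counts_a, counts_b, net_a, net_b,
                                           config)
    report["modules"], assignments = _modules_stage(net_a, net_b, config)
    if out_dir is not None:
        _write_artifacts(out_dir, report, config, counts_a, counts_b,
                         _norm, net_a, net_b, assignments)
    return report


def run_pipeline(config: StudyConfig, out_dir=None) -> dict:
    """Read the configured CSVs, run all stages, optionally write artifacts.

    Stage order: behavior -> expression -> network -> metrics ->
    inference -> modules.  Any failure aborts with a stage-named error.
    """
    stage = "input"
    try:
        counts_a = read_count_table(config.counts_a, config.condition_a)
        counts_b = read_count_table(config.counts_b, config.condition_b)
        beh_a = read_behavior_table(config.behavior_a, config.condition_a)
        beh_b = read_behavior_table(config.behavior_b, config.condition_b)
        stage = "pipeline"
        return run_pipeline_from_tables(counts_a, counts_b, beh_a, beh_b,
                                        config, out_dir=out_dir)
    except Exception as err:
        raise RuntimeError(f"pipeline failed during {stage} stage: {err}"
                           ) from err


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    d["resolution_grid"] = [float(g) for g in d["resolution_grid"]]
    return d


def _write_artifacts(out_dir, report, config, counts_a, counts_b, norm,
                     net_a, net_b, assignments) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, net in ((config.condition_a, net_a),
                      (config.condition_b, net_b)):
        net.rho.rename_axis("region").to_csv(out / f"rho_{cond}.csv")
        net.p.rename_axis("region").to_csv(out / f"p_{cond}.csv")
        net.edges.to_csv(out / f"edges_{cond}.csv", index=False)
        nw.write_graphml(net, out / f"network_{cond}.graphml",
                         communities=assignments.get(cond))
        node_rows = report["network"][cond]["node_metrics"]
        pd.DataFrame(node_rows).to_csv(out / f"node_metrics_{cond}.csv",
                                       index=False)
    for cond, table in ((config.condition_a, norm["norm_a"]),
                        (config.condition_b, norm["norm_b"])):
        write_count_table(table, out / f"counts_normalized_{cond}.csv")
    write_report(report, out / "report.json")


def write_report(report: dict, path) -> None:
    """Serialize the report deterministically (sorted keys, fixed floats)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
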
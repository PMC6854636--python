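"""End-to-end orchestration: simulate -> score -> estimate -> compare ->
pathways -> stability -> describe, with a manifest for reproducibility.

Each stage writes its outputs under the configured directory; the manifest
records the configuration hash, package version, seeds and per-stage
timing so a run can be audited and repeated bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import build_ground_truth, sample_item_panel, sample_score_panel
from .comparison import nct_independent, nct_paired
from .errors import ConfigError
from .groupstats import bh_fdr, chisq_yates_2x2, moderation_fit, wilcoxon_ranksum_cc, wilcoxon_signedrank_cc
from .io import (
    read_item_panel,
    read_score_panel,
    write_ground_truth,
    write_item_panel,
    write_network,
    write_result_json,
    write_score_panel,
)
from .measurement import score_item_panel
from .network import EstimatorConfig, expected_influence, select_network_ebic
from .panels import GROUPS, OCCASIONS, ScorePanel
from .paths import compare_pathways, shortest_pathways
from .stability import bootstrap_edges, casedrop_stability

log = logging.getLogger("rfnet")

ALL_STAGES = ("simulate", "score", "estimate", "compare", "pathways", "stability", "describe")


@dataclass
class RunConfig:
    out_dir: str = "rfnet_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 1
    # inputs: either a scenario to simulate or panels on disk
    scenario: dict | str = "adversity"
    n_per_group: dict[str, int] | None = None
    item_level: bool = False
    score_panel_path: str | None = None
    item_panel_path: str | None = None
    # estimation / inference settings
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_method: str = "pearson"
    permutations: int = 5000
    bootstrap_replicates: int = 2000
    binarize: dict[str, object] = field(
        default_factory=lambda: {"aggression": "any-endorsement", "expressive_suppression": "any-endorsement"}
    )
    gd_node: str = "GD"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.seed < 0 or self.permutations < 1 or self.bootstrap_replicates < 10:
            raise ConfigError("seed must be >= 0, permutations >= 1, bootstrap replicates >= 10")
        for path in (self.score_panel_path, self.item_panel_path):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def estimator(self) -> EstimatorConfig:
        return EstimatorConfig(
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            correlation_method=self.correlation_method,
        )

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _safe_name(group: str, occasion: str) -> str:
    return f"{'cap' if group == 'CA+' else 'cam'}_{occasion}"


def _frame(panel: ScorePanel, group: str, occasion: str) -> pd.DataFrame:
    return pd.DataFrame(panel.matrix(group=group, occasion=occasion), columns=panel.score_columns)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest (also written to disk).

    Deterministic for a fixed config: every stage draws its randomness from
    an independent stream spawned from the single run seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage_seed(name: str, k: int = 0) -> int:
        # stable small integers derived from the run seed, < 2**31
        h = hashlib.sha256(f"{config.seed}:{name}:{k}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "stages": {},
        "partial": False,
    }
    est = config.estimator()
    panel: ScorePanel | None = None
    networks: dict[tuple[str, str], object] = {}

    def record(stage: str, t0: float, **extra) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **extra}
        log.info("stage %s finished in %.2fs", stage, manifest["stages"][stage]["seconds"])

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            truth = build_ground_truth(config.scenario)
            write_ground_truth(truth, out / "ground_truth.json")
            sim_seed = stage_seed("simulate")
            if config.item_level:
                item_panel = sample_item_panel(truth, config.n_per_group, seed=sim_seed)
                write_item_panel(item_panel, out / "item_panel.csv")
            else:
                panel = sample_score_panel(truth, config.n_per_group, seed=sim_seed)
                write_score_panel(panel, out / "score_panel.csv")
            record("simulate", t0, seed=sim_seed)

        if "score" in config.stages:
            t0 = time.time()
            if config.item_panel_path is not None:
                item_panel = read_item_panel(config.item_panel_path)
            elif "simulate" in config.stages and config.item_level:
                pass  # item_panel from the simulate stage
            else:
                item_panel = None
            if item_panel is not None:
                panel, models = score_item_panel(item_panel, binarize=config.binarize)
                write_score_panel(panel, out / "score_panel.csv")
                record("score", t0, scales=len(models))
            else:
                record("score", t0, skipped="no item-level input")

        if panel is None:
            if config.score_panel_path is not None:
                panel = read_score_panel(config.score_panel_path)
            elif (out / "score_panel.csv").exists():
                panel = read_score_panel(out / "score_panel.csv")
        if panel is None and set(config.stages) - {"simulate", "score"}:
            raise ConfigError("no score panel available for the requested stages")

        if "estimate" in config.stages:
            t0 = time.time()
            for grp in GROUPS:
                for occ in OCCASIONS:
                    net = select_network_ebic(panel, config=est, group=grp, occasion=occ)
                    networks[(grp, occ)] = net
                    write_network(net, out / f"network_{_safe_name(grp, occ)}")
            ei = {
                f"{g}|{o}": expected_influence(networks[(g, o)]).global_ei
                for g in GROUPS
                for o in OCCASIONS
            }
            (out / "expected_influence.json").write_text(json.dumps(ei, indent=2))
            record("estimate", t0, networks=len(networks), global_ei=ei)

        if "compare" in config.stages:
            t0 = time.time()
            results = {}
            for i, occ in enumerate(OCCASIONS):
                res = nct_independent(
                    _frame(panel, GROUPS[0], occ),
                    _frame(panel, GROUPS[1], occ),
                    K=config.permutations,
                    seed=stage_seed("compare", i),
                    config=est,
                )
                results[f"groups_{occ}"] = res
            for i, grp in enumerate(GROUPS):
                x1, x2, _ = panel.paired_matrices(group=grp)
                cols = list(panel.score_columns)
                res = nct_paired(
                    pd.DataFrame(x1, columns=cols),
                    pd.DataFrame(x2, columns=cols),
                    K=config.permutations,
                    seed=stage_seed("compare", 10 + i),
                    config=est,
                )
                results[f"occasions_{_safe_name(grp, 'both')[:3]}"] = res
            for name, res in results.items():
                write_result_json(res, out / f"nct_{name}.json", drop=("network_a", "network_b"))
            record(
                "compare",
                t0,
                permutations=config.permutations,
                p_values={k: v.p_values for k, v in results.items()},
            )

        if "pathways" in config.stages:
            t0 = time.time()
            path_tables = {}
            if not networks:
                for grp in GROUPS:
                    for occ in OCCASIONS:
                        networks[(grp, occ)] = select_network_ebic(
                            panel, config=est, group=grp, occasion=occ
                        )
            for (grp, occ), net in networks.items():
                pr = shortest_pathways(net, target=config.gd_node)
                pr.table().to_csv(out / f"pathways_{_safe_name(grp, occ)}.csv", index=False)
                path_tables[f"{grp}|{occ}"] = {"dp": pr.dp, "sp": pr.sp}
            comp = {}
            for i, occ in enumerate(OCCASIONS):
                res = compare_pathways(
                    _frame(panel, GROUPS[0], occ),
                    _frame(panel, GROUPS[1], occ),
                    variant="independent",
                    target=config.gd_node,
                    K=config.permutations,
                    seed=stage_seed("pathways", i),
                    config=est,
                )
                comp[f"groups_{occ}"] = res
                write_result_json(res, out / f"pathway_comparison_groups_{occ}.json", drop=("network_a", "network_b"))
            record("pathways", t0, summaries=path_tables, p_values={k: v.p_values for k, v in comp.items()})

        if "stability" in config.stages:
            t0 = time.time()
            stab = {}
            for i, (grp, occ) in enumerate([(g, o) for g in GROUPS for o in OCCASIONS]):
                X = panel.matrix(group=grp, occasion=occ)
                boot = bootstrap_edges(
                    X, B=config.bootstrap_replicates, seed=stage_seed("stability", i), config=est
                )
                boot.node_labels = list(panel.score_columns)
                cs = casedrop_stability(
                    X, B=config.bootstrap_replicates, seed=stage_seed("stability", 10 + i), config=est
                )
                stab[f"{grp}|{occ}"] = cs.cs_coefficient
                write_result_json(
                    boot, out / f"edge_ci_{_safe_name(grp, occ)}.json", drop=("edge_samples",)
                )
                write_result_json(
                    cs, out / f"stability_{_safe_name(grp, occ)}.json", drop=("casedrop_correlations",)
                )
            record("stability", t0, B=config.bootstrap_replicates, cs=stab)

        if "describe" in config.stages:
            t0 = time.time()
            rows = []
            continuous = [c for c in panel.score_columns if c not in panel.binary_columns]
            for occ in OCCASIONS:
                for col in continuous:
                    a = panel.slice(GROUPS[0], occ)[col].to_numpy(dtype=float)
                    b = panel.slice(GROUPS[1], occ)[col].to_numpy(dtype=float)
                    r = wilcoxon_ranksum_cc(a, b)
                    rows.append(
                        {
                            "variable": col,
                            "comparison": f"groups@{occ}",
                            "method": r.method,
                            "statistic": r.statistic,
                            "df": "",
                            "p": r.p,
                            "ci_low": r.ci_low,
                            "ci_high": r.ci_high,
                        }
                    )
                for col in sorted(panel.binary_columns):
                    a = panel.slice(GROUPS[0], occ)[col].to_numpy()
                    b = panel.slice(GROUPS[1], occ)[col].to_numpy()
                    table = [
                        [int((a == 1).sum()), int((a == 0).sum())],
                        [int((b == 1).sum()), int((b == 0).sum())],
                    ]
                    r = chisq_yates_2x2(table)
                    rows.append(
                        {
                            "variable": col,
                            "comparison": f"groups@{occ}",
                            "method": r.method,
                            "statistic": r.statistic,
                            "df": 1,
                            "p": r.p,
                            "ci_low": "",
                            "ci_high": "",
                        }
                    )
            for grp in GROUPS:
                x1, x2, ids = panel.paired_matrices(group=grp)
                for j, col in enumerate(panel.score_columns):
                    if col in panel.binary_columns:
                        continue
                    r = wilcoxon_signedrank_cc(x1[:, j], x2[:, j])
                    rows.append(
                        {
                            "variable": col,
                            "comparison": f"occasions@{grp}",
                            "method": r.method,
                            "statistic": r.statistic,
                            "df": "",
                            "p": r.p,
                            "ci_low": r.ci_low,
                            "ci_high": r.ci_high,
                        }
                    )
            table = pd.DataFrame(rows)
            # FDR correction within each comparison family of mean tests
            table["p_fdr"] = np.nan
            for fam, idx in table.groupby("comparison").groups.items():
                table.loc[idx, "p_fdr"] = bh_fdr(table.loc[idx, "p"].to_numpy(dtype=float))
            # moderation: does group membership modify occasion change?
            mod_rows = []
            long = panel.data
            age = (long["occasion"] == OCCASIONS[1]).to_numpy(dtype=float)
            grp_ind = (long["group"] == GROUPS[0]).to_numpy(dtype=float)
            sid = long["subject_id"].to_numpy()
            for col in panel.score_columns:
                m = moderation_fit(long[col].to_numpy(dtype=float), age, grp_ind, sid)
                mod_rows.append(
                    {"variable": col, "method": m.method, "interaction": m.statistic, "p": m.p}
                )
            table.to_csv(out / "group_stats.csv", index=False)
            pd.DataFrame(mod_rows).to_csv(out / "moderation.csv", index=False)
            record("describe", t0, tests=len(rows))
    except Exception:
        manifest["partial"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
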
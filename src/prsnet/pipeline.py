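"""End-to-end orchestration: config, dataset IO, the full run, exports.

A run chains generate/load -> Spearman correlations -> network estimation
-> predictive path diagram -> node-specific predictive betweenness ->
bootstraps, and writes every stage's output plus a manifest (config hash,
package version, seeds) so that a rerun with the same manifest is
byte-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (ConfigError, DataValidationError, InputError,
                     MissingColumnError)
from .ggm import ESTIMATORS, CorrelationMatrix, NetworkModel, estimate, spearman_matrix
from .paths import (node_predictive_betweenness, predictive_path_diagram,
                    shortest_predictive_paths)
from .stability import DEFAULT_DROP_GRID, casedrop_bootstrap, nonparametric_bootstrap
from .synthetic import (PRESETS, ColumnInfo, SymptomDataset, sample_dataset,
                        write_dataset)

FLOAT_FORMAT = "%.10g"  # fixed output formatting => byte-identical reruns


@dataclass
class BootstrapConfig:
    enabled: bool = True
    B: int = 1000
    casedrop: bool = True
    casedrop_B: int = 100
    proportions: tuple[float, ...] = DEFAULT_DROP_GRID
    #: optionally re-estimate resamples with a cheaper estimator than the
    #: main network (e.g. "threshold" when the main fit is "modselect")
    estimator: str | None = None
    settings: dict = field(default_factory=dict)


@dataclass
class PathsConfig:
    source: str | None = None  # default: the risk column
    max_levels: int | None = None
    tie_rule: str = "fractional"
    exclude_negative: bool = False


@dataclass
class PipelineConfig:
    """Everything a run needs; read from YAML/JSON for reproducibility."""

    input_path: str | None = None
    preset: str | None = None
    n: int | None = None
    risk_column: str = "PRS"
    estimator: str = "modselect"
    estimator_settings: dict = field(default_factory=dict)
    paths: PathsConfig = field(default_factory=PathsConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    seed: int | None = None
    output_dir: str = "prsnet_output"

    def validate(self) -> None:
        violations = []
        if (self.input_path is None) == (self.preset is None):
            violations.append("exactly one of input_path or preset must be set")
        if self.preset is not None and self.preset not in PRESETS:
            violations.append(f"unknown preset {self.preset!r}; "
                              f"available: {sorted(PRESETS)}")
        if not self.risk_column:
            violations.append("risk_column must be a non-empty name")
        if self.estimator not in ESTIMATORS:
            violations.append(f"estimator must be one of {sorted(ESTIMATORS)}, "
                              f"got {self.estimator!r}")
        boot_est = self.bootstrap.estimator
        if boot_est is not None and boot_est not in ESTIMATORS:
            violations.append(f"bootstrap.estimator must be one of "
                              f"{sorted(ESTIMATORS)}, got {boot_est!r}")
        if self.paths.tie_rule not in ("fractional", "binary"):
            violations.append("paths.tie_rule must be 'fractional' or 'binary'")
        stochastic = self.preset is not None or self.bootstrap.enabled
        if stochastic and self.seed is None:
            violations.append("seed is required when a stochastic stage "
                              "(simulation or bootstrap) is enabled")
        if self.bootstrap.enabled and self.bootstrap.B < 1:
            violations.append("bootstrap.B must be >= 1")
        if violations:
            raise ConfigError(violations)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "paths" in d and isinstance(d["paths"], dict):
            d["paths"] = PathsConfig(**d["paths"])
        if "bootstrap" in d and isinstance(d["bootstrap"], dict):
            b = dict(d["bootstrap"])
            if "proportions" in b:
                b["proportions"] = tuple(float(q) for q in b["proportions"])
            d["bootstrap"] = BootstrapConfig(**b)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError([f"unknown config key {k!r}" for k in sorted(unknown)])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_dataset(path: str | Path, risk_column: str,
                 ordinal_columns: list[str] | None = None,
                 domains: dict[str, str] | None = None) -> SymptomDataset:
    """Load and validate a subject-by-variable CSV/TSV.

    Every column except the risk column is treated as a 4-level ordinal
    item unless ``ordinal_columns`` narrows the list.  Ordinal cells must
    be integers in {0, 1, 2, 3} or empty; violations are reported with
    row and column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    if table.empty:
        raise DataValidationError(f"{path} contains no rows")
    if risk_column not in table.columns:
        raise MissingColumnError(f"declared risk column {risk_column!r} "
                                 f"is missing from {path.name}")
    if ordinal_columns is None:
        ordinal_columns = [c for c in table.columns if c != risk_column]
    missing = [c for c in ordinal_columns if c not in table.columns]
    if missing:
        raise MissingColumnError(f"declared ordinal columns missing from "
                                 f"{path.name}: {missing}")

    for col in ordinal_columns:
        vals = table[col]
        bad = vals.notna() & (~vals.isin([0, 1, 2, 3]) | (vals % 1 != 0))
        if bad.any():
            row = int(bad.idxmax())
            raise DataValidationError(
                f"ordinal column {col!r} has out-of-range or non-integer "
                f"value {vals[row]!r} at row {row} (allowed: 0..3 or missing)")

    domains = domains or {}
    cols = []
    for c in table.columns:
        if c == risk_column:
            cols.append(ColumnInfo(c, "risk", "continuous"))
        elif c in ordinal_columns:
            cols.append(ColumnInfo(c, domains.get(c, "positive"), "ordinal4"))
        else:
            continue
    keep = [c.name for c in cols]
    return SymptomDataset(table=table[keep].astype(float), columns=tuple(cols))


def _write_network(model: NetworkModel, outdir: Path, prefix: str = "network"):
    model.edge_list().to_csv(outdir / f"{prefix}_edges.csv", index=False,
                             float_format=FLOAT_FORMAT)
    pd.DataFrame(model.weights, index=list(model.labels),
                 columns=list(model.labels)).to_csv(
        outdir / f"{prefix}_weights.csv", float_format=FLOAT_FORMAT)
    report = {
        "estimator": model.estimator,
        "n": model.n,
        "n_edges": model.n_edges,
        "loglik": model.loglik,
        "k_params": model.k_params,
        "bic": model.bic,
        "settings": {k: v for k, v in model.settings.items()},
    }
    (outdir / f"{prefix}_fit.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str))
    G = nx.Graph()
    G.add_nodes_from(model.labels)
    for _, row in model.edge_list().iterrows():
        G.add_edge(row["node_i"], row["node_j"], weight=float(row["weight"]))
    nx.write_graphml(G, outdir / f"{prefix}.graphml")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured run and write all artifacts to output_dir.

    Returns a dict of the in-memory stage results (dataset, correlation
    matrix, model, diagram, betweenness, bootstrap summaries, manifest).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- data -------------------------------------------------------------
    if config.preset is not None:
        gen = PRESETS[config.preset]()
        net = gen.build_network(seed=config.seed)
        n = config.n or gen.n
        data = sample_dataset(net, n=n, seed=config.seed + 1)
        write_dataset(data, outdir / "dataset.csv")
    else:
        data = read_dataset(config.input_path, config.risk_column)
    risk = data.risk_column

    # --- correlations and network ----------------------------------------
    S = spearman_matrix(data)
    pd.DataFrame(S.matrix, index=list(S.labels), columns=list(S.labels)).to_csv(
        outdir / "spearman.csv", float_format=FLOAT_FORMAT)
    model = estimate(S, estimator=config.estimator, **config.estimator_settings)
    _write_network(model, outdir)

    # --- path analytics ---------------------------------------------------
    source = config.paths.source or risk
    diagram = predictive_path_diagram(model, source,
                                      max_levels=config.paths.max_levels,
                                      exclude_negative=config.paths.exclude_negative)
    diagram.to_json(outdir / "path_diagram.json")
    spaths = shortest_predictive_paths(model, source,
                                       exclude_negative=config.paths.exclude_negative)
    profile = node_predictive_betweenness(model, source,
                                          tie_rule=config.paths.tie_rule,
                                          exclude_negative=config.paths.exclude_negative)
    btw = profile.as_series().rename_axis("node").reset_index()
    btw.to_csv(outdir / "betweenness.csv", index=False, float_format=FLOAT_FORMAT)

    results = {"dataset": data, "correlation": S, "model": model,
               "diagram": diagram, "shortest_paths": spaths,
               "betweenness": profile}

    # --- bootstraps -------------------------------------------------------
    if config.bootstrap.enabled:
        est = config.bootstrap.estimator or config.estimator
        est_settings = (config.bootstrap.settings
                        if config.bootstrap.estimator else config.estimator_settings)
        boot = nonparametric_bootstrap(
            data, B=config.bootstrap.B, estimator=est, settings=est_settings,
            source=source, tie_rule=config.paths.tie_rule, seed=config.seed)
        boot.per_edge.to_csv(outdir / "bootstrap_edges.csv", index=False,
                             float_format=FLOAT_FORMAT)
        boot.per_node_betweenness.to_csv(outdir / "bootstrap_betweenness.csv",
                                         index=False, float_format=FLOAT_FORMAT)
        results["bootstrap"] = boot
        if config.bootstrap.casedrop:
            curve = casedrop_bootstrap(
                data, proportions=config.bootstrap.proportions,
                B=config.bootstrap.casedrop_B, estimator=est,
                settings=est_settings, source=source,
                tie_rule=config.paths.tie_rule, seed=config.seed + 10_000)
            curve.summary().to_csv(outdir / "stability_curve.csv", index=False,
                                   float_format=FLOAT_FORMAT)
            (outdir / "stability_report.json").write_text(json.dumps({
                "cs_coefficient": curve.cs_coefficient,
                "n_failed": curve.n_failed,
                "B": curve.B,
                "drop_proportions": list(curve.drop_proportions),
            }, indent=1))
            results["stability"] = curve

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "prsnet_version": __version__,
        "seeds": {
            "master": config.seed,
            "network": config.seed if config.preset else None,
            "dataset": config.seed + 1 if config.preset else None,
            "bootstrap": config.seed if config.bootstrap.enabled else None,
            "casedrop": (config.seed + 10_000
                         if config.bootstrap.enabled and config.bootstrap.casedrop
                         else None),
        },
        "n_subjects": data.n,
        "n_nodes": len(data.labels),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    results["manifest"] = manifest
    return results


def compare_estimators(data: SymptomDataset,
                       estimators: dict[str, dict] | None = None,
                       output_dir: str | Path | None = None) -> pd.DataFrame:
    """Fit all three estimators on one dataset and tabulate edge agreement.

    Returns one row per edge found by at least one estimator, with a
    boolean column per estimator and ``n_methods``, mirroring the
    cross-method robustness table of applied network studies.
    """
    if estimators is None:
        estimators = {"modselect": {}, "ebic_path": {}, "threshold": {}}
    S = spearman_matrix(data)
    edge_sets: dict[str, set] = {}
    weights: dict[str, dict] = {}
    for name, settings in estimators.items():
        model = estimate(S, estimator=name, **settings)
        edges = model.edge_list()
        keys = list(zip(edges["node_i"], edges["node_j"]))
        edge_sets[name] = set(keys)
        weights[name] = dict(zip(keys, edges["weight"]))

    order = {lab: i for i, lab in enumerate(S.labels)}
    all_edges = sorted(set().union(*edge_sets.values()),
                       key=lambda e: (order[e[0]], order[e[1]]))
    rows = []
    for e in all_edges:
        row = {"node_i": e[0], "node_j": e[1]}
        for name in estimators:
            row[f"in_{name}"] = e in edge_sets[name]
            row[f"weight_{name}"] = weights[name].get(e, 0.0)
        row["n_methods"] = sum(e in edge_sets[name] for name in estimators)
        rows.append(row)
    df = pd.DataFrame(rows)
    if output_dir is not None:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(output_dir) / "estimator_agreement.csv", index=False,
                  float_format=FLOAT_FORMAT)
    return df
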
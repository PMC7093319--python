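"""Synthetic cohorts with planted partial-correlation structure.

The generator mirrors the data layout of a psychosis-spectrum cohort
assessed with a 42-item self-report symptom scale (20 positive, 14
negative, 8 depressive items, each scored on a 4-point frequency scale)
plus one continuous polygenic-risk-score column per subject.

Data are simulated from a latent-Gaussian threshold model: a sparse
Gaussian graphical model (GGM) is planted on latent continuous variables,
symptom columns are discretized at fixed cut-points into four ordered
levels, and the risk column stays continuous.  Under this model rank
correlations (Spearman) consistently recover the latent association
structure, which is why the estimation stage uses them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstructionError, InputError

RISK_DOMAIN = "risk"
DOMAINS = ("positive", "negative", "depressive", RISK_DOMAIN)

#: latent cut-points giving equal 25% occupancy of the four ordinal levels
QUARTILE_CUTS = stats.norm.ppf([0.25, 0.50, 0.75])

#: skewed cut-points for symptom-like items: most subjects endorse the
#: lowest level ("never"), few the highest (level probabilities
#: 0.55 / 0.25 / 0.13 / 0.07)
SKEWED_CUTS = stats.norm.ppf(np.cumsum([0.55, 0.25, 0.13]))


def _pcor_from_precision(precision: np.ndarray) -> np.ndarray:
    """Standardize a precision matrix into partial correlations.

    pcor[i, j] = -kappa_ij / sqrt(kappa_ii * kappa_jj), zero diagonal.
    """
    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground truth used to simulate a cohort.

    ``pcor_true`` holds the realized partial correlations (after any
    positive-definiteness repair), ``precision`` the generating inverse
    covariance, ``thresholds`` the latent cut-points per ordinal variable
    (none for the risk node), and ``shrinkage`` the common factor applied
    to off-diagonal precision entries to restore positive definiteness
    (1.0 when no repair was needed).
    """

    labels: tuple[str, ...]
    pcor_true: np.ndarray
    precision: np.ndarray
    adjacency: np.ndarray
    thresholds: dict[str, np.ndarray]
    domain_tags: tuple[str, ...]
    shrinkage: float = 1.0

    def __post_init__(self):
        p = len(self.labels)
        for name, mat in (("pcor_true", self.pcor_true),
                          ("precision", self.precision),
                          ("adjacency", self.adjacency)):
            if mat.shape != (p, p):
                raise InputError(f"{name} must be {p}x{p}, got {mat.shape}")
        eigmin = float(np.linalg.eigvalsh(self.precision)[0])
        if eigmin <= 0:
            raise ConstructionError(
                f"precision is not positive definite (min eigenvalue {eigmin:g})")
        for lab, cuts in self.thresholds.items():
            if np.any(np.diff(cuts) <= 0):
                raise InputError(f"thresholds for {lab!r} are not strictly increasing")

    @property
    def risk_index(self) -> int:
        return self.domain_tags.index(RISK_DOMAIN)

    @property
    def risk_label(self) -> str:
        return self.labels[self.risk_index]

    @property
    def symptom_labels(self) -> tuple[str, ...]:
        return tuple(l for l, d in zip(self.labels, self.domain_tags) if d != RISK_DOMAIN)

    def covariance(self) -> np.ndarray:
        """Latent covariance, rescaled to unit variances."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)


@dataclass(frozen=True)
class ColumnInfo:
    name: str
    domain: str
    scale: str  # "ordinal4" | "continuous"


@dataclass
class SymptomDataset:
    """Subject-by-variable table: ordinal symptom items plus a continuous
    risk column.  Ordinal cells are integers in {0, 1, 2, 3} stored as
    floats so that missing cells can be NaN."""

    table: pd.DataFrame
    columns: tuple[ColumnInfo, ...]
    truth: PlantedNetwork | None = None

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise InputError("column names must be unique")
        if list(self.table.columns) != names:
            raise InputError("table columns do not match column metadata")
        if len(self.table) < 1:
            raise InputError("dataset must have at least one row")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def risk_column(self) -> str:
        risk = [c.name for c in self.columns if c.scale == "continuous"]
        if len(risk) != 1:
            raise InputError(f"expected exactly one continuous risk column, found {risk}")
        return risk[0]

    @property
    def ordinal_columns(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.scale == "ordinal4")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.table.isna()


def _domain_edge_probability(edge_probability, tag_i: str, tag_j: str) -> float:
    if isinstance(edge_probability, Mapping):
        key = "within" if tag_i == tag_j else "between"
        return float(edge_probability[key])
    return float(edge_probability)


def planted_network_from_pcor(
    pcor: np.ndarray,
    labels: Sequence[str],
    domain_tags: Sequence[str],
    thresholds="quartile",
    eig_floor: float = 1e-6,
    shrink_step: float = 0.95,
) -> PlantedNetwork:
    """Build a :class:`PlantedNetwork` from target partial correlations.

    Off-diagonal precision entries are set to minus the target partial
    correlations on a unit diagonal.  If the result is not positive
    definite, all off-diagonal entries are shrunk by a common factor until
    the smallest eigenvalue reaches ``eig_floor``; the realized partial
    correlations (recomputed from the final precision) become the ground
    truth and the cumulative factor is recorded as ``shrinkage``.
    """
    pcor = np.asarray(pcor, dtype=float)
    p = pcor.shape[0]
    if pcor.shape != (p, p) or not np.allclose(pcor, pcor.T, atol=1e-12):
        raise InputError("pcor must be a symmetric square matrix")
    if np.any(np.abs(pcor[~np.eye(p, dtype=bool)]) >= 1):
        raise InputError("target partial correlations must lie in (-1, 1)")
    labels = tuple(labels)
    domain_tags = tuple(domain_tags)
    if len(labels) != p or len(domain_tags) != p:
        raise InputError("labels/domain_tags length must match matrix size")

    precision = np.eye(p) - pcor  # unit diagonal, off-diagonal -pcor
    np.fill_diagonal(precision, 1.0)
    shrink = 1.0
    # uniform off-diagonal shrinkage until PD (deterministic repair)
    for _ in range(2000):
        if np.linalg.eigvalsh(precision)[0] >= eig_floor:
            break
        shrink *= shrink_step
        off = precision - np.diag(np.diag(precision))
        precision = np.diag(np.diag(precision)) + off * shrink_step
    else:
        raise ConstructionError(
            "could not reach positive definiteness by off-diagonal shrinkage")

    realized = _pcor_from_precision(precision)
    adjacency = realized != 0.0
    np.fill_diagonal(adjacency, False)

    thr: dict[str, np.ndarray] = {}
    for lab, tag in zip(labels, domain_tags):
        if tag == RISK_DOMAIN:
            continue
        if isinstance(thresholds, str):
            if thresholds == "quartile":
                cuts = QUARTILE_CUTS
            elif thresholds == "skewed":
                cuts = SKEWED_CUTS
            else:
                raise InputError(f"unknown thresholds preset {thresholds!r}")
        elif isinstance(thresholds, Mapping):
            cuts = np.asarray(thresholds[lab], dtype=float)
        else:
            cuts = np.asarray(thresholds, dtype=float)
        if cuts.shape != (3,) or np.any(np.diff(cuts) <= 0):
            raise InputError(f"thresholds for {lab!r} must be 3 strictly increasing cut-points")
        thr[lab] = np.array(cuts, dtype=float)

    return PlantedNetwork(labels=labels, pcor_true=realized, precision=precision,
                          adjacency=adjacency, thresholds=thr,
                          domain_tags=domain_tags, shrinkage=shrink)


def generate_planted_network(
    n_symptoms: int,
    edge_probability,
    weight_range: tuple[float, float],
    risk_edges: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    labels: Sequence[str] | None = None,
    domain_tags: Sequence[str] | None = None,
    risk_label: str = "PRS",
    thresholds="quartile",
) -> PlantedNetwork:
    """Plant a random sparse GGM over symptoms plus one risk node.

    Symptom-symptom edges appear independently with ``edge_probability``
    (a scalar, or a ``{"within": ..., "between": ...}`` mapping keyed by
    domain co-membership) and receive weights drawn uniformly from
    ``weight_range``.  Direct risk edges are given explicitly via
    ``risk_edges`` (symptom name -> partial correlation); the risk node
    gets no other edges, so any additional connectivity to the risk node
    in an estimate is a false positive by construction.
    """
    if n_symptoms < 2:
        raise InputError("need at least 2 symptoms")
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not (-1 < lo <= hi < 1):
        raise InputError("weight_range must lie within (-1, 1)")
    risk_edges = dict(risk_edges or {})

    if labels is None:
        width = len(str(n_symptoms))
        labels = [f"S{i + 1:0{width}d}" for i in range(n_symptoms)]
    labels = list(labels)
    if len(labels) != n_symptoms:
        raise InputError("labels length must equal n_symptoms")
    if domain_tags is None:
        domain_tags = ["positive"] * n_symptoms
    domain_tags = list(domain_tags)

    unknown = set(risk_edges) - set(labels)
    if unknown:
        raise InputError(f"risk_edges name unknown symptoms: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    p = n_symptoms + 1
    pcor = np.zeros((p, p))
    for i in range(n_symptoms):
        for j in range(i + 1, n_symptoms):
            prob = _domain_edge_probability(edge_probability, domain_tags[i], domain_tags[j])
            if rng.random() < prob:
                w = rng.uniform(lo, hi)
                pcor[i, j] = pcor[j, i] = w
    for name, w in risk_edges.items():
        i = labels.index(name)
        if not -1 < w < 1:
            raise InputError(f"risk edge weight for {name!r} must lie in (-1, 1)")
        pcor[i, n_symptoms] = pcor[n_symptoms, i] = float(w)

    return planted_network_from_pcor(
        pcor, labels=labels + [risk_label],
        domain_tags=domain_tags + [RISK_DOMAIN], thresholds=thresholds)


@dataclass(frozen=True)
class GeneratorConfig:
    """A named bundle of generator settings (a preset)."""

    name: str
    n_symptoms: int
    domain_sizes: tuple[int, int, int]
    edge_probability: Mapping[str, float]
    weight_range: tuple[float, float]
    risk_edges: Mapping[str, float]
    thresholds: str
    n: int

    @property
    def labels(self) -> list[str]:
        n_pos, n_neg, n_dep = self.domain_sizes
        return ([f"P{i + 1:02d}" for i in range(n_pos)]
                + [f"N{i + 1:02d}" for i in range(n_neg)]
                + [f"D{i + 1:02d}" for i in range(n_dep)])

    @property
    def domain_tags(self) -> list[str]:
        n_pos, n_neg, n_dep = self.domain_sizes
        return ["positive"] * n_pos + ["negative"] * n_neg + ["depressive"] * n_dep

    def build_network(self, seed: int) -> PlantedNetwork:
        return generate_planted_network(
            self.n_symptoms, self.edge_probability, self.weight_range,
            risk_edges=self.risk_edges, seed=seed, labels=self.labels,
            domain_tags=self.domain_tags, thresholds=self.thresholds)


def cape_like_config() -> GeneratorConfig:
    """Preset emulating a 42-item symptom scale plus a polygenic risk node.

    20 positive, 14 negative and 8 depressive items on a 4-point scale;
    within-domain edges denser than between-domain edges; skewed item
    marginals (symptom endorsement is rare); one risk node with four weak
    direct partial correlations (|rho| <= 0.1) into positive and
    depressive items; default cohort size n = 2180.
    """
    return GeneratorConfig(
        name="cape_like",
        n_symptoms=42,
        domain_sizes=(20, 14, 8),
        edge_probability={"within": 0.12, "between": 0.03},
        weight_range=(0.15, 0.35),
        risk_edges={"P03": 0.10, "P11": 0.09, "P17": 0.08, "D02": 0.07},
        thresholds="skewed",
        n=2180,
    )


PRESETS = {"cape_like": cape_like_config}


def sample_dataset(
    net: PlantedNetwork,
    n: int,
    thresholds_spec=None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SymptomDataset:
    """Draw a cohort of ``n`` subjects from a planted network.

    Latent vectors are multivariate normal with the network's unit-variance
    covariance; each symptom column is cut at its thresholds into ordinal
    levels 0..3; the risk column stays continuous.  Missing cells are set
    independently (MCAR) at ``missing_rate``.  Identical arguments yield a
    bit-identical table.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if not 0 <= missing_rate < 1:
        raise InputError("missing_rate must be in [0, 1)")

    p = len(net.labels)
    cov = net.covariance()
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n, p)) @ L.T

    data = np.empty((n, p))
    cols: list[ColumnInfo] = []
    for k, (lab, tag) in enumerate(zip(net.labels, net.domain_tags)):
        if tag == RISK_DOMAIN:
            data[:, k] = latent[:, k]
            cols.append(ColumnInfo(lab, tag, "continuous"))
            continue
        if thresholds_spec is None:
            cuts = net.thresholds[lab]
        elif isinstance(thresholds_spec, str) and thresholds_spec == "quartile":
            cuts = QUARTILE_CUTS
        elif isinstance(thresholds_spec, Mapping):
            cuts = np.asarray(thresholds_spec[lab], dtype=float)
        else:
            cuts = np.asarray(thresholds_spec, dtype=float)
        data[:, k] = np.searchsorted(cuts, latent[:, k]).astype(float)
        cols.append(ColumnInfo(lab, tag, "ordinal4"))

    if missing_rate > 0:
        mask = rng.random((n, p)) < missing_rate
        data[mask] = np.nan

    table = pd.DataFrame(data, columns=list(net.labels))
    return SymptomDataset(table=table, columns=tuple(cols), truth=net)


# ---------------------------------------------------------------------------
# on-disk representation: CSV table + sidecar JSON metadata

def write_dataset(ds: SymptomDataset, path: str | Path,
                  include_truth: bool = True) -> Path:
    """Write the table as CSV with a ``.meta.json`` sidecar (column domains
    and scale types; planted-truth matrices when available, for test use).
    Returns the sidecar path."""
    path = Path(path)
    ds.table.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "columns": [{"name": c.name, "domain": c.domain, "scale": c.scale}
                    for c in ds.columns],
    }
    if include_truth and ds.truth is not None:
        t = ds.truth
        meta["truth"] = {
            "labels": list(t.labels),
            "domain_tags": list(t.domain_tags),
            "pcor_true": t.pcor_true.tolist(),
            "precision": t.precision.tolist(),
            "adjacency": t.adjacency.astype(int).tolist(),
            "thresholds": {k: v.tolist() for k, v in t.thresholds.items()},
            "shrinkage": t.shrinkage,
        }
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return side


def read_dataset_csv(path: str | Path) -> SymptomDataset:
    """Read a dataset written by :func:`write_dataset` (sidecar required)."""
    path = Path(path)
    side = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(side.read_text())
    cols = tuple(ColumnInfo(c["name"], c["domain"], c["scale"]) for c in meta["columns"])
    table = pd.read_csv(path)
    truth = None
    if "truth" in meta:
        t = meta["truth"]
        truth = PlantedNetwork(
            labels=tuple(t["labels"]),
            pcor_true=np.asarray(t["pcor_true"], dtype=float),
            precision=np.asarray(t["precision"], dtype=float),
            adjacency=np.asarray(t["adjacency"], dtype=bool),
            thresholds={k: np.asarray(v, dtype=float) for k, v in t["thresholds"].items()},
            domain_tags=tuple(t["domain_tags"]),
            shrinkage=float(t["shrinkage"]),
        )
    return SymptomDataset(table=table, columns=cols, truth=truth)
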
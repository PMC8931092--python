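"""Synthetic RPPA cohort generator with known planted structure.

Emulates the study conditions of a large CLL RPPA cohort: 384 proteins
sorted into 40 functional groups (PFGs), ~800 patients plus 5 CD19+
B-cell controls, per-PFG k-means-recoverable cluster structure, a
signature-dependent binary block structure over the one-hot pattern
matrix, and signature-group-dependent proportional-hazards survival
(OS / TTFT / TTST) with uniform censoring.  Every downstream stage of
the pipeline is testable against the planted truth.

Generative model
----------------
* Each patient draws a signature uniformly from ``1..R``.
* Within each PFG the cluster centroids sit on scaled simplex vertices,
  so every pair of centroids is exactly ``centroid_separation`` apart.
* For each (signature, PFG) one cluster is "preferred"; the patient's
  cluster is categorical with weight ``block_p_in`` on the preferred
  cluster and ``block_p_out`` on each other cluster (weights
  normalized).  Preferred clusters are wired so that one-hot pattern
  columns group into ``C`` planted constellations: signature ``r``
  prefers columns of constellation ``(r-1) mod C``.
* Expression = centroid + iid Gaussian(0, noise_sd).  Controls are
  drawn at the designated normal-like centroid of each PFG.
* Survival per endpoint is Exponential with the hazard of the patient's
  signature group; censoring is Uniform(0, censor_window); the event
  indicator is 1 for an observed event and 0 for censored, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .rppa import ExpressionMatrix

ENDPOINTS = ("OS", "TTFT", "TTST")


class ConfigError(ValueError):
    """A SimConfig invariant is violated; the message names it."""


def _default_pfg_sizes() -> tuple[int, ...]:
    # 40 PFGs summing to 384 proteins (24 groups of 10, 16 of 9)
    return tuple([10] * 24 + [9] * 16)


def _default_true_k() -> tuple[int, ...]:
    # 150 patterns over 40 PFGs (mean 3.75)
    return tuple([3, 4, 4, 4] * 10)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the scale of the emulated study: 800 patients,
    5 CD19+ controls, 384 proteins in 40 PFGs with 150 planted patterns,
    16 signatures and 13 constellations.  Hazards are per signature
    group in units of 1/years; ``censor_window`` is the administrative
    follow-up horizon in years.
    """

    n_patients: int = 800
    n_controls: int = 5
    pfg_sizes: Sequence[int] = field(default_factory=_default_pfg_sizes)
    true_k_per_pfg: Sequence[int] = field(default_factory=_default_true_k)
    n_signatures: int = 16
    n_constellations: int = 13
    centroid_separation: float = 2.0
    noise_sd: float = 0.5
    block_p_in: float = 0.9
    block_p_out: float = 0.05
    hazard_per_group: Mapping[str, Sequence[float]] | None = None
    censor_window: float = 25.0
    signature_group_map: Mapping[int, int] | None = None
    seed: int = 0

    def n_proteins(self) -> int:
        return int(sum(self.pfg_sizes))

    def n_groups(self) -> int:
        if self.signature_group_map is None:
            return self.n_signatures
        return len(set(self.signature_group_map.values()))

    def group_of(self, signature: int) -> int:
        """Signature-group of a 1-based signature label (identity by default)."""
        if self.signature_group_map is None:
            return signature
        return self.signature_group_map[signature]

    def hazards(self) -> dict[str, np.ndarray]:
        """Per-endpoint hazard per signature group (1/years)."""
        g = self.n_groups()
        if self.hazard_per_group is None:
            # spread of median survivals roughly 6-23y (OS), 3.5-14y (TTFT/TTST)
            default = {
                "OS": np.linspace(0.03, 0.12, g),
                "TTFT": np.linspace(0.05, 0.20, g),
                "TTST": np.linspace(0.04, 0.15, g),
            }
            return default
        out = {}
        for ep in ENDPOINTS:
            h = np.asarray(self.hazard_per_group[ep], dtype=float)
            if len(h) != g:
                raise ConfigError(
                    f"hazard_per_group[{ep!r}] has {len(h)} entries for {g} groups")
            out[ep] = h
        return out

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.n_controls < 0:
            raise ConfigError("n_controls must be >= 0")
        if len(self.pfg_sizes) != len(self.true_k_per_pfg):
            raise ConfigError("pfg_sizes and true_k_per_pfg must have equal length")
        if any(k < 1 for k in self.true_k_per_pfg):
            raise ConfigError("all true_k_per_pfg must be >= 1")
        for size, k in zip(self.pfg_sizes, self.true_k_per_pfg):
            if size < k:
                raise ConfigError(
                    f"pfg size {size} smaller than its cluster count {k}: "
                    "simplex centroid construction needs dimension >= k")
        if not (0 <= self.block_p_out < self.block_p_in <= 1):
            raise ConfigError("require 0 <= block_p_out < block_p_in <= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_signatures < 1 or self.n_constellations < 1:
            raise ConfigError("n_signatures and n_constellations must be >= 1")
        if self.censor_window <= 0:
            raise ConfigError("censor_window must be > 0")
        for h in self.hazards().values():
            if np.any(h <= 0):
                raise ConfigError("hazards must be > 0")
        if self.signature_group_map is not None:
            if set(self.signature_group_map) != set(range(1, self.n_signatures + 1)):
                raise ConfigError("signature_group_map must map every signature 1..R")


@dataclass
class Truth:
    """Planted ground truth of a generated cohort.

    All labels are 1-based.  ``constellations`` maps each pattern column
    id (``"PFG01|C2"`` style) to its planted constellation;
    ``normal_like`` maps each PFG to the cluster whose centroid the
    controls were drawn near.
    """

    signatures: pd.Series            # patient -> signature 1..R
    cluster_labels: pd.DataFrame     # patients x PFGs, 1..k_g
    constellations: pd.Series        # pattern column id -> constellation 1..C
    normal_like: dict[str, int]      # pfg -> normal-like cluster
    group_map: dict[int, int]        # signature -> signature group
    preferred: pd.DataFrame          # signatures x PFGs, preferred cluster (0 = none)

    def groups(self) -> pd.Series:
        """Per-patient signature-group label."""
        return self.signatures.map(self.group_map).rename("group")

    def pattern_matrix(self) -> pd.DataFrame:
        """One-hot patients x pattern-columns encoding of the planted clusters."""
        blocks = []
        for pfg in self.cluster_labels.columns:
            lab = self.cluster_labels[pfg]
            k = int(lab.max())
            cols = [f"{pfg}|C{j}" for j in range(1, k + 1)]
            onehot = pd.DataFrame(
                np.eye(k, dtype=int)[lab.to_numpy() - 1],
                index=lab.index, columns=cols)
            blocks.append(onehot)
        return pd.concat(blocks, axis=1)


def pfg_definitions(config: SimConfig) -> dict[str, list[str]]:
    """PFG name -> member protein ids, matching the generated matrix columns."""
    defs: dict[str, list[str]] = {}
    for g, size in enumerate(config.pfg_sizes, start=1):
        name = f"PFG{g:02d}"
        defs[name] = [f"{name}_p{m:02d}" for m in range(1, size + 1)]
    return defs


def _centroids(k: int, dim: int, separation: float) -> np.ndarray:
    """k centroids in R^dim with all pairwise distances == separation.

    Scaled standard-simplex vertices: v_j = (s/sqrt(2)) e_j.
    """
    c = np.zeros((k, dim))
    c[np.arange(k), np.arange(k)] = separation / np.sqrt(2.0)
    return c


def _plant_structure(config: SimConfig):
    """Constellation of every pattern column and preferred cluster per (signature, PFG)."""
    C = config.n_constellations
    defs = pfg_definitions(config)
    names = list(defs)
    const: dict[str, int] = {}
    preferred = np.zeros((config.n_signatures, len(names)), dtype=int)
    for gi, (name, k) in enumerate(zip(names, config.true_k_per_pfg)):
        for j in range(1, k + 1):
            if k == C:
                c = j
            else:
                c = (gi + j - 1) % C + 1
            const[f"{name}|C{j}"] = c
        for r in range(1, config.n_signatures + 1):
            want = (r - 1) % C + 1
            js = [j for j in range(1, k + 1) if const[f"{name}|C{j}"] == want]
            preferred[r - 1, gi] = js[0] if js else 0
    return const, pd.DataFrame(preferred, index=np.arange(1, config.n_signatures + 1),
                               columns=names)


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, Truth]:
    """Generate (expression, clinical table, truth) for one synthetic cohort.

    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    defs = pfg_definitions(config)
    names = list(defs)
    n, R = config.n_patients, config.n_signatures
    patients = [f"PT{i:04d}" for i in range(1, n + 1)]
    controls = [f"CD19_{i}" for i in range(1, config.n_controls + 1)]

    const, preferred = _plant_structure(config)
    signatures = rng.integers(1, R + 1, size=n)

    cluster_labels = np.zeros((n, len(names)), dtype=int)
    expr = np.empty((n + config.n_controls, config.n_proteins()))
    normal_like: dict[str, int] = {}
    col_start = 0
    for gi, (name, k) in enumerate(zip(names, config.true_k_per_pfg)):
        dim = config.pfg_sizes[gi]
        cent = _centroids(k, dim, config.centroid_separation)
        # cluster draw per patient: categorical weights p_in / p_out, normalized
        labels = np.empty(n, dtype=int)
        for r in range(1, R + 1):
            mask = signatures == r
            if not mask.any():
                continue
            pref = preferred.at[r, name]
            if pref == 0 or k == 1:
                w = np.full(k, 1.0 / k)
            else:
                w = np.full(k, config.block_p_out)
                w[pref - 1] = config.block_p_in
                w = w / w.sum()
            labels[mask] = rng.choice(np.arange(1, k + 1), size=int(mask.sum()), p=w)
        cluster_labels[:, gi] = labels
        block = cent[labels - 1] + rng.normal(0.0, config.noise_sd, size=(n, dim))
        expr[:n, col_start:col_start + dim] = block
        nl = int(rng.integers(1, k + 1))
        normal_like[name] = nl
        if config.n_controls:
            expr[n:, col_start:col_start + dim] = (
                cent[nl - 1]
                + rng.normal(0.0, config.noise_sd, size=(config.n_controls, dim)))
        col_start += dim

    all_ids = patients + controls
    values = pd.DataFrame(expr, index=all_ids,
                          columns=[p for ps in defs.values() for p in ps])
    meta = pd.DataFrame(index=all_ids)
    meta["diagnosis"] = ["CLL"] * n + ["normal"] * config.n_controls
    meta["is_control"] = [False] * n + [True] * config.n_controls
    meta["organ"] = list(rng.choice(["PB", "BM"], size=n, p=[0.92, 0.08])) + ["PB"] * config.n_controls
    meta["preservation"] = list(rng.choice(["frozen", "fresh"], size=n, p=[0.85, 0.15])) + \
        ["fresh"] * config.n_controls
    meta["collection_interval"] = np.r_[rng.exponential(3.0, size=n),
                                        np.zeros(config.n_controls)]
    meta["therapy_class"] = list(
        rng.choice(["none", "chemo", "antibody", "BTKi"], size=n,
                   p=[0.60, 0.22, 0.05, 0.13])) + ["none"] * config.n_controls
    m = ExpressionMatrix(values, meta)

    group_map = (dict(config.signature_group_map) if config.signature_group_map
                 else {r: r for r in range(1, R + 1)})
    groups = np.array([group_map[s] for s in signatures])
    group_index = {g: i for i, g in enumerate(sorted(set(group_map.values())))}
    hazards = config.hazards()
    clin = pd.DataFrame(index=pd.Index(patients, name="sample_id"))
    for ep in ENDPOINTS:
        h = hazards[ep][[group_index[g] for g in groups]]
        t_event = rng.exponential(1.0 / h)
        t_cens = rng.uniform(0.0, config.censor_window, size=n)
        clin[f"{ep}_time"] = np.minimum(t_event, t_cens)
        clin[f"{ep}_event"] = (t_event <= t_cens).astype(int)
    clin["age"] = np.clip(rng.normal(65, 10, size=n), 30, 95).round(1)
    clin["rai_stage"] = rng.choice([0, 1, 2, 3, 4], size=n,
                                   p=[0.34, 0.30, 0.06, 0.17, 0.13])
    clin["binet"] = rng.choice(["A", "B", "C"], size=n, p=[0.61, 0.09, 0.30])
    clin["ighv"] = rng.choice(["mutated", "unmutated", "unknown"], size=n,
                              p=[0.40, 0.40, 0.20])
    for col, p in [("del17p", 0.10), ("del11q", 0.14), ("del13q", 0.38),
                   ("trisomy12", 0.15), ("zap70", 0.50)]:
        clin[col] = rng.random(n) < p
    clin["b2m"] = np.round(rng.lognormal(np.log(2.4), 0.5, size=n), 2)
    clin["therapy_class"] = meta["therapy_class"].iloc[:n].to_numpy()

    truth = Truth(
        signatures=pd.Series(signatures, index=patients, name="signature"),
        cluster_labels=pd.DataFrame(cluster_labels, index=patients, columns=names),
        constellations=pd.Series(const, name="constellation"),
        normal_like=normal_like,
        group_map=group_map,
        preferred=preferred,
    )
    return m, clin, truth


def write_cohort(out_dir: str | Path, m: ExpressionMatrix, clinical: pd.DataFrame,
                 truth: Truth, config: SimConfig | None = None) -> None:
    """Write expression/metadata/clinical as TSV and truth (+config) as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(out / "expression.tsv", sep="\t", index_label="sample_id")
    m.sample_meta.drop(columns=["_meta_missing"], errors="ignore").to_csv(
        out / "sample_meta.tsv", sep="\t", index_label="sample_id")
    clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="sample_id")
    doc = {
        "signatures": {k: int(v) for k, v in truth.signatures.items()},
        "cluster_labels": {p: [int(x) for x in row]
                           for p, row in truth.cluster_labels.iterrows()},
        "pfg_order": list(truth.cluster_labels.columns),
        "constellations": {k: int(v) for k, v in truth.constellations.items()},
        "normal_like": {k: int(v) for k, v in truth.normal_like.items()},
        "group_map": {int(k): int(v) for k, v in truth.group_map.items()},
    }
    if config is not None:
        doc["config"] = {
            "n_patients": config.n_patients, "n_controls": config.n_controls,
            "pfg_sizes": list(config.pfg_sizes),
            "true_k_per_pfg": list(config.true_k_per_pfg),
            "n_signatures": config.n_signatures,
            "n_constellations": config.n_constellations,
            "centroid_separation": config.centroid_separation,
            "noise_sd": config.noise_sd,
            "block_p_in": config.block_p_in, "block_p_out": config.block_p_out,
            "censor_window": config.censor_window, "seed": config.seed,
        }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    with open(out / "pfg_definitions.tsv", "w") as fh:
        fh.write("pfg_name\tprotein_id\n")
        cfg = config if config is not None else SimConfig()
        for pfg, prots in pfg_definitions(cfg).items():
            for p in prots:
                fh.write(f"{pfg}\t{p}\n")
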
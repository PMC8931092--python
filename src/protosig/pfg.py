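"""Per-functional-group clustering with stability-based k selection.

Each protein functional group (PFG) — a curated set of functionally
related proteins — is clustered over patients with k-means.  The number
of clusters is chosen by the gap statistic (Tibshirani, Walther &
Hastie): the within-cluster dispersion of the data is compared on the
log scale with that of uniform reference datasets drawn over the
PCA-aligned bounding box of the data, and the smallest k satisfying
``Gap(k) >= Gap(k+1) - se(k+1)`` is selected.  A progeny-resampling
stability criterion is available as an alternative.  Each resulting
patient cluster ("expression pattern") is then compared against the
CD19+ control samples via PCA + LDA to flag clusters whose expression
is normal-like.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA

from .rppa import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PFGDefinition:
    pfg_name: str
    member_protein_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.member_protein_ids) < 2:
            raise DataError(f"PFG {self.pfg_name!r} needs >= 2 member proteins")


def load_pfg_definitions(path, sep: str = "\t") -> list[PFGDefinition]:
    """Read a two-column table (pfg_name, protein_id) into definitions."""
    df = pd.read_csv(path, sep=sep)
    if not {"pfg_name", "protein_id"} <= set(df.columns):
        raise DataError("PFG definition table needs columns pfg_name, protein_id")
    return [PFGDefinition(name, list(grp["protein_id"]))
            for name, grp in df.groupby("pfg_name", sort=True)]


@dataclass
class PFGClusterModel:
    """Fitted clustering of one PFG.

    ``labels`` are 1..k per patient, renumbered canonically by
    descending cluster size; ``k_diagnostics`` holds per-candidate-k gap
    values and standard errors; ``normal_like_flags[c]`` is True when at
    least one control sample is classified into cluster c.
    """

    pfg_name: str
    k_selected: int
    centroids: np.ndarray
    labels: pd.Series
    k_diagnostics: pd.DataFrame
    normal_like_flags: dict[int, bool] = field(default_factory=dict)
    control_assignments: pd.Series | None = None


def _within_dispersion(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    return float(((X - centers[labels]) ** 2).sum())


def _kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 10):
    if k == 1:
        center = X.mean(axis=0, keepdims=True)
        return np.zeros(len(X), dtype=int), center
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    lab = km.fit_predict(X)
    return lab, km.cluster_centers_


def _reference_sampler(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over the PCA-aligned bounding box of X.

    Aligning the box with the principal axes (rather than the feature
    axes) makes the null respect the data's overall shape, and makes k
    selection equivariant under rescaling of the submatrix.
    """
    mu = X.mean(axis=0)
    Xc = X - mu
    # rotation from SVD; falls back to identity for degenerate data
    try:
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover
        Vt = np.eye(X.shape[1])
    scores = Xc @ Vt.T
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    ref = rng.uniform(lo, hi, size=scores.shape)
    return ref @ Vt + mu


def gap_statistic(X: np.ndarray, k_range: Sequence[int], n_refs: int = 50,
                  seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """Gap statistic table over candidate k.

    Returns a DataFrame indexed by k with columns ``log_w`` (log within
    dispersion of the data), ``gap`` and ``se`` where
    ``gap(k) = mean_b log(W_ref_b,k) - log(W_k)`` and
    ``se(k) = sd_b(log W_ref_b,k) * sqrt(1 + 1/B)``.
    """
    rng = np.random.default_rng(seed)
    ks = sorted(set(int(k) for k in k_range))
    refs = [_reference_sampler(X, rng) for _ in range(n_refs)]
    rows = []
    for k in ks:
        lab, cen = _kmeans(X, k, seed=seed, n_init=n_init)
        log_w = np.log(max(_within_dispersion(X, lab, cen), 1e-300))
        log_w_ref = np.empty(n_refs)
        for b, ref in enumerate(refs):
            rl, rc = _kmeans(ref, k, seed=seed + b + 1, n_init=n_init)
            log_w_ref[b] = np.log(max(_within_dispersion(ref, rl, rc), 1e-300))
        gap = log_w_ref.mean() - log_w
        se = log_w_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
        rows.append((k, log_w, gap, se))
    return pd.DataFrame(rows, columns=["k", "log_w", "gap", "se"]).set_index("k")


def progeny_stability(X: np.ndarray, k_range: Sequence[int], n_refs: int = 20,
                      seed: int = 0, n_init: int = 10,
                      n_progeny: int = 40) -> pd.DataFrame:
    """Progeny-resampling stability score over candidate k.

    For each k the data are clustered, then "progeny" pseudo-samples are
    built by resampling each feature independently within a cluster
    (preserving marginal structure, destroying residual correlation) and
    re-clustered; the score is the mean fraction of progeny pairs from
    the same parent cluster that are co-assigned, minus the same
    quantity for pairs from different parents.  Higher is more stable.
    """
    rng = np.random.default_rng(seed)
    ks = [k for k in sorted(set(map(int, k_range)))]
    rows = []
    for k in ks:
        if k == 1:
            rows.append((k, 0.0))
            continue
        lab, _ = _kmeans(X, k, seed=seed, n_init=n_init)
        scores = []
        for b in range(n_refs):
            prog = np.empty((k * n_progeny, X.shape[1]))
            parent = np.repeat(np.arange(k), n_progeny)
            for c in range(k):
                members = X[lab == c]
                for j in range(X.shape[1]):
                    prog[parent == c, j] = rng.choice(members[:, j], size=n_progeny)
            pl, _ = _kmeans(prog, k, seed=seed + b + 1, n_init=n_init)
            same_parent = parent[:, None] == parent[None, :]
            same_child = pl[:, None] == pl[None, :]
            iu = np.triu_indices(len(parent), 1)
            within = same_child[iu][same_parent[iu]].mean()
            between = same_child[iu][~same_parent[iu]].mean()
            scores.append(within - between)
        rows.append((k, float(np.mean(scores))))
    return pd.DataFrame(rows, columns=["k", "stability"]).set_index("k")


def select_k(submatrix: np.ndarray | pd.DataFrame, k_range: Sequence[int] = range(1, 9),
             n_refs: int = 50, seed: int = 0, method: str = "gap",
             n_init: int = 10) -> tuple[int, pd.DataFrame]:
    """Choose the number of patient clusters for one PFG.

    Default criterion is the gap statistic; ``method='progeny'``
    switches to the progeny-stability score (argmax over k >= 2 unless
    no k beats instability 0).  Degenerate (zero-variance) input yields
    k=1 with a warning.
    """
    X = np.asarray(submatrix, dtype=float)
    ks = sorted(set(map(int, k_range)))
    if not ks or ks[0] < 1 or ks[-1] >= len(X):
        raise DataError("k_range must lie within [1, n_patients)")
    if np.allclose(X.var(axis=0), 0.0):
        warnings.warn("zero-variance submatrix; selecting k=1")
        diag = pd.DataFrame({"log_w": np.nan, "gap": np.nan, "se": np.nan}, index=ks)
        return 1, diag
    if method == "progeny":
        diag = progeny_stability(X, ks, n_refs=max(10, n_refs // 2), seed=seed,
                                 n_init=n_init)
        k_sel = int(diag["stability"].idxmax())
        return k_sel, diag
    if method != "gap":
        raise DataError(f"unknown k-selection method {method!r}")
    diag = gap_statistic(X, ks, n_refs=n_refs, seed=seed, n_init=n_init)
    k_sel = None
    for i, k in enumerate(ks[:-1]):
        nxt = ks[i + 1]
        if diag.at[k, "gap"] >= diag.at[nxt, "gap"] - diag.at[nxt, "se"]:
            k_sel = k
            break
    if k_sel is None:
        k_sel = int(diag["gap"].idxmax())
    return int(k_sel), diag


def _canonical_relabel(labels: np.ndarray, centers: np.ndarray):
    """Renumber clusters 1..k by descending size (ties: centroid lexicographic)."""
    k = centers.shape[0]
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], tuple(centers[c])))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[labels], centers[order]


def cluster_pfg(submatrix: pd.DataFrame, k: int, seed: int = 0,
                n_init: int = 10) -> tuple[pd.Series, np.ndarray]:
    """k-means with restarts and canonical 1..k label numbering."""
    X = np.asarray(submatrix, dtype=float)
    if k < 1:
        raise DataError("k must be >= 1")
    if k > len(X):
        raise DataError(f"k={k} exceeds number of patients {len(X)}")
    lab0, cen0 = _kmeans(X, k, seed=seed, n_init=n_init)
    lab, cen = _canonical_relabel(lab0, cen0)
    index = submatrix.index if isinstance(submatrix, pd.DataFrame) else pd.RangeIndex(len(X))
    return pd.Series(lab, index=index, name="cluster"), cen


def label_normal_like(model: PFGClusterModel, patient_submatrix: pd.DataFrame,
                      controls_submatrix: pd.DataFrame,
                      mahalanobis_q: float = 0.95) -> PFGClusterModel:
    """Flag clusters whose expression the CD19+ controls resemble.

    Controls are projected into the PFG's PCA space and classified by an
    LDA trained on the patient cluster labels; a cluster is normal-like
    iff at least one control is assigned to it.  With a single cluster
    there is nothing to discriminate, so the cluster is flagged iff the
    controls fall inside its ``mahalanobis_q`` chi-square contour.
    """
    if len(controls_submatrix) < 1:
        raise DataError("label_normal_like requires >= 1 control sample")
    k = model.k_selected
    Xp = np.asarray(patient_submatrix, dtype=float)
    Xc = np.asarray(controls_submatrix, dtype=float)
    if k == 1:
        mu = Xp.mean(axis=0)
        cov = np.cov(Xp, rowvar=False) + 1e-6 * np.eye(Xp.shape[1])
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ij,jk,ik->i", Xc - mu, inv, Xc - mu)
        thresh = stats.chi2.ppf(mahalanobis_q, df=Xp.shape[1])
        inside = d2 <= thresh
        model.normal_like_flags = {1: bool(inside.any())}
        model.control_assignments = pd.Series(
            np.where(inside, 1, 0), index=controls_submatrix.index, name="cluster")
        return model
    n_comp = min(Xp.shape[1], max(2, k - 1), len(Xp) - 1)
    pca = PCA(n_components=n_comp, random_state=0).fit(Xp)
    Zp, Zc = pca.transform(Xp), pca.transform(Xc)
    lda = LinearDiscriminantAnalysis()
    lda.fit(Zp, model.labels.to_numpy())
    assign = lda.predict(Zc)
    model.control_assignments = pd.Series(assign, index=controls_submatrix.index,
                                          name="cluster")
    model.normal_like_flags = {c: bool((assign == c).any()) for c in range(1, k + 1)}
    return model


@dataclass
class PFGParams:
    """Stage parameters for :func:`cluster_all_pfgs`."""

    k_range: Sequence[int] = tuple(range(1, 9))
    n_refs: int = 50
    n_init: int = 10
    seed: int = 0
    method: str = "gap"


def cluster_all_pfgs(m: ExpressionMatrix, pfg_defs: Sequence[PFGDefinition],
                     params: PFGParams | None = None
                     ) -> tuple[list[PFGClusterModel], pd.DataFrame]:
    """Run select_k + cluster + normal-like labeling for every PFG.

    Returns the fitted models and the one-hot patient x pattern binary
    matrix (total columns = sum of selected k).  Controls (flagged in
    ``sample_meta``) are excluded from clustering and used only for
    normal-like labeling.
    """
    params = params or PFGParams()
    ctrl_ids = m.control_ids()
    pat = m.patients()
    models: list[PFGClusterModel] = []
    blocks: list[pd.DataFrame] = []
    for i, d in enumerate(pfg_defs):
        missing = [p for p in d.member_protein_ids if p not in m.values.columns]
        if missing:
            raise DataError(f"PFG {d.pfg_name!r}: proteins not in matrix: {missing}")
        sub = pat.values[d.member_protein_ids]
        try:
            kr = [k for k in params.k_range if k < len(sub)]
            k_sel, diag = select_k(sub, kr, n_refs=params.n_refs,
                                   seed=params.seed + i, method=params.method,
                                   n_init=params.n_init)
            labels, centroids = cluster_pfg(sub, k_sel, seed=params.seed + i,
                                            n_init=params.n_init)
        except Exception as exc:
            raise DataError(f"PFG {d.pfg_name!r}: {exc}") from exc
        model = PFGClusterModel(pfg_name=d.pfg_name, k_selected=k_sel,
                                centroids=centroids, labels=labels,
                                k_diagnostics=diag)
        if ctrl_ids:
            model = label_normal_like(model, sub, m.values.loc[ctrl_ids,
                                                               d.member_protein_ids])
        logger.info("PFG %s: k=%d, normal-like=%s", d.pfg_name, k_sel,
                    sorted(c for c, f in model.normal_like_flags.items() if f))
        models.append(model)
        cols = [f"{d.pfg_name}|C{j}" for j in range(1, k_sel + 1)]
        onehot = pd.DataFrame(np.eye(k_sel, dtype=int)[labels.to_numpy() - 1],
                              index=labels.index, columns=cols)
        blocks.append(onehot)
    if not blocks:
        return [], pd.DataFrame(index=pat.values.index)
    return models, pd.concat(blocks, axis=1)
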
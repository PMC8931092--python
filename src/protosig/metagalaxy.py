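"""Block co-clustering of the binary patient x pattern matrix.

The per-PFG cluster memberships are one-hot encoded into a binary
patients x patterns matrix (1 = the patient belongs to that expression
pattern).  A Bernoulli latent block model is fitted by classification
EM: rows (patients) are partitioned into R *signatures* and columns
(patterns) into C *constellations*, with a constant Bernoulli fill rate
per (signature, constellation) block.  The number of signatures and
constellations is selected by maximizing a chi-square-style score over
a grid of (R, C): with O_rc the observed count of ones in block (r, c)
and E_rc the independence expectation
``E_rc = (total ones in constellation c) * (patients in signature r) / n``,
the score is ``sum_rc (O_rc - E_rc)^2 / E_rc`` — large when the fitted
blocks deviate strongly from a structureless fill.  Signatures are
finally merged into a small number of signature groups by hierarchical
clustering of their constellation-prevalence profiles, with an
outcome-similarity check reported alongside.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .rppa import DataError

logger = logging.getLogger(__name__)

_EPS = 1e-9


def build_pattern_matrix(models) -> pd.DataFrame:
    """One-hot encode PFG cluster models into the binary pattern matrix.

    Column order is grouped by PFG then cluster index; within each PFG's
    column block every row sums to exactly one.
    """
    if not models:
        raise DataError("no PFG models supplied")
    index = models[0].labels.index
    blocks = []
    for model in models:
        if not model.labels.index.equals(index):
            extra = index.symmetric_difference(model.labels.index)
            raise DataError(
                f"PFG {model.pfg_name!r}: patient sets differ (e.g. {list(extra)[:5]})")
        k = model.k_selected
        cols = [f"{model.pfg_name}|C{j}" for j in range(1, k + 1)]
        onehot = pd.DataFrame(np.eye(k, dtype=int)[model.labels.to_numpy() - 1],
                              index=index, columns=cols)
        blocks.append(onehot)
    return pd.concat(blocks, axis=1)


@dataclass
class BlockModel:
    """A fitted Bernoulli latent block model of the pattern matrix."""

    R: int
    C: int
    row_labels: pd.Series       # patient -> signature 1..R
    col_labels: pd.Series       # pattern -> constellation 1..C
    block_rates: np.ndarray     # R x C mean fill
    O: np.ndarray               # R x C observed ones per block
    E: np.ndarray               # R x C expected ones (independence)
    score: float
    loglik: float
    seed: int
    n_restarts: int
    loglik_trace: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "R": self.R, "C": self.C,
            "row_labels": {k: int(v) for k, v in self.row_labels.items()},
            "col_labels": {k: int(v) for k, v in self.col_labels.items()},
            "block_rates": self.block_rates.tolist(),
            "score": self.score, "loglik": self.loglik,
            "seed": self.seed, "n_restarts": self.n_restarts,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _loglik(Y: np.ndarray, z: np.ndarray, w: np.ndarray, P: np.ndarray) -> float:
    Pz = np.clip(P, _EPS, 1 - _EPS)
    lp, lq = np.log(Pz), np.log1p(-Pz)
    # sum over cells via block counts
    ones = _block_counts(Y, z, w, P.shape[0], P.shape[1])
    sizes = (np.bincount(z, minlength=P.shape[0])[:, None]
             * np.bincount(w, minlength=P.shape[1])[None, :])
    return float((ones * lp + (sizes - ones) * lq).sum())


def _block_counts(Y: np.ndarray, z: np.ndarray, w: np.ndarray, R: int, C: int) -> np.ndarray:
    Zr = np.zeros((len(z), R))
    Zr[np.arange(len(z)), z] = 1.0
    Wc = np.zeros((len(w), C))
    Wc[np.arange(len(w)), w] = 1.0
    return Zr.T @ Y @ Wc


def _update_rates(Y, z, w, R, C) -> np.ndarray:
    ones = _block_counts(Y, z, w, R, C)
    sizes = (np.bincount(z, minlength=R)[:, None] *
             np.bincount(w, minlength=C)[None, :])
    with np.errstate(invalid="ignore"):
        P = np.where(sizes > 0, ones / np.maximum(sizes, 1), Y.mean())
    return P


def _assign_rows(Y, w, P) -> np.ndarray:
    """Best signature per row given column labels and block rates."""
    R, C = P.shape
    Pz = np.clip(P, _EPS, 1 - _EPS)
    S = Y @ np.eye(C)[w]                      # n x C: ones per column block
    m = np.bincount(w, minlength=C).astype(float)
    scores = S @ np.log(Pz / (1 - Pz)).T + np.log1p(-Pz) @ m
    return scores.argmax(axis=1)


def _assign_cols(Y, z, P) -> np.ndarray:
    return _assign_rows(Y.T, z, P.T)


def _repair_empty(labels: np.ndarray, n_clusters: int, fit_scores: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Refill empty clusters by splitting the largest: move its worst-fitting half."""
    counts = np.bincount(labels, minlength=n_clusters)
    for c in np.flatnonzero(counts == 0):
        big = int(np.argmax(np.bincount(labels, minlength=n_clusters)))
        members = np.flatnonzero(labels == big)
        if len(members) < 2:
            continue
        order = members[np.argsort(fit_scores[members])]
        labels[order[: len(order) // 2]] = c
    return labels


def fit_block_model(pm: pd.DataFrame, R: int, C: int, n_restarts: int = 10,
                    seed: int = 0, max_sweeps: int = 200) -> BlockModel:
    """Fit the Bernoulli latent block model by classification EM.

    Alternates: assign each row to the best signature given column
    blocks and rates; assign columns likewise; re-estimate block rates;
    until labels converge or ``max_sweeps``.  The best of ``n_restarts``
    random initializations by log-likelihood is kept.  Deterministic
    given ``seed``.  The classification log-likelihood is non-decreasing
    across sweeps (asserted) except immediately after an empty-cluster
    repair.
    """
    Y = np.asarray(pm, dtype=float)
    n, p = Y.shape
    if not (1 <= R <= n):
        raise DataError(f"R={R} out of range [1, {n}]")
    if not (1 <= C <= p):
        raise DataError(f"C={C} out of range [1, {p}]")
    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng((seed, restart))
        z = rng.integers(0, R, size=n)
        w = rng.integers(0, C, size=p)
        P = _update_rates(Y, z, w, R, C)
        prev_ll = -np.inf
        trace = []
        for _ in range(max_sweeps):
            repaired = False
            z_new = _assign_rows(Y, w, P)
            if len(np.unique(z_new)) < R:
                z_new = _repair_empty(z_new, R, np.zeros(n), rng)
                repaired = True
            P = _update_rates(Y, z_new, w, R, C)
            w_new = _assign_cols(Y, z_new, P)
            if len(np.unique(w_new)) < C:
                w_new = _repair_empty(w_new, C, np.zeros(p), rng)
                repaired = True
            P = _update_rates(Y, z_new, w_new, R, C)
            ll = _loglik(Y, z_new, w_new, P)
            trace.append(ll)
            if not repaired and ll < prev_ll - 1e-6:
                raise AssertionError(
                    f"CEM log-likelihood decreased: {prev_ll} -> {ll}")
            converged = np.array_equal(z_new, z) and np.array_equal(w_new, w)
            z, w = z_new, w_new
            if converged and not repaired:
                break
            prev_ll = ll if not repaired else -np.inf
        ll = _loglik(Y, z, w, P)
        if best is None or ll > best[0]:
            best = (ll, z.copy(), w.copy(), P.copy(), trace)
    ll, z, w, P, trace = best
    O = _block_counts(Y, z, w, R, C)
    model = BlockModel(
        R=R, C=C,
        row_labels=pd.Series(z + 1, index=pm.index, name="signature"),
        col_labels=pd.Series(w + 1, index=pm.columns, name="constellation"),
        block_rates=P, O=O, E=np.zeros_like(O), score=0.0, loglik=ll,
        seed=seed, n_restarts=n_restarts, loglik_trace=trace)
    model.E = expected_counts(model)
    model.score = selection_score(model)
    return model


def expected_counts(bm: BlockModel, literal_division: bool = False) -> np.ndarray:
    """Independence expectation per block.

    Default: ``E_rc = (total ones in constellation c) * (n_r / n)`` —
    the standard contingency-table expectation, so the selection score
    is a Pearson chi-square of the collapsed R x C count table.  The
    ``literal_division`` variant ``E_rc = (constellation total) / (n_r / n)``
    is retained for comparison only.
    """
    col_tot = bm.O.sum(axis=0)                      # ones per constellation
    n_r = np.bincount(bm.row_labels.to_numpy() - 1, minlength=bm.R).astype(float)
    prop = n_r / n_r.sum()
    if literal_division:
        with np.errstate(divide="ignore"):
            return col_tot[None, :] / np.where(prop[:, None] > 0, prop[:, None], np.nan)
    return col_tot[None, :] * prop[:, None]


def selection_score(bm: BlockModel, literal_division: bool = False) -> float:
    """Chi-square-style block selection statistic sum_rc (O-E)^2 / E.

    Boxes with zero expectation are excluded with a warning (their
    count logged).  Pure function of the fitted partition; invariant to
    relabeling of signatures and constellations.
    """
    E = expected_counts(bm, literal_division=literal_division)
    O = bm.O
    mask = E > 0
    n_zero = int((~mask).sum())
    if n_zero:
        warnings.warn(f"selection_score: {n_zero} zero-expectation boxes excluded")
        logger.info("selection_score excluded %d zero-E boxes", n_zero)
    return float((((O - E) ** 2)[mask] / E[mask]).sum())


def search_grid(pm: pd.DataFrame, R_range: Sequence[int] = range(9, 16),
                C_range: Sequence[int] = range(9, 18), n_restarts: int = 10,
                seed: int = 0, criterion: str = "penalized"
                ) -> tuple[BlockModel, pd.DataFrame]:
    """Fit every (R, C) pair and return the selected model plus the score grid.

    The default ranges (signatures 9-15, constellations 9-17) span 63
    combinations.  The returned grid always holds the raw chi-square
    selection score.  Model choice uses ``criterion``:

    * ``"penalized"`` (default): argmax of
      ``score - 2 log(n*p) * (R-1)(C-1)``.  The raw score is inflated
      by classification EM's adaptively chosen partitions and is
      therefore monotone in (R, C); charging each additional block
      degree of freedom ``2 log(n*p)`` — the usual risk-inflation rate
      for a parameter selected among ~n*p candidates — makes the
      criterion peak at planted structure in recovery experiments.
    * ``"raw"``: argmax of the raw score.

    Ties are broken toward smaller R+C, then smaller R.
    """
    R_range = sorted(set(map(int, R_range)))
    C_range = sorted(set(map(int, C_range)))
    if not R_range or not C_range:
        raise DataError("empty R or C range")
    if criterion not in ("penalized", "raw"):
        raise DataError(f"unknown criterion {criterion!r}")
    n, p = pm.shape
    lam = 2.0 * np.log(n * p) if criterion == "penalized" else 0.0
    grid = pd.DataFrame(np.nan, index=pd.Index(R_range, name="R"),
                        columns=pd.Index(C_range, name="C"))
    best_model, best_key = None, None
    for R, C in itertools.product(R_range, C_range):
        bm = fit_block_model(pm, R, C, n_restarts=n_restarts, seed=seed)
        grid.loc[R, C] = bm.score
        val = bm.score - lam * (R - 1) * (C - 1)
        key = (-val, R + C, R)
        if best_key is None or key < best_key:
            best_key, best_model = key, bm
    return best_model, grid


@dataclass
class SignatureGroupMap:
    """Mapping signature -> group label, with the merge method recorded."""

    mapping: dict[int, str]
    method: str
    linkage: np.ndarray | None = None
    outcome_flags: pd.DataFrame | None = None

    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for sig, g in self.mapping.items():
            out.setdefault(g, []).append(sig)
        return out

    def patient_groups(self, row_labels: pd.Series) -> pd.Series:
        return row_labels.map(self.mapping).rename("signature_group")


def _group_letters(n: int) -> list[str]:
    letters = []
    for i in range(n):
        s, j = "", i
        while True:
            s = chr(ord("A") + j % 26) + s
            j = j // 26 - 1
            if j < 0:
                break
        letters.append(s)
    return letters


def merge_signatures_to_groups(bm: BlockModel, n_groups: int,
                               clinical: pd.DataFrame | None = None,
                               endpoint: str = "OS", merge_alpha: float = 0.05,
                               manual_map: dict[int, str] | None = None
                               ) -> SignatureGroupMap:
    """Merge signatures into signature groups A, B, C, ...

    Default procedure: average-linkage hierarchical clustering of the
    signatures on their constellation-prevalence profiles (per-signature
    mean block fill per constellation, Euclidean distance), cut at
    ``n_groups``.  Groups are lettered by ascending smallest member
    signature.  When a clinical table with ``{endpoint}_time/_event`` is
    supplied, each within-group signature pair is checked with a
    log-rank test; pairs with p < ``merge_alpha`` are flagged for review
    (reported, not enforced).  A ``manual_map`` overrides everything.
    """
    if manual_map is not None:
        if len(manual_map) != bm.R:
            raise DataError("manual map must cover every signature")
        return SignatureGroupMap(mapping=dict(manual_map), method="manual")
    if n_groups > bm.R:
        raise DataError(f"requested {n_groups} groups for {bm.R} signatures")
    profiles = bm.block_rates  # R x C prevalence profiles
    if bm.R == 1:
        return SignatureGroupMap(mapping={1: "A"}, method="single-signature")
    Z = hierarchy.linkage(pdist(profiles, metric="euclidean"), method="average")
    cut = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    # letter groups by smallest member signature for stable naming
    order = sorted(set(cut), key=lambda g: min(np.flatnonzero(cut == g)))
    letters = _group_letters(len(order))
    relabel = {g: letters[i] for i, g in enumerate(order)}
    mapping = {sig: relabel[cut[sig - 1]] for sig in range(1, bm.R + 1)}
    flags = None
    if clinical is not None:
        from .survival import logrank  # local import to avoid a cycle
        rows = []
        pat_groups = bm.row_labels.map(mapping)
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        for g, members in SignatureGroupMap(mapping, "tmp").groups().items():
            for a, b in itertools.combinations(sorted(members), 2):
                ids = bm.row_labels.index[bm.row_labels.isin([a, b])]
                ids = ids.intersection(clinical.index)
                if len(ids) < 4:
                    continue
                sub = clinical.loc[ids]
                labels = bm.row_labels.loc[ids]
                if labels.nunique() < 2 or sub[ecol].sum() < 2:
                    continue
                res = logrank(sub[tcol], sub[ecol], labels)
                rows.append((g, a, b, res.p, res.p < merge_alpha))
        flags = pd.DataFrame(rows, columns=["group", "sig_a", "sig_b", "p", "flagged"])
    return SignatureGroupMap(mapping=mapping, method="average-linkage", linkage=Z,
                             outcome_flags=flags)
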
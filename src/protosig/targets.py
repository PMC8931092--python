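"""Therapeutic-target discovery and the reduced protein classifier.

Two downstream layers over the signature-group assignment:

* differential expression of each signature group versus the CD19+
  control samples (one-way ANOVA across groups + controls, then Tukey
  honest-significant-difference contrasts of each group against the
  controls), yielding per-group up/down target lists;
* a random-forest classifier reduced to a small protein panel
  (permutation-importance ranking, refit, out-of-bag confusion), plus a
  survival comparison of correctly classified versus misclassified
  patients within each true group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .rppa import DataError, ExpressionMatrix
from .survival import km_fit, logrank

logger = logging.getLogger(__name__)

CONTROL_GROUP = "__control__"


@dataclass
class DifferentialResult:
    protein_id: str
    signature_group: str
    direction: str              # "up" / "down" relative to controls
    anova_p: float
    tukey_p: float
    effect: float               # median(group) - median(controls), log2 units


def differential_vs_controls(m: ExpressionMatrix, group_labels: pd.Series,
                             control_ids: list[str] | None = None,
                             alpha: float = 0.05) -> list[DifferentialResult]:
    """Per-protein ANOVA + Tukey HSD of each signature group vs controls.

    Returns contrasts with Tukey-adjusted p < ``alpha``; the direction is
    the sign of the median log2 difference from the controls.
    Zero-variance proteins are skipped with a log entry; groups with a
    single sample raise an error naming the group.
    """
    if control_ids is None:
        control_ids = m.control_ids()
    if not control_ids:
        raise DataError("differential_vs_controls: no control samples")
    group_labels = group_labels.astype(str)
    groups = sorted(group_labels.unique())
    if len(groups) < 2:
        raise DataError("need >= 2 signature groups")
    cells = {g: list(group_labels.index[group_labels == g]) for g in groups}
    cells[CONTROL_GROUP] = list(control_ids)
    for g, ids in cells.items():
        if len(ids) < 2:
            name = "controls" if g == CONTROL_GROUP else g
            raise DataError(f"group {name!r} has fewer than 2 samples")
    order = groups + [CONTROL_GROUP]
    results: list[DifferentialResult] = []
    for prot in m.protein_ids:
        samples = [m.values.loc[cells[g], prot].dropna().to_numpy() for g in order]
        if any(len(s) < 2 for s in samples):
            continue
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            logger.info("protein %s zero-variance; skipped", prot)
            continue
        try:
            _, anova_p = stats.f_oneway(*samples)
        except Exception:
            continue
        tk = stats.tukey_hsd(*samples)
        ci = len(order) - 1  # index of the control sample set
        ctrl_med = np.median(samples[ci])
        for gi, g in enumerate(groups):
            p_adj = float(tk.pvalue[gi, ci])
            if not np.isfinite(p_adj) or p_adj >= alpha:
                continue
            effect = float(np.median(samples[gi]) - ctrl_med)
            results.append(DifferentialResult(
                protein_id=prot, signature_group=g,
                direction="up" if effect > 0 else "down",
                anova_p=float(anova_p), tukey_p=p_adj, effect=effect))
    return results


def target_lists(results: list[DifferentialResult]) -> dict[str, pd.DataFrame]:
    """Per-group table of up/down proteins, sorted by adjusted p."""
    out: dict[str, pd.DataFrame] = {}
    by_group: dict[str, list[DifferentialResult]] = {}
    for r in results:
        by_group.setdefault(r.signature_group, []).append(r)
    for g, rs in by_group.items():
        out[g] = pd.DataFrame(
            [(r.protein_id, r.direction, r.anova_p, r.tukey_p, r.effect) for r in rs],
            columns=["protein_id", "direction", "anova_p", "tukey_p", "effect"],
        ).sort_values("tukey_p").reset_index(drop=True)
    return out


def oob_permutation_importance(rf: RandomForestClassifier, X: np.ndarray,
                               y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Per-tree out-of-bag permutation importance (mean decrease accuracy).

    For every tree, its OOB accuracy is compared with the accuracy after
    permuting one feature at a time (only features the tree actually
    splits on; the others cannot change its predictions).  Averaging the
    drop over trees credits each member of a redundant feature set,
    unlike whole-forest permutation where the remaining copies mask the
    permuted one.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    # individual trees predict class indices, not the original labels
    y_enc = np.searchsorted(rf.classes_, y).astype(float)
    imp = np.zeros(X.shape[1])
    for tree in rf.estimators_:
        # reproduce sklearn's bootstrap draw for this tree
        rs = np.random.RandomState(tree.random_state)
        boot = rs.randint(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0:
            continue
        Xo, yo = X[oob], y_enc[oob]
        base = (tree.predict(Xo) == yo).mean()
        used = np.unique(tree.tree_.feature)
        for j in used[used >= 0]:
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            imp[j] += base - (tree.predict(Xp) == yo).mean()
    return imp / len(rf.estimators_)


@dataclass
class ClassifierReport:
    selected_protein_ids: list[str]
    importances: pd.Series
    confusion: pd.DataFrame        # OOB confusion, rows = true groups
    per_group_recall: pd.Series
    error_rate: float              # overall OOB error of the reduced panel
    oob_predictions: pd.Series
    model: RandomForestClassifier = field(repr=False, default=None)


def select_classifier(m: ExpressionMatrix, group_labels: pd.Series,
                      n_proteins: int = 30, seed: int = 0,
                      n_estimators: int = 500) -> ClassifierReport:
    """Reduce the proteome to a small classifying panel with a random forest.

    A forest over all proteins is ranked by out-of-bag permutation
    importance (mean decrease in per-tree OOB accuracy); the top
    ``n_proteins`` are kept and the forest refitted on them.  The
    report's confusion matrix, recalls and error rate are out-of-bag
    (each sample predicted only by trees that did not train on it), the
    honest error of the reduced panel.  Deterministic given ``seed``.
    """
    ids = group_labels.index.intersection(m.values.index)
    X = m.values.loc[ids]
    y = group_labels.loc[ids].astype(str)
    if y.nunique() < 2:
        raise DataError("need >= 2 groups to classify")
    if n_proteins > X.shape[1]:
        raise DataError(f"n_proteins={n_proteins} exceeds available {X.shape[1]}")
    # stable under column reordering: sort features by name before fitting
    X = X[sorted(X.columns)]
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                oob_score=True)
    rf.fit(X.to_numpy(), y.to_numpy())
    imp = oob_permutation_importance(rf, X.to_numpy(), y.to_numpy(), seed=seed)
    importances = pd.Series(imp, index=X.columns)
    selected = list(importances.sort_values(ascending=False).index[:n_proteins])
    selected_sorted = sorted(selected)
    rf2 = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                 oob_score=True)
    rf2.fit(X[selected_sorted].to_numpy(), y.to_numpy())
    classes = rf2.classes_
    oob = pd.Series(classes[np.argmax(rf2.oob_decision_function_, axis=1)],
                    index=ids, name="oob_prediction")
    confusion = pd.crosstab(y, oob).reindex(index=classes, columns=classes,
                                            fill_value=0)
    recall = pd.Series(np.diag(confusion) / confusion.sum(axis=1), index=classes)
    err = float((oob != y).mean())
    return ClassifierReport(selected_protein_ids=selected,
                            importances=importances.sort_values(ascending=False),
                            confusion=confusion, per_group_recall=recall,
                            error_rate=err, oob_predictions=oob, model=rf2)


@dataclass
class MisclassificationResult:
    group: str
    evaluable: bool
    n_correct: int
    n_misclassified: int
    logrank_p: float = np.nan
    median_correct: float = np.nan
    median_misclassified: float = np.nan
    differential: pd.DataFrame | None = None


def misclassification_survival(m: ExpressionMatrix, group_labels: pd.Series,
                               predictions: pd.Series, clinical: pd.DataFrame,
                               endpoint: str = "OS",
                               alpha: float = 0.05) -> list[MisclassificationResult]:
    """Compare outcomes of correctly vs misclassified patients per true group.

    Within each true group: a log-rank test and KM medians for correct vs
    misclassified, plus per-protein differential expression between the
    two subsets (Welch t-test, BH across proteins).  Groups without
    misclassified patients are flagged not evaluable.
    """
    if predictions.empty:
        raise DataError("empty predictions")
    ids = group_labels.index.intersection(predictions.index).intersection(clinical.index)
    if len(ids) == 0:
        raise DataError("no overlap between labels, predictions and clinical table")
    y = group_labels.loc[ids].astype(str)
    yhat = predictions.loc[ids].astype(str)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    results = []
    for g in sorted(y.unique()):
        members = ids[y == g]
        correct = members[yhat.loc[members] == g]
        wrong = members[yhat.loc[members] != g]
        if len(wrong) == 0 or len(correct) == 0:
            results.append(MisclassificationResult(
                group=g, evaluable=False, n_correct=len(correct),
                n_misclassified=len(wrong)))
            continue
        lab = pd.Series(np.where(yhat.loc[members] == g, "correct", "misclassified"),
                        index=members)
        try:
            lr_p = logrank(clinical.loc[members, tcol],
                           clinical.loc[members, ecol].astype(int), lab).p
        except DataError:
            lr_p = np.nan
        med_c = km_fit(clinical.loc[correct, tcol],
                       clinical.loc[correct, ecol].astype(int)).median
        med_w = km_fit(clinical.loc[wrong, tcol],
                       clinical.loc[wrong, ecol].astype(int)).median
        de = None
        if len(correct) >= 2 and len(wrong) >= 2:
            rows = []
            for prot in m.protein_ids:
                a = m.values.loc[correct, prot].dropna()
                b = m.values.loc[wrong, prot].dropna()
                if len(a) < 2 or len(b) < 2 or (a.var() == 0 and b.var() == 0):
                    continue
                _, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append((prot, float(p), float(a.median() - b.median())))
            de = pd.DataFrame(rows, columns=["protein_id", "p", "effect"])
            if len(de):
                de["q"] = multipletests(de["p"], method="fdr_bh")[1]
                de = de[de["q"] < alpha].sort_values("q").reset_index(drop=True)
        results.append(MisclassificationResult(
            group=g, evaluable=True, n_correct=len(correct),
            n_misclassified=len(wrong), logrank_p=lr_p,
            median_correct=med_c, median_misclassified=med_w, differential=de))
    return results
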
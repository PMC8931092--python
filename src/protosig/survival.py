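"""Outcome analytics: KM / log-rank / Cox layers, protein screening with
resampled cutpoint-model validation, CLL-IPI, nested stratification, and
the Watch-and-Wait three-protein score.

Conventions
-----------
* Times are in years; event indicators are 1 = event observed,
  0 = censored, everywhere.
* Endpoints are named ``OS`` (overall survival), ``TTFT`` (time to first
  treatment) and ``TTST`` (time to second treatment); a clinical table
  carries ``{endpoint}_time`` / ``{endpoint}_event`` columns.
* Ties in Cox partial likelihood use the Efron approximation
  (lifelines' default).
* Multiple testing across proteins uses Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rppa import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

FORMS = ("median", "tertile", "sextile", "continuous")
_FORM_Q = {"median": 2, "tertile": 3, "sextile": 6}


# ---------------------------------------------------------------------------
# core engines

@dataclass
class KMResult:
    fitter: KaplanMeierFitter
    median: float            # NaN when S(t) never reaches 0.5
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        return float(self.fitter.predict(t))


def km_fit(times: Sequence[float], events: Sequence[int], label: str = "KM") -> KMResult:
    """Product-limit survival estimate with median and its 95% CI."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) < 1:
        raise DataError("km_fit requires at least one observation")
    if np.any(t < 0):
        raise DataError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=label)
    med = float(kmf.median_survival_time_)
    try:
        from lifelines.utils import median_survival_times
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    except Exception:  # pragma: no cover
        lo, hi = np.nan, np.nan
    if not np.isfinite(med):
        med = np.nan
    return KMResult(fitter=kmf, median=med, median_ci=(lo, hi),
                    n=len(t), n_events=int(e.sum()))


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float
    pairwise: pd.DataFrame | None = None   # columns: a, b, p, q (BH)


def logrank(times, events, group_labels) -> LogrankResult:
    """K-sample log-rank test with BH-corrected all-pairs table."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise DataError("logrank requires >= 2 non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    pairwise = None
    if len(levels) > 2:
        rows = []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                mask = (g == levels[i]) | (g == levels[j])
                sub = multivariate_logrank_test(t[mask], g[mask], e[mask])
                rows.append((levels[i], levels[j], float(sub.p_value)))
        pairwise = pd.DataFrame(rows, columns=["a", "b", "p"])
        pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return LogrankResult(statistic=float(res.test_statistic),
                         df=len(levels) - 1, p=float(res.p_value),
                         pairwise=pairwise)


@dataclass
class CoxResult:
    summary: pd.DataFrame | None   # index covariate; HR, ci_lower, ci_upper, p
    c_index: float
    n: int
    n_events: int
    flagged: str | None = None     # reason when the fit is degenerate

    @property
    def ok(self) -> bool:
        return self.flagged is None


def cox_fit(design: pd.DataFrame, times, events, penalizer: float = 0.0) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald CI/p and c-index.

    Degenerate inputs (constant or collinear covariates, separation,
    non-convergence) yield a flagged result rather than an exception.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n_events = int(e.sum())
    if n_events < 1:
        return CoxResult(None, np.nan, len(t), 0, flagged="no events")
    X = design.astype(float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        return CoxResult(None, np.nan, len(t), n_events,
                         flagged=f"constant covariates: {const}")
    if X.shape[1] > 1 and np.linalg.matrix_rank(X - X.mean()) < X.shape[1]:
        return CoxResult(None, np.nan, len(t), n_events, flagged="collinear covariates")
    df = X.copy()
    df["_time"], df["_event"] = t, e
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:
        return CoxResult(None, np.nan, len(t), n_events, flagged=str(exc))
    summ = pd.DataFrame({
        "HR": np.exp(cph.params_),
        "ci_lower": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "ci_upper": np.exp(cph.confidence_intervals_.iloc[:, 1]),
        "p": cph.summary["p"],
    })
    risk = cph.predict_partial_hazard(X).to_numpy().ravel()
    cidx = concordance_index(t, -risk, e)
    return CoxResult(summary=summ, c_index=float(cidx), n=len(t), n_events=n_events)


# ---------------------------------------------------------------------------
# protein-level screening and validation

@dataclass
class ProteinPrognosisResult:
    protein_id: str
    endpoint: str
    per_form: pd.DataFrame          # index form; p, q, c_index, hr
    best_form: str | None
    p: float
    q: float = np.nan
    validation_fraction: float = np.nan
    validated: bool = False
    flagged: str | None = None


def _grouped_labels(x: pd.Series, n_q: int, cutpoints: np.ndarray | None = None):
    """Quantile-group codes 0..n_q-1; cutpoints may come from training data."""
    if cutpoints is None:
        qs = np.quantile(x, np.linspace(0, 1, n_q + 1)[1:-1])
    else:
        qs = cutpoints
    return np.searchsorted(qs, x, side="right"), qs


def protein_screen(m: ExpressionMatrix, clinical: pd.DataFrame, endpoint: str,
                   forms: Sequence[str] = FORMS, alpha: float = 0.05
                   ) -> list[ProteinPrognosisResult]:
    """Screen every protein for prognosis under four model forms.

    Continuous form: univariate Cox Wald p.  Grouped forms (median /
    tertile / sextile cutpoints): k-sample log-rank p across the
    quantile groups.  BH-FDR is applied across proteins within each
    form; a protein's headline (p, best_form) is its smallest raw p.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in clinical.columns:
        raise DataError(f"clinical table lacks {tcol}")
    ids = m.patients().values.index.intersection(clinical.index)
    expr = m.values.loc[ids]
    clin = clinical.loc[ids]
    t, e = clin[tcol], clin[ecol].astype(int)
    results: list[ProteinPrognosisResult] = []
    if e.sum() == 0:
        for prot in expr.columns:
            results.append(ProteinPrognosisResult(
                protein_id=prot, endpoint=endpoint,
                per_form=pd.DataFrame(), best_form=None, p=np.nan,
                flagged="no events: non-estimable"))
        return results
    for prot in expr.columns:
        x = expr[prot]
        if x.nunique() <= 1:
            logger.info("protein %s constant; skipped", prot)
            results.append(ProteinPrognosisResult(
                protein_id=prot, endpoint=endpoint, per_form=pd.DataFrame(),
                best_form=None, p=np.nan, flagged="constant expression"))
            continue
        rows = {}
        for form in forms:
            if form == "continuous":
                res = cox_fit(pd.DataFrame({prot: x}), t, e)
                if res.ok:
                    rows[form] = (float(res.summary["p"].iloc[0]),
                                  res.c_index, float(res.summary["HR"].iloc[0]))
                else:
                    rows[form] = (np.nan, np.nan, np.nan)
            else:
                codes, _ = _grouped_labels(x, _FORM_Q[form])
                if len(np.unique(codes)) < 2:
                    rows[form] = (np.nan, np.nan, np.nan)
                    continue
                lr = logrank(t, e, codes)
                rows[form] = (lr.p, np.nan, np.nan)
        per_form = pd.DataFrame(rows, index=["p", "c_index", "hr"]).T
        finite = per_form["p"].dropna()
        best = finite.idxmin() if len(finite) else None
        results.append(ProteinPrognosisResult(
            protein_id=prot, endpoint=endpoint, per_form=per_form,
            best_form=best, p=float(finite.min()) if len(finite) else np.nan))
    # BH within each form across proteins
    for form in forms:
        ps, idx = [], []
        for i, r in enumerate(results):
            if r.flagged is None and form in r.per_form.index and \
                    np.isfinite(r.per_form.at[form, "p"]):
                ps.append(r.per_form.at[form, "p"])
                idx.append(i)
        if not ps:
            continue
        qs = multipletests(ps, method="fdr_bh")[1]
        for i, q in zip(idx, qs):
            results[i].per_form.at[form, "q"] = q
    for r in results:
        if r.best_form is not None and "q" in r.per_form.columns:
            r.q = float(r.per_form.at[r.best_form, "q"])
    return results


def screen_counts(results: list[ProteinPrognosisResult], threshold: float = 0.05,
                  on: str = "p") -> dict[str, int]:
    """Number of proteins under ``threshold`` per form (raw p or BH q)."""
    counts: dict[str, int] = {}
    for form in FORMS:
        c = 0
        for r in results:
            if r.flagged is not None or form not in r.per_form.index:
                continue
            v = r.per_form.at[form, on] if on in r.per_form.columns else np.nan
            if np.isfinite(v) and v <= threshold:
                c += 1
        counts[form] = c
    return counts


def iterative_validation(m: ExpressionMatrix, clinical: pd.DataFrame, endpoint: str,
                         protein: str, n_iter: int = 200, train_frac: float = 0.66,
                         seed: int = 0, min_test_events: int = 5,
                         threshold: float = 0.70):
    """Resampled cutpoint-model validation of one protein's prognosis.

    Per iteration: split patients into train (``train_frac``) / test;
    estimate median/tertile/sextile cutpoints on the training split
    only; fit all four Cox forms on train and pick the one with the
    best Harrell c-index; apply the train cutpoints to the test split
    and record whether the protein is significant there (log-rank for
    grouped forms, Cox Wald p for continuous) at p < 0.05.  Returns
    ``(validation_fraction, history)`` where the fraction is the share
    of evaluable iterations that were significant; the protein is
    "validated" when the fraction exceeds ``threshold``.  Iterations
    with fewer than ``min_test_events`` test events are skipped and the
    denominator adjusted.  Deterministic given ``seed``.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    ids = m.patients().values.index.intersection(clinical.index)
    x = m.values.loc[ids, protein]
    t = clinical.loc[ids, tcol].astype(float)
    e = clinical.loc[ids, ecol].astype(int)
    rng = np.random.default_rng(seed)
    n = len(ids)
    n_train = int(round(train_frac * n))
    history = []
    n_sig = n_done = 0
    for it in range(n_iter):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if e.iloc[te].sum() < min_test_events or e.iloc[tr].sum() < min_test_events:
            history.append({"iter": it, "skipped": True})
            logger.info("iteration %d skipped: too few events", it)
            continue
        best_form, best_c, cutpoints = None, -np.inf, {}
        for form in FORMS:
            if form == "continuous":
                design = pd.DataFrame({protein: x.iloc[tr].to_numpy()})
            else:
                codes, qs = _grouped_labels(x.iloc[tr], _FORM_Q[form])
                cutpoints[form] = qs
                if len(np.unique(codes)) < 2:
                    continue
                design = pd.DataFrame({"grp": codes}).astype(float)
            res = cox_fit(design, t.iloc[tr].to_numpy(), e.iloc[tr].to_numpy())
            if res.ok and np.isfinite(res.c_index) and res.c_index > best_c:
                best_c, best_form = res.c_index, form
        if best_form is None:
            history.append({"iter": it, "skipped": True})
            continue
        if best_form == "continuous":
            res = cox_fit(pd.DataFrame({protein: x.iloc[te].to_numpy()}),
                          t.iloc[te].to_numpy(), e.iloc[te].to_numpy())
            p = float(res.summary["p"].iloc[0]) if res.ok else np.nan
        else:
            codes, _ = _grouped_labels(x.iloc[te], _FORM_Q[best_form],
                                       cutpoints=cutpoints[best_form])
            if len(np.unique(codes)) < 2:
                history.append({"iter": it, "skipped": True})
                continue
            p = logrank(t.iloc[te], e.iloc[te], codes).p
        sig = bool(np.isfinite(p) and p < 0.05)
        n_done += 1
        n_sig += sig
        history.append({"iter": it, "skipped": False, "form": best_form,
                        "train_c": best_c, "test_p": p, "significant": sig})
    frac = n_sig / n_done if n_done else np.nan
    return frac, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# clinical indices and stratification

#: published CLL-IPI weights (component -> points)
CLL_IPI_WEIGHTS = {
    "tp53_abnormal": 4,      # del(17p) and/or TP53 mutation
    "ighv_unmutated": 2,
    "b2m_high": 2,           # beta-2-microglobulin > 3.5 mg/L
    "stage_advanced": 1,     # Rai I-IV (or Binet B-C)
    "age_high": 1,           # age > 65 years
}

CLL_IPI_GROUPS = [            # (lo, hi, label), inclusive point ranges
    (0, 1, "low"), (2, 3, "intermediate"), (4, 6, "high"), (7, 10, "very high"),
]


def cll_ipi(clinical: pd.DataFrame, weights: dict[str, int] | None = None
            ) -> pd.DataFrame:
    """CLL International Prognostic Index points and risk group per patient.

    Required columns: ``age``, ``rai_stage``, ``ighv``, ``b2m``,
    ``del17p``.  Patients missing any component are excluded with the
    reason recorded (column ``excluded``).  Risk groups: low 0-1,
    intermediate 2-3, high 4-6, very high 7-10.
    """
    w = dict(CLL_IPI_WEIGHTS if weights is None else weights)
    need = ["age", "rai_stage", "ighv", "b2m", "del17p"]
    missing_cols = [c for c in need if c not in clinical.columns]
    if missing_cols:
        raise DataError(f"clinical table lacks columns: {missing_cols}")
    out = pd.DataFrame(index=clinical.index,
                       columns=["points", "risk_group", "excluded"], dtype=object)
    for pid, row in clinical.iterrows():
        miss = [c for c in need
                if pd.isna(row[c]) or (c == "ighv" and row[c] == "unknown")]
        if miss:
            out.loc[pid] = [np.nan, np.nan, f"missing: {','.join(miss)}"]
            continue
        pts = (w["tp53_abnormal"] * bool(row["del17p"])
               + w["ighv_unmutated"] * (row["ighv"] == "unmutated")
               + w["b2m_high"] * (float(row["b2m"]) > 3.5)
               + w["stage_advanced"] * (int(row["rai_stage"]) >= 1)
               + w["age_high"] * (float(row["age"]) > 65))
        out.loc[pid] = [int(pts), ipi_group(int(pts)), None]
    return out


def ipi_group(points: int) -> str:
    for lo, hi, label in CLL_IPI_GROUPS:
        if lo <= points <= hi:
            return label
    raise DataError(f"CLL-IPI points {points} outside 0-10")


def nested_stratification(groupsA: pd.Series, groupsB: pd.Series,
                          clinical: pd.DataFrame, endpoint: str,
                          min_events: int = 5) -> pd.DataFrame:
    """Within each level of A, log-rank across B (and the transpose).

    BH correction within each direction's family.  Strata with fewer
    than 2 represented B-levels or fewer than ``min_events`` events are
    flagged insufficient.  This is the additivity check: e.g. signature
    groups within each Rai stage, and Rai stages within each signature
    group.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    ids = groupsA.index.intersection(groupsB.index).intersection(clinical.index)
    A, B, clin = groupsA.loc[ids], groupsB.loc[ids], clinical.loc[ids]
    rows = []
    for direction, strat, across in (("B_within_A", A, B), ("A_within_B", B, A)):
        for level in pd.unique(strat):
            mask = strat == level
            sub_t = clin.loc[mask, tcol]
            sub_e = clin.loc[mask, ecol].astype(int)
            sub_g = across[mask]
            if sub_g.nunique() < 2 or sub_e.sum() < min_events:
                rows.append((direction, level, np.nan, np.nan, "insufficient"))
                continue
            try:
                res = logrank(sub_t, sub_e, sub_g)
                rows.append((direction, level, res.statistic, res.p, "ok"))
            except DataError:
                rows.append((direction, level, np.nan, np.nan, "insufficient"))
    tab = pd.DataFrame(rows, columns=["direction", "stratum", "statistic", "p", "status"])
    for direction in tab["direction"].unique():
        mask = (tab["direction"] == direction) & tab["p"].notna()
        if mask.any():
            tab.loc[mask, "q"] = multipletests(tab.loc[mask, "p"], method="fdr_bh")[1]
    return tab


# ---------------------------------------------------------------------------
# Watch-and-Wait three-protein score

#: marker -> adverse direction ("low": adverse when strictly below the
#: cohort median; "high": adverse when at or above it)
WAW_MARKERS = {"ANXA1": "low", "TFRC": "low", "SMAD2.p245": "high"}


@dataclass
class WaWScore:
    adverse_count: pd.Series      # 0..3 per patient
    risk_group: pd.Series         # "0-1" or "2-3"
    excluded: dict[str, str] = field(default_factory=dict)


def waw_score(expr: pd.DataFrame, medians: pd.Series | None = None,
              markers: dict[str, str] | None = None) -> WaWScore:
    """Count adverse marker levels per patient and bin into risk groups.

    The default markers (low ANXA1, low TFRC, high SMAD2.p245) flag
    patients likely to need treatment soon; patients with >= 2 adverse
    levels fall in the "2-3" risk group.  At-median values: "low"
    markers use strict ``<`` (at-median is not adverse), "high" markers
    use ``>=`` (at-median is adverse).  ``medians`` default to the
    cohort medians of ``expr``.
    """
    markers = dict(WAW_MARKERS if markers is None else markers)
    missing = [p for p in markers if p not in expr.columns]
    if missing:
        raise DataError(f"marker proteins not in matrix: {missing}")
    if medians is None:
        medians = expr[list(markers)].median(axis=0)
    excluded: dict[str, str] = {}
    rows = expr.index[~expr[list(markers)].isna().any(axis=1)]
    for pid in expr.index.difference(rows):
        bad = [p for p in markers if pd.isna(expr.at[pid, p])]
        excluded[pid] = f"missing markers: {','.join(bad)}"
    sub = expr.loc[rows, list(markers)]
    count = pd.Series(0, index=rows, dtype=int)
    for prot, direction in markers.items():
        med = float(medians[prot])
        if direction == "low":
            count += (sub[prot] < med).astype(int)
        else:
            count += (sub[prot] >= med).astype(int)
    group = pd.Series(np.where(count >= 2, "2-3", "0-1"), index=rows,
                      name="risk_group")
    return WaWScore(adverse_count=count.rename("adverse_count"),
                    risk_group=group, excluded=excluded)
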
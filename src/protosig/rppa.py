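"""Expression-matrix data model, I/O, normalization and bias screening.

The pipeline's universal currency is a samples x proteins matrix of log2
relative protein expression, as produced by reverse phase protein array
(RPPA) quantification, together with per-sample metadata (diagnosis,
control flag, source organ, preservation, collection interval, therapy
class).  Normalization follows the standard RPPA convention: a single
pass of row-median then column-median centering to make slides
comparable, followed by subtraction of the per-protein median over
normal CD19+ B-cell control samples so that zero means "at the normal
level" and the sign of a patient value reads as above/below normal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MODIFICATION_TYPES = frozenset({"total", "phospho", "cleaved", "methyl"})


class DataError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass
class AntibodyRecord:
    """One antibody of the 'Rosetta' annotation table."""

    antibody_id: str
    target_name: str
    modification: str
    vendor: str = ""
    catalog: str = ""

    def __post_init__(self) -> None:
        if self.modification not in MODIFICATION_TYPES:
            raise DataError(
                f"antibody {self.antibody_id!r}: modification "
                f"{self.modification!r} not in {sorted(MODIFICATION_TYPES)}"
            )


@dataclass
class ExpressionMatrix:
    """Samples x proteins log2 expression with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are protein (antibody)
        ids.  Missing values are permitted on ingest; see
        :func:`prepare_complete` for the downstream completeness policy.
    sample_meta
        DataFrame indexed by sample id.  Recognised columns include
        ``diagnosis``, ``is_control``, ``organ``, ``preservation``,
        ``collection_interval`` and ``therapy_class``; extra columns are
        carried through untouched.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        dup_s = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_s):
            raise DataError(f"duplicate sample ids: {list(dup_s)}")
        dup_p = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_p):
            raise DataError(f"duplicate protein ids: {list(dup_p)}")
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(index=self.values.index)
        unknown = self.values.index.difference(self.sample_meta.index)
        # rows with no metadata are kept but flagged
        self.sample_meta = self.sample_meta.reindex(self.values.index)
        self.sample_meta["_meta_missing"] = False
        if len(unknown):
            self.sample_meta.loc[unknown, "_meta_missing"] = True
            logger.warning("samples with no metadata: %s", list(unknown))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def control_ids(self) -> list[str]:
        if "is_control" not in self.sample_meta.columns:
            return []
        flags = self.sample_meta["is_control"].fillna(False).astype(bool)
        return list(self.sample_meta.index[flags])

    def patients(self) -> "ExpressionMatrix":
        """Sub-matrix of non-control samples."""
        ctrl = set(self.control_ids())
        keep = [s for s in self.sample_ids if s not in ctrl]
        return ExpressionMatrix(self.values.loc[keep], self.sample_meta.loc[keep])


def load_expression(path: str | Path, meta_path: str | Path | None = None,
                    sep: str = "\t") -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (samples in rows, header of protein ids).

    ``meta_path`` points to a table keyed by sample id.  The parse is a
    lossless round trip with :func:`write_expression`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"expression matrix not found: {path}")
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    meta = pd.DataFrame(index=values.index)
    if meta_path is not None:
        meta_path = Path(meta_path)
        if not meta_path.exists():
            raise DataError(f"metadata file not found: {meta_path}")
        meta = pd.read_csv(meta_path, sep=sep, index_col=0)
        meta.index = meta.index.astype(str)
        extra = meta.index.difference(values.index)
        if len(extra):
            raise DataError(f"metadata rows with no matching sample: {list(extra)}")
    return ExpressionMatrix(values, meta)


def write_expression(m: ExpressionMatrix, path: str | Path,
                     meta_path: str | Path | None = None, sep: str = "\t") -> None:
    m.values.to_csv(path, sep=sep, index_label="sample_id")
    if meta_path is not None:
        meta = m.sample_meta.drop(columns=["_meta_missing"], errors="ignore")
        meta.to_csv(meta_path, sep=sep, index_label="sample_id")


def load_rosetta(path: str | Path, sep: str = "\t") -> list[AntibodyRecord]:
    """Read the antibody annotation table (antibody_id, target, modification, ...)."""
    df = pd.read_csv(path, sep=sep)
    required = {"antibody_id", "target", "modification"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"rosetta table missing columns: {sorted(missing)}")
    if df["antibody_id"].duplicated().any():
        dups = df.loc[df["antibody_id"].duplicated(), "antibody_id"].tolist()
        raise DataError(f"duplicate antibody ids: {dups}")
    return [
        AntibodyRecord(
            antibody_id=str(r.antibody_id),
            target_name=str(r.target),
            modification=str(r.modification),
            vendor=str(getattr(r, "vendor", "")),
            catalog=str(getattr(r, "catalog", "")),
        )
        for r in df.itertuples(index=False)
    ]


def median_center(m: ExpressionMatrix, polish: bool = False,
                  max_iter: int = 10, tol: float = 1e-10) -> ExpressionMatrix:
    """Row-median then column-median centering (single pass by default).

    After the pass every column (protein) median is exactly zero; row
    medians after the column pass are attached as a diagnostic in
    ``sample_meta['row_median_residual']``.  With ``polish=True`` the two
    passes are iterated to convergence (Tukey median polish).
    """
    X = m.values
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise DataError("median_center requires at least 2 samples and 2 proteins")
    if X.isna().all(axis=1).any():
        raise DataError("sample with all values missing")
    if X.isna().all(axis=0).any():
        raise DataError("protein with all values missing")
    out = X.copy()
    n_pass = max_iter if polish else 1
    for _ in range(n_pass):
        row_med = out.median(axis=1, skipna=True)
        out = out.sub(row_med, axis=0)
        col_med = out.median(axis=0, skipna=True)
        out = out.sub(col_med, axis=1)
        if polish and float(np.abs(row_med).max()) < tol and float(np.abs(col_med).max()) < tol:
            break
    meta = m.sample_meta.copy()
    meta["row_median_residual"] = out.median(axis=1, skipna=True)
    return ExpressionMatrix(out, meta)


def normalize_to_controls(m: ExpressionMatrix,
                          control_ids: Sequence[str] | None = None) -> ExpressionMatrix:
    """Subtract the per-protein median over control samples.

    Afterwards the per-protein median across the controls is exactly
    zero, so a patient value reads directly as log2 distance from the
    normal B-cell level.
    """
    if control_ids is None:
        control_ids = m.control_ids()
    control_ids = list(control_ids)
    if not control_ids:
        raise DataError("normalize_to_controls: empty control set")
    missing = set(control_ids) - set(m.sample_ids)
    if missing:
        raise DataError(f"control ids not in matrix: {sorted(missing)}")
    if "is_control" in m.sample_meta.columns:
        flags = m.sample_meta.loc[control_ids, "is_control"].fillna(False).astype(bool)
        if not flags.all():
            bad = list(flags.index[~flags])
            raise DataError(f"samples not flagged is_control: {bad}")
    ctrl_median = m.values.loc[control_ids].median(axis=0, skipna=True)
    return ExpressionMatrix(m.values.sub(ctrl_median, axis=1), m.sample_meta.copy())


def prepare_complete(m: ExpressionMatrix, max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Completeness policy for clustering stages.

    Proteins missing in more than ``max_missing_frac`` of samples are
    dropped (logged); remaining missing values are median-imputed per
    protein.
    """
    frac = m.values.isna().mean(axis=0)
    drop = list(frac.index[frac > max_missing_frac])
    if drop:
        logger.info("dropping %d proteins with >%d%% missing: %s",
                    len(drop), int(100 * max_missing_frac), drop)
    vals = m.values.drop(columns=drop)
    vals = vals.fillna(vals.median(axis=0))
    return ExpressionMatrix(vals, m.sample_meta.copy())


@dataclass
class BiasReport:
    """Per-factor bias screen over proteins.

    ``tables`` maps factor name -> DataFrame with per-protein test
    statistic, raw p and BH q; ``flagged`` maps factor -> proteins with
    q < alpha; ``prechecks`` records the Shapiro-Wilk and Levene
    screening that motivates the rank-based test.
    """

    tables: dict[str, pd.DataFrame]
    flagged: dict[str, list[str]]
    skipped: list[str]
    prechecks: dict[str, dict[str, float]]
    alpha: float = 0.05


def qc_bias_screen(m: ExpressionMatrix, factors: Iterable[str],
                   alpha: float = 0.05) -> BiasReport:
    """Screen each protein for association with pre-analytic factors.

    For each factor (e.g. organ, fresh/frozen, therapy class, collection
    interval binned by the caller) a Kruskal-Wallis test is run per
    protein across factor levels, with Shapiro-Wilk normality and Levene
    variance-homogeneity prechecks logged to justify the non-parametric
    choice.  P-values are BH-FDR corrected across proteins within each
    factor; proteins with q < ``alpha`` are flagged.
    """
    tables: dict[str, pd.DataFrame] = {}
    flagged: dict[str, list[str]] = {}
    prechecks: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for factor in factors:
        if factor not in m.sample_meta.columns:
            raise DataError(f"factor {factor!r} not in sample metadata")
        levels = m.sample_meta[factor].dropna()
        uniq = levels.unique()
        if len(uniq) < 2:
            warnings.warn(f"factor {factor!r} has a single level; skipped")
            skipped.append(factor)
            continue
        groups_idx = {lv: levels.index[levels == lv] for lv in uniq}
        # precheck on the pooled first protein: document non-normality/heteroscedasticity
        first = m.values.iloc[:, 0]
        grp_vals = [first.loc[ix].dropna().to_numpy() for ix in groups_idx.values()]
        grp_vals = [g for g in grp_vals if len(g) >= 3]
        pre = {}
        if len(grp_vals) >= 2:
            pooled = np.concatenate(grp_vals)
            if len(pooled) >= 3:
                pre["shapiro_p"] = float(stats.shapiro(pooled[:5000]).pvalue)
            pre["levene_p"] = float(stats.levene(*grp_vals).pvalue)
        prechecks[factor] = pre
        rows = []
        for prot in m.protein_ids:
            col = m.values[prot]
            samples = [col.loc[ix].dropna().to_numpy() for ix in groups_idx.values()]
            samples = [s for s in samples if len(s) >= 2]
            if len(samples) < 2:
                continue
            try:
                stat, p = stats.kruskal(*samples)
            except ValueError:  # all identical values
                stat, p = 0.0, 1.0
            rows.append((prot, stat, p))
        tab = pd.DataFrame(rows, columns=["protein", "statistic", "p"]).set_index("protein")
        tab["q"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
        tables[factor] = tab
        flagged[factor] = list(tab.index[tab["q"] < alpha])
    return BiasReport(tables=tables, flagged=flagged, skipped=skipped,
                      prechecks=prechecks, alpha=alpha)
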
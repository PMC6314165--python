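"""Metabolite-matrix preprocessing and descriptive statistics.

Batch correction divides each raw intensity by its (metabolite, batch) mean,
so corrected values have per-batch mean 1 per metabolite and the operation
is idempotent. Descriptive summaries cover the per-metabolite coefficient of
variation, the four detection classes (both parents / Col-0 only / ddm1-2
only / epiRIL only, the last being the transgressive class), and pairwise
correlation summaries within and between tissues at a configurable
|rho| > 0.2 threshold. Flowering-time correction divides raw-scale trait
values by each line's flowering time.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import DETECTION_CLASSES, MetaboliteMatrix, TraitVector

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CorrelationSummary:
    """Pairwise metabolite correlations between (or within) two matrices."""

    tissue_pair: tuple[str, str]
    matrix: pd.DataFrame
    threshold: float = 0.2
    method: str = "pearson"

    @property
    def fraction_correlated(self) -> float:
        """Fraction of row metabolites with at least one |rho| > threshold partner."""
        m = self.matrix.copy()
        if self.tissue_pair[0] == self.tissue_pair[1]:
            np.fill_diagonal(m.values, np.nan)
        hit = (m.abs() > self.threshold).any(axis=1)
        return float(hit.mean()) if len(hit) else 0.0

    @property
    def fraction_negative(self) -> float:
        """Among pairs with |rho| > threshold, the fraction with rho < -threshold."""
        vals = self.matrix.to_numpy(float)
        if self.tissue_pair[0] == self.tissue_pair[1]:
            iu = np.triu_indices(vals.shape[0], k=1)
            vals = vals[iu]
        else:
            vals = vals.ravel()
        vals = vals[~np.isnan(vals)]
        strong = np.abs(vals) > self.threshold
        if strong.sum() == 0:
            return 0.0
        return float((vals[strong] < -self.threshold).mean())


def batch_correct(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each intensity by its (metabolite, batch) mean.

    Missing values stay missing; a batch in which a metabolite is entirely
    missing keeps its missing values (warning logged). Idempotent to 1e-9.
    """
    vals = m.intensities
    out = vals.copy()
    for b, idx in vals.groupby(m.batch).groups.items():
        sub = vals.loc[idx]
        means = sub.mean(axis=0, skipna=True)
        all_missing = means.isna()
        if all_missing.any():
            logger.warning("batch %s: %d metabolites entirely missing",
                           b, int(all_missing.sum()))
        out.loc[idx] = sub.div(means.where(~all_missing, np.nan), axis=1)
    return MetaboliteMatrix(tissue=m.tissue, intensities=out, batch=m.batch,
                            detection_class=m.detection_class, batch_corrected=True)


def coefficient_of_variation(m: MetaboliteMatrix) -> pd.Series:
    """Per-metabolite CV% = 100 * sample sd / mean on the raw corrected scale.

    Metabolites with fewer than two observations or zero mean are reported
    missing.
    """
    vals = m.intensities
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    n = vals.notna().sum(axis=0)
    cv = 100.0 * sd / mean
    cv[(n < 2) | (mean == 0) | mean.isna()] = np.nan
    cv.name = "cv_percent"
    return cv


def classify_detection(m: MetaboliteMatrix,
                       parent_flags: pd.DataFrame) -> pd.Series:
    """Assign each metabolite to one of the four detection classes.

    ``parent_flags`` has boolean columns ``Col`` and ``ddm1`` per metabolite.
    epiRIL detection means at least one non-missing epiRIL value. Metabolites
    detected nowhere are excluded with a warning. The classes partition all
    detected metabolites: both_parents, col_only, ddm1_only, epiRIL_only
    (absent in both parents -> transgressive).
    """
    det_epiril = m.intensities.notna().any(axis=0)
    out = {}
    for met in m.metabolites:
        col = bool(parent_flags.loc[met, "Col"]) if met in parent_flags.index else False
        dd = bool(parent_flags.loc[met, "ddm1"]) if met in parent_flags.index else False
        epi = bool(det_epiril.get(met, False))
        if col and dd:
            out[met] = "both_parents"
        elif col:
            out[met] = "col_only"
        elif dd:
            out[met] = "ddm1_only"
        elif epi:
            out[met] = "epiRIL_only"
        else:
            logger.warning("metabolite %s detected nowhere; excluded", met)
    s = pd.Series(out, name="detection_class")
    assert set(s.unique()) <= set(DETECTION_CLASSES)
    return s


def correlation_summary(m1: MetaboliteMatrix, m2: MetaboliteMatrix,
                        method: str = "pearson",
                        threshold: float = 0.2) -> CorrelationSummary:
    """Pairwise correlations between metabolites of two matrices.

    Computed on log10 batch-corrected values over the shared lines with
    pairwise-complete observations. Zero-variance metabolites get missing
    coefficients for all their pairs.
    """
    shared = m1.intensities.index.intersection(m2.intensities.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared lines for correlations")
    a = np.log10(m1.intensities.loc[shared])
    b = np.log10(m2.intensities.loc[shared])
    if m1.tissue == m2.tissue and a.columns.equals(b.columns):
        mat = a.corr(method=method, min_periods=3)
    else:
        joint = pd.concat([a.add_prefix("a::"), b.add_prefix("b::")], axis=1)
        full = joint.corr(method=method, min_periods=3)
        mat = full.loc[[c for c in joint if c.startswith("a::")],
                       [c for c in joint if c.startswith("b::")]]
        mat.index = [c[3:] for c in mat.index]
        mat.columns = [c[3:] for c in mat.columns]
    return CorrelationSummary(tissue_pair=(m1.tissue, m2.tissue), matrix=mat,
                              threshold=threshold, method=method)


def flowering_correct(trait: TraitVector, ft: TraitVector) -> TraitVector:
    """Divide raw-scale trait values by each line's flowering time.

    Flowering time must be strictly positive wherever the trait is observed;
    a non-positive value raises an error naming the line.
    """
    vals = trait.values
    ftv = ft.values.reindex(vals.index)
    bad = vals.notna() & (ftv.isna() | (ftv <= 0))
    if bad.any():
        line = bad.index[bad][0]
        raise ValueError(f"non-positive or missing flowering time for line {line}")
    return TraitVector(trait_id=trait.trait_id, values=vals / ftv,
                       transform_log=trait.transform_log,
                       ft_corrected=True, ft_source=ft.trait_id)


def knockout_compare(mutant: pd.DataFrame, wildtype: pd.DataFrame,
                     log10_transform: bool = True) -> pd.DataFrame:
    """Per-feature mutant vs wild-type comparison (Welch t-test).

    Inputs are replicate x feature intensity tables. Intensities are log10
    transformed before testing (matching the trait preprocessing); fold
    change is reported on the raw scale as mean(mutant)/mean(WT). Features
    with fewer than two replicates in either group are skipped. Stars mark
    p < 0.05 / 0.01 / 0.001.
    """
    rows = []
    features = [f for f in mutant.columns if f in wildtype.columns]
    for f in features:
        a = mutant[f].dropna().to_numpy(float)
        b = wildtype[f].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("feature %s: <2 replicates in a group; skipped", f)
            continue
        fold = float(a.mean() / b.mean()) if b.mean() != 0 else np.nan
        ta, tb = (np.log10(a), np.log10(b)) if log10_transform else (a, b)
        if np.allclose(ta, ta[0]) and np.allclose(tb, tb[0]) and np.isclose(ta[0], tb[0]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ta, tb, equal_var=False)
        stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append((f, float(a.mean()), float(b.mean()), fold, float(t), float(p), stars))
    return pd.DataFrame(rows, columns=["feature", "mean_mutant", "mean_wt",
                                       "fold_change", "t_stat", "p_value", "stars"])
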
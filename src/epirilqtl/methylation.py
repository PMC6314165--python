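"""Probe-level methylation scoring and its statistical links to traits.

The ML score of a probe is defined from the posterior probabilities of the
unmethylated/methylated states as ``ml = post_U * (-1) + post_M * 1``, lying
in [-1, 1]. Scores in [-1, -0.3) are called hypomethylated and scores in
[-0.3, 1] methylated (the -0.3 boundary belongs to the methylated side).

Region-level methylation averages the ML scores of probes overlapping a
0-based half-open interval; the same threshold converts the mean to a
state. Associations between region methylation and trait values use simple
linear regression on the continuous ML (binary two-group t-test available);
cosegregation between region state and marker epiallele uses a 2x2
chi-square test without continuity correction, switching to Fisher's exact
test when any expected cell count is below 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    CALL_COL,
    CALL_DDM1,
    HYPOMETHYLATED,
    METHYLATED,
    EpigenotypeMap,
    ProbeMethylation,
    QtlScanResult,
    TraitVector,
)
from . import mapping

logger = logging.getLogger(__name__)

STATE_THRESHOLD = -0.3


def methylation_level(post_u: float | np.ndarray,
                      post_m: float | np.ndarray) -> float | np.ndarray:
    """ML score from state posteriors: ``ml = -post_U + post_M``.

    The posteriors must sum to 1 within 1e-6.
    """
    pu = np.asarray(post_u, float)
    pm = np.asarray(post_m, float)
    if np.any(np.abs(pu + pm - 1.0) > 1e-6):
        raise ValueError("post_U + post_M must sum to 1")
    if np.any((pu < 0) | (pu > 1) | (pm < 0) | (pm > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    ml = -pu + pm
    return float(ml) if np.isscalar(post_u) else ml


def methylation_state(ml: float | np.ndarray) -> np.ndarray | str:
    """Hypomethylated for ml in [-1, -0.3), methylated for ml in [-0.3, 1]."""
    arr = np.asarray(ml, float)
    if np.any((arr < -1 - 1e-9) | (arr > 1 + 1e-9)):
        raise ValueError("ml outside [-1, 1]")
    out = np.where(arr < STATE_THRESHOLD, HYPOMETHYLATED, METHYLATED)
    return str(out) if np.isscalar(ml) else out


@dataclass
class RegionMethylation:
    """Per-line mean ML and state for one genomic region."""

    region: tuple[str, int, int]
    ml: pd.Series
    n_probes: int

    @property
    def state(self) -> pd.Series:
        return pd.Series(methylation_state(self.ml.to_numpy()), index=self.ml.index)


def region_methylation(probes: ProbeMethylation,
                       region: tuple[str, int, int]) -> RegionMethylation | None:
    """Mean ML over probes overlapping a half-open region, per line.

    Overlap uses half-open interval logic: a probe [100, 150) does not
    overlap region [150, 300). Returns None (with a warning) when no probe
    overlaps.
    """
    chrom, start, end = region
    pt = probes.probes
    hit = (pt["chrom"].astype(str) == str(chrom)) & (pt["start"] < end) & (start < pt["end"])
    ids = pt.loc[hit, "probe_id"]
    if len(ids) == 0:
        logger.warning("region %s:%d-%d has no probes; skipped", chrom, start, end)
        return None
    ml = probes.ml.loc[ids].mean(axis=0)
    return RegionMethylation(region=region, ml=ml, n_probes=len(ids))


def associate_methylation_trait(region_ml: pd.Series, trait: TraitVector,
                                log10_trait: bool = True,
                                ) -> tuple[float, float] | None:
    """Linear regression of (log10) trait on region ML.

    Returns ``(slope, p_value)`` from the two-sided t-test on the slope, or
    None when ML has zero variance or fewer than 10 complete pairs exist.
    """
    y = trait.values.reindex(region_ml.index)
    if log10_trait:
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.log10(y.where(y > 0))
    ok = y.notna() & region_ml.notna()
    if ok.sum() < 10:
        logger.warning("trait %s: only %d complete pairs", trait.trait_id, int(ok.sum()))
        return None
    x = region_ml[ok].to_numpy(float)
    yv = y[ok].to_numpy(float)
    if np.allclose(x, x[0]):
        logger.warning("zero-variance region ML; association undefined")
        return None
    res = _linregress(x, yv)
    return res


def _linregress(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook simple regression: slope and slope t-test p-value."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    if s2 <= 0:
        return slope, 0.0
    se = np.sqrt(s2 / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return slope, float(p)


def two_group_association(region_state: pd.Series, trait: TraitVector,
                          log10_trait: bool = True) -> tuple[float, float] | None:
    """Alternative binary association: Welch t-test between methylation states."""
    y = trait.values.reindex(region_state.index)
    if log10_trait:
        y = np.log10(y.where(y > 0))
    ok = y.notna()
    hypo = y[ok & (region_state == HYPOMETHYLATED)]
    meth = y[ok & (region_state == METHYLATED)]
    if len(hypo) < 2 or len(meth) < 2:
        return None
    t, p = stats.ttest_ind(hypo, meth, equal_var=False)
    return float(hypo.mean() - meth.mean()), float(p)


def cosegregation_test(region_state: pd.Series, marker_calls: pd.Series,
                       ) -> tuple[float, float, pd.DataFrame]:
    """Does the region methylation state cosegregate with a marker?

    Builds the 2x2 table (hypomethylated/methylated x COL/DDM1) over shared
    lines and applies the chi-square test without continuity correction,
    falling back to Fisher's exact test when any expected count is < 5. A
    zero margin returns (0, 1) with a degenerate table.
    """
    shared = region_state.index.intersection(marker_calls.index)
    st = region_state.reindex(shared)
    mk = marker_calls.reindex(shared)
    ok = st.notna() & mk.notna()
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 shared classified lines, got {int(ok.sum())}")
    st, mk = st[ok], mk[ok]
    table = pd.DataFrame(0, index=[HYPOMETHYLATED, METHYLATED],
                         columns=[CALL_COL, CALL_DDM1])
    for s, m in zip(st, mk):
        table.loc[s, m] += 1
    obs = table.to_numpy(float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        logger.warning("degenerate cosegregation table (zero margin)")
        return 0.0, 1.0, table
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(obs)
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        return chi2, float(p), table
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p), table


def eqtl_scan(expression: TraitVector, epi: EpigenotypeMap,
              scanpos: mapping.ScanPositions | None = None,
              n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
              log2_transform: bool = True, step_cM: float = 2.0,
              ) -> QtlScanResult:
    """eQTL scan of (log2) relative expression; delegates to the mapping engine."""
    vals = expression.values
    if log2_transform:
        vals = np.log2(vals.where(vals > 0))
    trait = TraitVector(trait_id=expression.trait_id, values=vals)
    if scanpos is None:
        scanpos = mapping.genotype_probabilities(epi, step_cM=step_cM)
    return mapping.scan_trait(trait, epi, scanpos, n_perm=n_perm,
                              alpha=alpha, seed=seed)
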
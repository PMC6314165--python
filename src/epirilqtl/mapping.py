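"""Haley-Knott interval mapping over a DMR marker map.

The mapping engine follows the classical epiRIL/RIL workflow: expected
epigenotype probabilities at a grid of (pseudo)marker positions, Haley-Knott
regression of the trait on those probabilities (optionally with MQM-style
marker cofactors outside an exclusion window), genome-wide significance by
phenotype permutation, 1.5-LOD support intervals and effect signs, and
single-linkage merging of overlapping support intervals into pleiotropic
regions.

The LOD score at a position is

    LOD = (n/2) * log10(RSS0 / RSS1)

where ``RSS1`` is the residual sum of squares of the least-squares fit of the
trait on intercept + P(DDM1) + cofactors and ``RSS0`` the same fit without
the position term. With no cofactors this reduces to the correlation closed
form ``(n/2) * log10(1/(1-r^2))``, which the permutation engine exploits to
scan thousands of permuted traits in one matrix product.

Epiallele coding for statistics is COL=0, DDM1=1; the reported effect sign is
``sign(mean(trait|COL) - mean(trait|DDM1))``, so a negative sign means the
trait is higher in *ddm1*-derived epigenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import EpigenotypeMap, QtlPeak, QtlScanResult, TraitVector

logger = logging.getLogger(__name__)


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a cM distance."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0)) / 2.0


def kosambi_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map function (alternative to Haldane)."""
    return 0.5 * np.tanh(2.0 * np.asarray(d_cM, float) / 100.0)


MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


@dataclass
class ScanPositions:
    """Grid of scan positions with per-line P(DDM1).

    ``positions`` has columns ``chrom, cM, is_pseudomarker, marker_id``
    (marker_id empty for pseudomarkers); ``p_ddm1`` is a line x position
    matrix of expected DDM1 epigenotype probabilities (never missing: lines
    without flank data fall back to the local population DDM1 frequency).
    """

    positions: pd.DataFrame
    p_ddm1: pd.DataFrame

    def __post_init__(self) -> None:
        if self.p_ddm1.shape[1] != len(self.positions):
            raise ValueError("p_ddm1 columns must match positions")

    @property
    def lines(self) -> list[str]:
        return self.p_ddm1.index.tolist()

    def marker_column(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.positions["marker_id"] == marker_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id} not in scan positions")
        return int(hits[0])


@dataclass
class CofactorSet:
    """Marker cofactors for MQM-style scans.

    Cofactors within ``window_cM`` of the test position are dropped from the
    model at that position so the cofactor does not absorb the local QTL.
    """

    marker_ids: list[str] = field(default_factory=list)
    window_cM: float = 10.0

    def __len__(self) -> int:
        return len(self.marker_ids)


# ---------------------------------------------------------------------------
# Genotype probabilities
# ---------------------------------------------------------------------------


def genotype_probabilities(epi: EpigenotypeMap, step_cM: float = 2.0,
                           map_function: str = "haldane") -> ScanPositions:
    """Expected P(DDM1) on a pseudomarker grid for Haley-Knott regression.

    Uses a symmetric two-state chain along each chromosome (the standard
    inbred-line approximation): the probability of switching epiallele over a
    gap ``d`` cM is the map-function recombination fraction ``r(d)``. For a
    line, P(DDM1) at a position conditions on the nearest observed flanking
    markers; with only one observed flank the single-flank transition is
    used, and with none the position falls back to the population DDM1
    frequency at the nearest marker.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    rfun = MAP_FUNCTIONS[map_function]
    coded = epi.coded()
    lines = coded.index
    pos_rows = []
    prob_cols = []
    for chrom in epi.markers.chroms:
        mtab = epi.markers.chrom_markers(chrom)
        if len(mtab) == 0:  # pragma: no cover - empty chromosomes are dropped upstream
            logger.warning("chromosome %s has no markers; skipped", chrom)
            continue
        mids = mtab["marker_id"].tolist()
        mpos = mtab["pos_cM"].to_numpy(float)
        G = coded[mids].to_numpy(float)  # lines x markers
        obs = ~np.isnan(G)
        # per-line nearest observed marker to the left/right of each marker
        left_val = pd.DataFrame(G).ffill(axis=1).to_numpy()
        left_pos = pd.DataFrame(np.where(obs, mpos, np.nan)).ffill(axis=1).to_numpy()
        right_val = pd.DataFrame(G).bfill(axis=1).to_numpy()
        right_pos = pd.DataFrame(np.where(obs, mpos, np.nan)).bfill(axis=1).to_numpy()
        with np.errstate(invalid="ignore"):
            marker_freq = np.nanmean(G, axis=0)
        marker_freq = np.where(np.isnan(marker_freq), 0.5, marker_freq)

        # pseudomarker grid: markers plus every step_cM in between
        grid: list[tuple[float, str]] = []
        for j, p in enumerate(mpos):
            grid.append((p, mids[j]))
            if j + 1 < len(mpos):
                x = p + step_cM
                while x < mpos[j + 1] - 1e-9:
                    grid.append((x, ""))
                    x += step_cM
        for x, marker_id in grid:
            j = int(np.searchsorted(mpos, x + 1e-9) - 1)  # marker at or left of x
            j = max(j, 0)
            jr = j + 1 if (j + 1 < len(mpos) and mpos[j] < x + 1e-9 <= mpos[j + 1] + 1e-9
                           and marker_id == "") else j
            if marker_id != "":
                lv, lp = left_val[:, j], left_pos[:, j]
                rv, rp = right_val[:, j], right_pos[:, j]
            else:
                lv, lp = left_val[:, j], left_pos[:, j]
                rv, rp = right_val[:, jr], right_pos[:, jr]
            p = _conditional_p(x, lv, lp, rv, rp, rfun)
            fallback = marker_freq[j]
            p = np.where(np.isnan(p), fallback, p)
            pos_rows.append((chrom, float(x), marker_id == "", marker_id))
            prob_cols.append(p)
    positions = pd.DataFrame(pos_rows, columns=["chrom", "cM", "is_pseudomarker", "marker_id"])
    p_ddm1 = pd.DataFrame(np.column_stack(prob_cols), index=lines)
    return ScanPositions(positions=positions, p_ddm1=p_ddm1)


def _conditional_p(x, left_val, left_pos, right_val, right_pos, rfun):
    """P(DDM1 at x | nearest observed flanks), symmetric two-state chain."""
    with np.errstate(invalid="ignore"):
        rL = rfun(np.abs(x - left_pos))
        rR = rfun(np.abs(right_pos - x))
        # probability of DDM1 at x given the left flank alone
        pL1 = np.where(left_val == 1.0, 1.0 - rL, rL)
        # transition from x to the right flank for each putative state
        pR_from1 = np.where(right_val == 1.0, 1.0 - rR, rR)
        pR_from0 = np.where(right_val == 1.0, rR, 1.0 - rR)
        num1 = pL1 * pR_from1
        num0 = (1.0 - pL1) * pR_from0
        both = num1 / (num0 + num1)
        only_left = pL1
        only_right = np.where(right_val == 1.0, 1.0 - rR, rR)
    have_l = ~np.isnan(left_val)
    have_r = ~np.isnan(right_val)
    p = np.full(left_val.shape, np.nan)
    p = np.where(have_l & have_r, both, p)
    p = np.where(have_l & ~have_r, only_left, p)
    p = np.where(~have_l & have_r, only_right, p)
    return p


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------


def _cofactor_design(epi: EpigenotypeMap, cofactors: CofactorSet,
                     lines: pd.Index) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Mean-imputed cofactor matrix plus each cofactor's (chrom, cM)."""
    coded = epi.coded().loc[lines]
    cols, meta, ids = [], [], []
    mtab = epi.markers.table.set_index("marker_id")
    for mid in cofactors.marker_ids:
        v = coded[mid].to_numpy(float)
        mu = np.nanmean(v)
        if np.isnan(mu):
            continue
        v = np.where(np.isnan(v), mu, v)
        cols.append(v)
        meta.append((mtab.loc[mid, "chrom"], float(mtab.loc[mid, "pos_cM"])))
        ids.append(mid)
    X = np.column_stack(cols) if cols else np.empty((len(lines), 0))
    return X, np.array(meta, dtype=object).reshape(-1, 2), ids


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def hk_scan(trait: TraitVector, scanpos: ScanPositions, epi: EpigenotypeMap,
            cofactors: CofactorSet | None = None,
            min_lines: int = 10) -> QtlScanResult:
    """Haley-Knott regression scan of one trait over all positions.

    Missing trait values are dropped pairwise; fewer than ``min_lines``
    complete observations raise an error. Cofactors within the exclusion
    window of the test position, or nearly collinear with it, are omitted at
    that position. Returns a :class:`QtlScanResult` carrying per-position LOD
    and fitted position coefficients (no peaks yet; see :func:`call_peaks`).
    """
    shared = [ln for ln in scanpos.lines if ln in trait.values.index]
    y_all = trait.values.reindex(shared)
    keep = y_all.notna()
    lines = y_all.index[keep]
    y = y_all[keep].to_numpy(float)
    n = len(y)
    if n < min_lines:
        raise ValueError(f"need >= {min_lines} lines with complete data, got {n}")
    P = scanpos.p_ddm1.loc[lines].to_numpy(float)
    npos = P.shape[1]
    lod = np.zeros(npos)
    effect = np.zeros(npos)
    yc = y - y.mean()
    syy = float(yc @ yc)

    if cofactors is None or len(cofactors) == 0:
        # closed form: LOD = (n/2) log10(1/(1-r^2)); beta from simple regression
        Pc = P - P.mean(axis=0)
        spp = (Pc * Pc).sum(axis=0)
        spy = Pc.T @ yc
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(spp > 0, spy**2 / (spp * syy), 0.0) if syy > 0 else np.zeros(npos)
            r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
            lod = (n / 2.0) * np.log10(1.0 / (1.0 - r2))
            effect = np.where(spp > 0, spy / np.where(spp > 0, spp, 1.0), 0.0)
        if syy == 0:
            lod[:] = 0.0
            effect[:] = 0.0
    else:
        C, cmeta, _ = _cofactor_design(epi, cofactors, lines)
        chroms = scanpos.positions["chrom"].to_numpy()
        cms = scanpos.positions["cM"].to_numpy(float)
        ones = np.ones((n, 1))
        for j in range(npos):
            x = P[:, j]
            if len(cmeta):
                same = cmeta[:, 0] == chroms[j]
                near = same & (np.abs(cmeta[:, 1].astype(float) - cms[j]) < cofactors.window_cM)
                use = ~near
                Cj = C[:, use]
                # drop cofactors nearly collinear with the test genotype
                if Cj.shape[1]:
                    xs = x - x.mean()
                    xn = np.sqrt(xs @ xs)
                    if xn > 0:
                        cs = Cj - Cj.mean(axis=0)
                        cn = np.sqrt((cs * cs).sum(axis=0))
                        with np.errstate(invalid="ignore", divide="ignore"):
                            cor = np.where(cn > 0, np.abs(cs.T @ xs) / (cn * xn), 0.0)
                        drop = cor > 0.95
                        if drop.any():
                            logger.debug("position %d: dropped %d collinear cofactors",
                                         j, int(drop.sum()))
                            Cj = Cj[:, ~drop]
            else:
                Cj = C
            X0 = np.hstack([ones, Cj])
            X1 = np.hstack([X0, x[:, None]])
            rss0 = _lstsq_rss(X0, y)
            rss1 = _lstsq_rss(X1, y)
            if rss1 <= 0 or rss0 <= 0:
                lod[j] = (n / 2.0) * np.log10(max(rss0, 1e-300) / max(rss1, 1e-300)) \
                    if rss0 > rss1 else 0.0
            else:
                lod[j] = max(0.0, (n / 2.0) * np.log10(rss0 / rss1))
            beta, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
            effect[j] = beta[-1]
    result = QtlScanResult(trait_id=trait.trait_id,
                           positions=scanpos.positions.copy(), lod=lod)
    result.positions["effect"] = effect
    return result


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------


def permutation_max_lods(trait: TraitVector, scanpos: ScanPositions,
                         n_perm: int, seed: int,
                         residualize: np.ndarray | None = None) -> np.ndarray:
    """Genome-wide maximum LOD for ``n_perm`` phenotype permutations.

    Vectorized through the correlation identity: after standardizing the
    genotype-probability columns and the permuted trait vectors, the full
    LOD matrix is one matrix product. Lines are shuffled against intact
    epigenotype rows, preserving marker LD. ``residualize`` (optional
    cofactor design) is projected out of trait and genotypes first.
    """
    y = trait.dropna()
    lines = [ln for ln in scanpos.lines if ln in y.index]
    yv = y.reindex(lines).to_numpy(float)
    P = scanpos.p_ddm1.loc[lines].to_numpy(float)
    n = len(yv)
    if residualize is not None and residualize.shape[1] > 0:
        Q, _ = np.linalg.qr(np.hstack([np.ones((n, 1)), residualize]))
        yv = yv - Q @ (Q.T @ yv)
        P = P - Q @ (Q.T @ P)
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = yv[idx].T  # n x n_perm
    Y = Y - Y.mean(axis=0)
    ynorm = np.sqrt((Y * Y).sum(axis=0))
    ynorm[ynorm == 0] = 1.0
    Y /= ynorm
    Pc = P - P.mean(axis=0)
    pnorm = np.sqrt((Pc * Pc).sum(axis=0))
    keep = pnorm > 0
    Pc = Pc[:, keep] / pnorm[keep]
    if Pc.shape[1] == 0:
        return np.zeros(n_perm)
    R = Pc.T @ Y  # n_pos x n_perm correlations
    r2 = np.clip(R * R, 0.0, 1.0 - 1e-15)
    lod = (n / 2.0) * np.log10(1.0 / (1.0 - r2))
    return lod.max(axis=0)


def permutation_threshold(trait: TraitVector, scanpos: ScanPositions,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0,
                          cofactor_design: np.ndarray | None = None) -> float:
    """Genome-wide LOD threshold: empirical (1-alpha) quantile of permutation
    maxima (default 1000 permutations, alpha 0.05)."""
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable quantile")
    maxima = permutation_max_lods(trait, scanpos, n_perm, seed,
                                  residualize=cofactor_design)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


# ---------------------------------------------------------------------------
# Cofactor selection (MQM-style)
# ---------------------------------------------------------------------------


def evenly_spaced_candidates(epi: EpigenotypeMap, spacing_cM: float = 10.0) -> list[str]:
    """Candidate cofactors evenly spaced along the map (>= spacing_cM apart)."""
    out: list[str] = []
    for chrom in epi.markers.chroms:
        mtab = epi.markers.chrom_markers(chrom)
        last = -np.inf
        for _, row in mtab.iterrows():
            if row["pos_cM"] - last >= spacing_cM:
                out.append(row["marker_id"])
                last = row["pos_cM"]
    return out


def select_cofactors(trait: TraitVector, epi: EpigenotypeMap,
                     candidate_markers: list[str] | None = None,
                     drop_alpha: float = 0.02,
                     window_cM: float = 10.0) -> CofactorSet:
    """Backward elimination of marker cofactors.

    Fits the trait on all candidates jointly and repeatedly removes the least
    significant marker until every remaining partial-F (equivalently
    squared-t) p-value is <= ``drop_alpha``.
    """
    if candidate_markers is None:
        candidate_markers = evenly_spaced_candidates(epi)
    y = trait.dropna()
    lines = y.index.intersection(epi.calls.index)
    yv = y.reindex(lines).to_numpy(float)
    n = len(yv)
    cands = list(candidate_markers)
    while n < len(cands) + 2 and len(cands) > 1:
        logger.warning("thinning cofactor candidates (%d) for n=%d", len(cands), n)
        cands = cands[::2]
    coded = epi.coded().loc[lines]
    while cands:
        cols = []
        for mid in cands:
            v = coded[mid].to_numpy(float)
            mu = np.nanmean(v)
            cols.append(np.where(np.isnan(v), mu, v))
        X = np.column_stack([np.ones(n)] + cols)
        beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        dof = n - X.shape[1]
        if dof <= 0:
            cands = cands[:-1]
            continue
        s2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 1e-300))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals[1:]), dof)
        worst = int(np.argmax(pvals))
        if pvals[worst] <= drop_alpha:
            break
        cands.pop(worst)
    return CofactorSet(marker_ids=cands, window_cM=window_cM)


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


def call_peaks(scan: QtlScanResult, threshold: float, lod_drop: float = 1.5,
               min_separation_cM: float = 10.0) -> QtlScanResult:
    """Call peaks above threshold with 1.5-LOD support intervals.

    Peaks are greedy local maxima separated by at least
    ``min_separation_cM``; each support interval is the contiguous region
    where LOD stays within ``lod_drop`` of the peak, extended outward to the
    flanking observed-marker positions. Effect size/sign are read from the
    per-position fitted coefficients stored by :func:`hk_scan`.
    """
    pos = scan.positions
    lod = scan.lod
    peaks: list[QtlPeak] = []
    for chrom in pd.unique(pos["chrom"]):
        mask = (pos["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        cms = pos.loc[mask, "cM"].to_numpy(float)
        lods = lod[idx]
        # candidates: local maxima of the profile at or above threshold
        is_max = np.ones(len(lods), bool)
        if len(lods) > 1:
            is_max[1:] &= lods[1:] >= lods[:-1]
            is_max[:-1] &= lods[:-1] >= lods[1:]
        order = [k for k in np.argsort(-lods, kind="mergesort") if is_max[k]]
        chosen: list[int] = []
        for k in order:
            if lods[k] < threshold:
                break
            if any(abs(cms[k] - cms[c]) < min_separation_cM for c in chosen):
                continue
            # a genuine secondary peak is separated from every accepted peak
            # by a valley at least lod_drop below it
            valley_ok = True
            for c in chosen:
                lo_i, hi_i = sorted((k, c))
                if lods[lo_i:hi_i + 1].min() > lods[k] - lod_drop:
                    valley_ok = False
                    break
            if valley_ok:
                chosen.append(k)
        is_marker = ~pos.loc[mask, "is_pseudomarker"].to_numpy()
        for k in sorted(chosen, key=lambda i: cms[i]):
            lo = k
            while lo > 0 and lods[lo - 1] >= lods[k] - lod_drop:
                lo -= 1
            hi = k
            while hi + 1 < len(lods) and lods[hi + 1] >= lods[k] - lod_drop:
                hi += 1
            # extend to flanking observed markers
            mlo = np.flatnonzero(is_marker[: lo + 1])
            mhi = np.flatnonzero(is_marker[hi:])
            ci_lo = cms[mlo[-1]] if len(mlo) else cms[lo]
            ci_hi = cms[hi + mhi[0]] if len(mhi) else cms[hi]
            beta = float(pos.loc[idx[k], "effect"]) if "effect" in pos.columns else 0.0
            sign = -1 if beta > 0 else 1
            peaks.append(QtlPeak(chrom=str(chrom), pos_cM=float(cms[k]),
                                 lod=float(lods[k]), ci_lo=float(ci_lo),
                                 ci_hi=float(ci_hi), effect_size=beta,
                                 effect_sign=sign))
    return QtlScanResult(trait_id=scan.trait_id, positions=scan.positions,
                         lod=scan.lod, threshold=threshold, peaks=peaks)


def scan_trait(trait: TraitVector, epi: EpigenotypeMap, scanpos: ScanPositions,
               n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
               cofactors: CofactorSet | None = None,
               lod_drop: float = 1.5) -> QtlScanResult:
    """Convenience: scan + permutation threshold + peak calling for a trait."""
    scan = hk_scan(trait, scanpos, epi, cofactors=cofactors)
    thr = permutation_threshold(trait, scanpos, n_perm=n_perm, alpha=alpha, seed=seed)
    return call_peaks(scan, thr, lod_drop=lod_drop)


# ---------------------------------------------------------------------------
# qPCR normalization, colocalization, pleiotropy
# ---------------------------------------------------------------------------


def qpcr_normalize(ct_table: pd.DataFrame, reference_genes: list[str],
                   target_gene: str, efficiency: float = 2.0) -> TraitVector:
    """Relative expression from qPCR Ct values.

    ``relative expression = efficiency ** (mean(Ct_refs) - Ct_target)``;
    normalization against reference genes (e.g. SAND and TIP41) averages
    their Ct per sample. Missing target Ct gives missing expression.
    """
    missing = [g for g in reference_genes + [target_gene] if g not in ct_table.columns]
    if missing:
        raise ValueError(f"genes absent from Ct table: {missing}")
    ref = ct_table[reference_genes].mean(axis=1)
    rel = efficiency ** (ref - ct_table[target_gene])
    return TraitVector(trait_id=f"expr_{target_gene}", values=rel)


def colocalize(eqtl: QtlScanResult, region: tuple[str, float, float]) -> bool:
    """True iff any eQTL peak lies in the (closed) cM interval of ``region``."""
    chrom, lo, hi = region
    known = set(eqtl.positions["chrom"].astype(str))
    if str(chrom) not in known:
        raise ValueError(f"region chromosome {chrom!r} not in scan chromosomes {sorted(known)}")
    return any(p.chrom == str(chrom) and lo <= p.pos_cM <= hi for p in eqtl.peaks)


def pleiotropy_regions(scans: list[QtlScanResult],
                       trait_groups: dict[str, str] | None = None,
                       traits: dict[str, TraitVector] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge overlapping support intervals into pleiotropic QTL regions.

    Single-linkage merge of the peaks' 1.5-LOD intervals per chromosome.
    Returns ``(regions, pairs)``: one row per merged region with member
    traits and trait-group composition, and one row per trait pair sharing a
    region with the Pearson correlation of their values and its t-test
    p-value (a substitute for the chi-square statistic used descriptively in
    the source analyses; labelled as such).
    """
    rows = []
    for scan in scans:
        for p in scan.peaks:
            grp = (trait_groups or {}).get(scan.trait_id, "trait")
            rows.append((p.chrom, p.ci_lo, p.ci_hi, scan.trait_id, grp))
    region_cols = ["region_id", "chrom", "cM_lo", "cM_hi", "n_traits", "traits", "groups"]
    pair_cols = ["region_id", "trait_a", "trait_b", "pearson_r", "p_value"]
    if not rows:
        return pd.DataFrame(columns=region_cols), pd.DataFrame(columns=pair_cols)
    df = pd.DataFrame(rows, columns=["chrom", "lo", "hi", "trait", "group"])
    regions, pairs = [], []
    rid = 0
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("lo")
        cur = None
        members: list[tuple[str, str]] = []

        def flush():
            nonlocal rid, cur, members
            if cur is None:
                return
            rid += 1
            tr = sorted({t for t, _ in members})
            gr = sorted({g for _, g in members})
            regions.append((f"R{rid}", chrom, cur[0], cur[1], len(tr),
                            ";".join(tr), ";".join(gr)))
            if traits:
                for i in range(len(tr)):
                    for j in range(i + 1, len(tr)):
                        a, b = tr[i], tr[j]
                        if a in traits and b in traits:
                            va, vb = traits[a].values.align(traits[b].values, join="inner")
                            ok = va.notna() & vb.notna()
                            if ok.sum() >= 3:
                                r, pv = stats.pearsonr(va[ok], vb[ok])
                                pairs.append((f"R{rid}", a, b, float(r), float(pv)))
            cur, members = None, []

        for _, row in grp.iterrows():
            if cur is None or row["lo"] > cur[1]:
                flush()
                cur = [row["lo"], row["hi"]]
                members = [(row["trait"], row["group"])]
            else:
                cur[1] = max(cur[1], row["hi"])
                members.append((row["trait"], row["group"]))
        flush()
    return (pd.DataFrame(regions, columns=region_cols),
            pd.DataFrame(pairs, columns=pair_cols))
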
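"""Staged cis-candidate funnel.

Starting from genes whose bodies fall inside a QTL's 1.5-LOD support
interval (projected from cM to bp by linear interpolation between flanking
marker midpoints), candidates pass through, in order:

1. interval membership,
2. optional pathway membership (local gene -> pathway table),
3. methylation-trait association (P < alpha in any of promoter / gene body /
   1 kb downstream),
4. cosegregation of the associated region's methylation state with the peak
   marker (P < alpha),
5. ranking: promoter DMRs weigh more than gene-body, gene-body more than
   downstream, plus a bonus for a TE within 1 kb and optional expression
   evidence.

Stage flags short-circuit, so the per-stage candidate counts are monotone
non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import EpigenotypeMap, GeneModel, MarkerMap, ProbeMethylation, \
    QtlScanResult, TraitVector
from . import methylation as meth

logger = logging.getLogger(__name__)

REGION_WEIGHTS = {"promoter": 3.0, "gene_body": 2.0, "downstream": 1.0}
STAGES = ("in_interval", "pathway_member", "assoc_significant", "coseg_significant")


@dataclass
class FunnelRecord:
    """Per gene x QTL record of every funnel stage."""

    gene_id: str
    trait_id: str
    peak_marker: str
    interval: tuple[str, float, float]
    in_interval: bool = False
    pathway_member: bool = False
    assoc_significant: bool = False
    assoc_p: float | None = None
    assoc_region: str | None = None
    coseg_significant: bool = False
    coseg_p: float | None = None
    rank_score: float = 0.0
    surviving: bool = False


def cm_to_bp(marker_map: MarkerMap, chrom: str, cm: float) -> float:
    """Project a cM position to bp by linear interpolation between the
    midpoints of flanking marker physical intervals (clipped at the map
    ends, logged)."""
    mtab = marker_map.chrom_markers(chrom)
    if len(mtab) == 0:
        raise ValueError(f"no markers on chromosome {chrom}")
    cms = mtab["pos_cM"].to_numpy(float)
    mids = ((mtab["phys_start"] + mtab["phys_end"]) / 2.0).to_numpy(float)
    if cm < cms[0] or cm > cms[-1]:
        logger.warning("cM %.2f outside marker range on %s; clipped", cm, chrom)
    return float(np.interp(cm, cms, mids))


def interval_to_bp(marker_map: MarkerMap, chrom: str, lo_cm: float,
                   hi_cm: float) -> tuple[float, float]:
    """bp span of a cM interval: the midpoint projection extended to cover
    the full physical intervals of every marker inside the cM range (the
    boundary markers themselves belong to the QTL region)."""
    lo_bp = cm_to_bp(marker_map, chrom, lo_cm)
    hi_bp = cm_to_bp(marker_map, chrom, hi_cm)
    mtab = marker_map.chrom_markers(chrom)
    inside = mtab[(mtab["pos_cM"] >= lo_cm) & (mtab["pos_cM"] <= hi_cm)]
    if len(inside):
        lo_bp = min(lo_bp, float(inside["phys_start"].min()))
        hi_bp = max(hi_bp, float(inside["phys_end"].max()))
    return lo_bp, hi_bp


def genes_in_interval(genes: list[GeneModel],
                      interval: tuple[str, float, float],
                      marker_map: MarkerMap) -> list[GeneModel]:
    """Genes whose body overlaps the bp projection of a cM support interval."""
    chrom, lo_cm, hi_cm = interval
    lo_bp, hi_bp = interval_to_bp(marker_map, chrom, lo_cm, hi_cm)
    out = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.gene_body[0] < hi_bp and lo_bp < g.gene_body[1]:
            out.append(g)
    return out


def filter_pathway(genes: list[GeneModel], pathway_table: pd.DataFrame,
                   pathway: str) -> list[GeneModel]:
    """Keep genes annotated to ``pathway`` in a local (gene_id, pathway) table.

    Genes absent from the table are treated as non-members. An empty table
    yields an empty list with a warning (disable the filter instead of
    passing an empty table if that is not intended).
    """
    if len(pathway_table) == 0:
        logger.warning("empty pathway table: all genes dropped")
        return []
    members = set(pathway_table.loc[pathway_table["pathway"] == pathway, "gene_id"])
    return [g for g in genes if g.gene_id in members]


def peak_marker_id(marker_map: MarkerMap, chrom: str, peak_cm: float) -> str:
    """The observed marker closest in cM to the peak (the 'most significant
    marker' used for cosegregation)."""
    mtab = marker_map.chrom_markers(chrom)
    k = int((mtab["pos_cM"] - peak_cm).abs().idxmin())
    return str(marker_map.table.loc[k, "marker_id"])


def run_funnel(genes: list[GeneModel], qtls: list[QtlScanResult],
               probes: ProbeMethylation, traits: dict[str, TraitVector],
               epi: EpigenotypeMap,
               alpha_assoc: float = 0.05, alpha_coseg: float = 0.05,
               pathway_table: pd.DataFrame | None = None,
               trait_pathways: dict[str, str] | None = None,
               expression_evidence: dict[str, bool] | None = None,
               region_weights: dict[str, float] = REGION_WEIGHTS,
               ) -> list[FunnelRecord]:
    """Run the staged funnel for every QTL peak of every scanned trait.

    The pathway stage runs only when both ``pathway_table`` and a pathway
    class for the trait are supplied; otherwise every in-interval gene
    passes it. Association is tested per region (promoter, gene body,
    downstream); a gene passes if any region is significant, and the most
    significant region carries forward to cosegregation and ranking. No
    multiple-testing correction is applied by default (``alpha`` values act
    on raw p-values); apply Benjamini-Hochberg downstream if desired.
    """
    records: list[FunnelRecord] = []
    for scan in qtls:
        trait = traits.get(scan.trait_id)
        if trait is None:
            logger.warning("no trait values for %s; skipped", scan.trait_id)
            continue
        for peak in scan.peaks:
            interval = (peak.chrom, peak.ci_lo, peak.ci_hi)
            pm = peak_marker_id(epi.markers, peak.chrom, peak.pos_cM)
            inside = genes_in_interval(genes, interval, epi.markers)
            inside_ids = {g.gene_id for g in inside}
            pathway = (trait_pathways or {}).get(scan.trait_id)
            if pathway_table is not None and pathway is not None:
                path_ids = {g.gene_id for g in
                            filter_pathway(inside, pathway_table, pathway)}
            else:
                path_ids = inside_ids
            for g in sorted(inside, key=lambda g: g.gene_id):
                rec = FunnelRecord(gene_id=g.gene_id, trait_id=scan.trait_id,
                                   peak_marker=pm, interval=interval,
                                   in_interval=True)
                records.append(rec)
                rec.pathway_member = g.gene_id in path_ids
                if not rec.pathway_member:
                    continue
                # stage 3: methylation-trait association per region
                best: tuple[float, str, pd.Series] | None = None
                for rname, riv in g.regions().items():
                    rm = meth.region_methylation(probes, (g.chrom, *riv))
                    if rm is None:
                        continue
                    res = meth.associate_methylation_trait(rm.ml, trait)
                    if res is None:
                        continue
                    _, p = res
                    if p < alpha_assoc and (best is None or p < best[0]):
                        best = (p, rname, rm.state)
                if best is None:
                    continue
                rec.assoc_significant = True
                rec.assoc_p, rec.assoc_region = best[0], best[1]
                # stage 4: cosegregation with the peak marker
                try:
                    _, coseg_p, _ = meth.cosegregation_test(best[2], epi.calls[pm])
                except ValueError as exc:
                    logger.warning("gene %s: cosegregation untestable (%s)",
                                   g.gene_id, exc)
                    continue
                rec.coseg_p = coseg_p
                if coseg_p >= alpha_coseg:
                    continue
                rec.coseg_significant = True
                # stage 5: ranking
                score = region_weights.get(best[1], 0.0)
                riv = g.regions()[best[1]]
                if _te_within_1kb(g, riv):
                    score += 1.0
                if expression_evidence and expression_evidence.get(g.gene_id):
                    score += 1.0
                rec.rank_score = score
                rec.surviving = True
    return records


def _te_within_1kb(g: GeneModel, region: tuple[int, int]) -> bool:
    for (ts, te), _fam in g.te_features:
        gap = max(ts - region[1], region[0] - te, 0)
        if gap < 1000:
            return True
    return False


def funnel_counts(records: list[FunnelRecord]) -> dict[str, int]:
    """Candidate count surviving each successive stage."""
    counts = {s: 0 for s in STAGES}
    counts["surviving"] = 0
    for r in records:
        for s in STAGES:
            counts[s] += bool(getattr(r, s))
        counts["surviving"] += r.surviving
    return counts


def funnel_table(records: list[FunnelRecord]) -> pd.DataFrame:
    rows = [{
        "gene_id": r.gene_id, "trait": r.trait_id, "peak_marker": r.peak_marker,
        "chrom": r.interval[0], "ci_lo": r.interval[1], "ci_hi": r.interval[2],
        "in_interval": r.in_interval, "pathway_member": r.pathway_member,
        "assoc_significant": r.assoc_significant, "assoc_p": r.assoc_p,
        "assoc_region": r.assoc_region,
        "coseg_significant": r.coseg_significant, "coseg_p": r.coseg_p,
        "rank_score": r.rank_score, "surviving": r.surviving,
    } for r in sorted(records, key=lambda r: (-r.rank_score, r.gene_id, r.trait_id))]
    cols = ["gene_id", "trait", "peak_marker", "chrom", "ci_lo", "ci_hi",
            "in_interval", "pathway_member", "assoc_significant", "assoc_p",
            "assoc_region", "coseg_significant", "coseg_p", "rank_score",
            "surviving"]
    return pd.DataFrame(rows, columns=cols)
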
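"""Trans-target discovery through artificial small RNAs.

The trans arm asks whether a QTL interval could regulate a distal gene via
RNA-directed DNA methylation: promoter probes of genes *outside* the QTL
interval are screened for methylation coupled to the QTL peak marker, the
promoters of passing genes are searched for segments of perfect sequence
identity with the QTL interval (forward or reverse complement), those
segments are decomposed into all 21-24 nt windows (artificial sRNAs), and
each artsRNA is scored for predicted ARGONAUTE 4/6/9 loading, matched
against real WT and *ddm1* small-RNA libraries, and annotated for
transposable-element proximity (< 1000 bp).

The AGO-loading scorer is pluggable: any object with a
``score(sequence) -> {"AGO4": p, "AGO6": p, "AGO9": p}`` method works. The
default is an explicit sequence-rule heuristic reflecting the canonical
sorting preferences (24-nt with a 5' A favours AGO4; 21-22 nt with a 5' U
favours the post-transcriptional AGOs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    ArtsRNACandidate,
    EpigenotypeMap,
    GeneModel,
    ProbeMethylation,
    QtlScanResult,
    SRNALibrary,
    revcomp,
)
from .cis_candidates import cm_to_bp, interval_to_bp, peak_marker_id
from .methylation import methylation_state

logger = logging.getLogger(__name__)

ARTS_LENGTHS = (21, 22, 23, 24)


# ---------------------------------------------------------------------------
# Criteria screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenHit:
    """A gene passing all five trans-screen criteria for one QTL."""

    gene_id: str
    trait_id: str
    qtl_chrom: str
    qtl_lo: float
    qtl_hi: float
    peak_marker: str
    probe_run: list[str] = field(default_factory=list)


def screen_trans_genes(probes: ProbeMethylation, genes: list[GeneModel],
                       epi: EpigenotypeMap, qtl_scans: list[QtlScanResult],
                       parent_calls: pd.DataFrame,
                       alpha: float = 0.05) -> list[ScreenHit]:
    """Five-criteria screen for putative trans-regulated genes.

    A gene passes for a given QTL peak when it has promoter probes
    (criterion 1) whose methylation varies across the epiRILs (2), whose
    parental calls are polymorphic (3, from ``parent_calls`` with per-probe
    columns ``Col``/``ddm1`` holding post_M), that include at least two
    consecutive probes significantly correlated with the peak-marker coding
    with the same sign (4), while the gene itself lies outside the QTL
    support interval (5).
    """
    hits: list[ScreenHit] = []
    coded = epi.coded()
    pml = probes.ml
    skipped_no_probe = 0
    for scan in qtl_scans:
        for peak in scan.peaks:
            pm = peak_marker_id(epi.markers, peak.chrom, peak.pos_cM)
            g_marker = coded[pm]
            lo_bp, hi_bp = interval_to_bp(epi.markers, peak.chrom,
                                          peak.ci_lo, peak.ci_hi)
            for gene in genes:
                # criterion 5: outside the QTL interval
                if gene.chrom == peak.chrom and \
                        gene.gene_body[0] < hi_bp and lo_bp < gene.gene_body[1]:
                    continue
                # criterion 1: probes in the promoter
                ps, pe = gene.promoter
                mask = ((probes.probes["chrom"].astype(str) == gene.chrom)
                        & (probes.probes["start"] < pe)
                        & (ps < probes.probes["end"]))
                prom = probes.probes.loc[mask].sort_values("start")
                if len(prom) == 0:
                    skipped_no_probe += 1
                    continue
                flags = []
                for pid in prom["probe_id"]:
                    ml = pml.loc[pid]
                    # criterion 2: variance across the population
                    if ml.std(ddof=0) <= 0:
                        flags.append((False, 0.0))
                        continue
                    # criterion 3: parents polymorphic
                    if pid in parent_calls.index:
                        c_state = methylation_state(2 * parent_calls.loc[pid, "Col"] - 1)
                        d_state = methylation_state(2 * parent_calls.loc[pid, "ddm1"] - 1)
                        if c_state == d_state:
                            flags.append((False, 0.0))
                            continue
                    else:
                        flags.append((False, 0.0))
                        continue
                    # criterion 4 (per probe): correlation with peak marker
                    x, y = g_marker.align(ml, join="inner")
                    ok = x.notna() & y.notna()
                    if ok.sum() < 3 or y[ok].std(ddof=0) == 0:
                        flags.append((False, 0.0))
                        continue
                    r, p = stats.pearsonr(x[ok], y[ok])
                    flags.append((p < alpha, float(np.sign(r))))
                # criterion 4: two consecutive probes, same-sign correlation
                run = None
                for k in range(len(flags) - 1):
                    (a_sig, a_sign), (b_sig, b_sign) = flags[k], flags[k + 1]
                    if a_sig and b_sig and a_sign == b_sign != 0.0:
                        run = prom["probe_id"].iloc[k:k + 2].tolist()
                        break
                if run:
                    hits.append(ScreenHit(gene_id=gene.gene_id,
                                          trait_id=scan.trait_id,
                                          qtl_chrom=peak.chrom,
                                          qtl_lo=peak.ci_lo, qtl_hi=peak.ci_hi,
                                          peak_marker=pm, probe_run=run))
    if skipped_no_probe:
        logger.info("%d gene x QTL pairs skipped: no promoter probes",
                    skipped_no_probe)
    return hits


# ---------------------------------------------------------------------------
# Perfect-similarity segments
# ---------------------------------------------------------------------------


@dataclass
class MatchSegment:
    """Maximal exact match between a promoter and a QTL interval sequence.

    Coordinates are offsets into the two input sequences; ``strand`` is +
    when the promoter matches the QTL sequence directly and - when it
    matches its reverse complement. ``sequence`` is the promoter-sense
    sequence of the match.
    """

    segment_id: str
    gene_id: str
    promoter_start: int
    promoter_end: int
    qtl_start: int
    qtl_end: int
    strand: str
    sequence: str

    @property
    def length(self) -> int:
        return self.promoter_end - self.promoter_start


def _maximal_matches(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= k as (a_start, b_start, length).

    Seed-and-extend on k-mers; N never matches. Any seed inside a maximal
    match extends to the same (start, diagonal, length), so de-duplication
    by (a_start, b_start) is exact.
    """
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        kmer = b[j:j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    seen: set[tuple[int, int]] = set()
    out = []
    for i in range(len(a) - k + 1):
        kmer = a[i:i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            s, t = i, j
            while s > 0 and t > 0 and a[s - 1] == b[t - 1] and a[s - 1] != "N":
                s -= 1
                t -= 1
            if (s, t) in seen:
                continue
            seen.add((s, t))
            e = i + k
            f = j + k
            while e < len(a) and f < len(b) and a[e] == b[f] and a[e] != "N":
                e += 1
                f += 1
            out.append((s, t, e - s))
    return out


def find_match_segments(promoter_seq: str, qtl_seq: str, min_match: int = 21,
                        gene_id: str = "", id_prefix: str = "seg",
                        ) -> list[MatchSegment]:
    """All maximal perfect-identity segments (>= min_match) between a
    promoter and a QTL interval, forward and reverse complement.

    Deterministic output order: promoter offset, then length, then strand.
    """
    if min_match < 21:
        raise ValueError("min_match must be >= 21")
    a = promoter_seq.upper().replace("U", "T")
    b = qtl_seq.upper().replace("U", "T")
    raw: list[tuple[int, int, int, str]] = []
    for s, t, L in _maximal_matches(a, b, min_match):
        raw.append((s, t, L, "+"))
    brc = revcomp(b)
    for s, t, L in _maximal_matches(a, brc, min_match):
        # map back to b coordinates
        raw.append((s, len(b) - t - L, L, "-"))
    raw.sort(key=lambda x: (x[0], x[2], x[3]))
    out = []
    for i, (s, t, L, strand) in enumerate(raw):
        out.append(MatchSegment(
            segment_id=f"{id_prefix}{i + 1}", gene_id=gene_id,
            promoter_start=s, promoter_end=s + L,
            qtl_start=t, qtl_end=t + L, strand=strand,
            sequence=a[s:s + L]))
    return out


# ---------------------------------------------------------------------------
# artsRNA decomposition and AGO scoring
# ---------------------------------------------------------------------------


def decompose_artsrnas(segment: MatchSegment,
                       lengths: Iterable[int] = ARTS_LENGTHS,
                       ) -> list[ArtsRNACandidate]:
    """Every substring of each configured length, both strands.

    For a segment of length L the candidate count is
    ``sum over k <= L of 2 * (L - k + 1)`` (duplicate (sequence, strand,
    offset) triples cannot occur).
    """
    L = segment.length
    out: list[ArtsRNACandidate] = []
    seen: set[tuple[str, str, int]] = set()
    for k in sorted(lengths):
        if k > L:
            continue
        for off in range(L - k + 1):
            window = segment.sequence[off:off + k]
            for strand, seq in (("+", window), ("-", revcomp(window))):
                key = (seq, strand, off)
                if key in seen:
                    continue
                seen.add(key)
                out.append(ArtsRNACandidate(sequence=seq, strand=strand,
                                            segment_id=segment.segment_id,
                                            offset=off))
    return out


class AgoScorer(Protocol):
    """Deterministic map from an sRNA sequence to AGO4/6/9 loading scores."""

    def score(self, sequence: str) -> dict[str, float]: ...


class DefaultAgoScorer:
    """Sequence-rule heuristic for AGO4/6/9 loading.

    Rules (on the DNA alphabet):

    * length 24 with a 5' A  -> AGO4 0.9, AGO6 0.2, AGO9 0.2 (the
      heterochromatic siRNA signature);
    * length 21-22 with a 5' T (= U) -> AGO4 0.1, AGO6 0.4, AGO9 0.4;
    * anything else -> 0.2 for all three.

    Any object with the same ``score`` signature (including one backed by a
    file of precomputed probabilities) can replace it.
    """

    def score(self, sequence: str) -> dict[str, float]:
        s = sequence.upper().replace("U", "T")
        if len(s) == 24 and s.startswith("A"):
            return {"AGO4": 0.9, "AGO6": 0.2, "AGO9": 0.2}
        if len(s) in (21, 22) and s.startswith("T"):
            return {"AGO4": 0.1, "AGO6": 0.4, "AGO9": 0.4}
        return {"AGO4": 0.2, "AGO6": 0.2, "AGO9": 0.2}


class FileAgoScorer:
    """AGO scores looked up from a table (columns sequence, AGO4, AGO6, AGO9)."""

    def __init__(self, table: pd.DataFrame, default: float = 0.0):
        self._scores = {
            row["sequence"].upper().replace("U", "T"):
                {a: float(row[a]) for a in ("AGO4", "AGO6", "AGO9")}
            for _, row in table.iterrows()
        }
        self._default = default

    def score(self, sequence: str) -> dict[str, float]:
        s = sequence.upper().replace("U", "T")
        return self._scores.get(s, {a: self._default for a in ("AGO4", "AGO6", "AGO9")})


def score_ago_loading(candidates: list[ArtsRNACandidate],
                      scorer: AgoScorer | None = None,
                      min_prob: float = 0.5) -> list[ArtsRNACandidate]:
    """Score every candidate and keep those with max AGO score >= min_prob.

    All three scores are retained on each candidate (also on filtered-out
    ones, which are simply not returned).
    """
    scorer = scorer or DefaultAgoScorer()
    kept = []
    for c in candidates:
        scores = scorer.score(c.sequence)
        for ago, s in scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"scorer returned {ago}={s} outside [0,1]")
        c.ago_scores = dict(scores)
        if max(scores.values()) >= min_prob:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Library matching and TE proximity
# ---------------------------------------------------------------------------


def match_srna_library(candidates: list[ArtsRNACandidate],
                       libraries: list[SRNALibrary],
                       max_mismatch: int = 0) -> list[ArtsRNACandidate]:
    """Summed read counts of library matches per source, sense or antisense.

    Exact matching (0 mismatches) by default; up to 2 mismatches supported
    by brute force. The WT/ddm1 depletion ratio can be computed downstream
    from the per-source counts.
    """
    if max_mismatch > 2:
        raise ValueError("max_mismatch > 2 not supported")
    indexes = {lib.source: lib.count_index() for lib in libraries}
    for c in candidates:
        hits: dict[str, int] = {}
        # dict dedupe keeps palindromic candidates from double counting
        queries = tuple(dict.fromkeys((c.sequence, revcomp(c.sequence))))
        for source, idx in indexes.items():
            total = 0
            if max_mismatch == 0:
                for q in queries:
                    total += idx.get(q, 0)
            else:
                for seq, cnt in idx.items():
                    if len(seq) != len(c.sequence):
                        continue
                    for q in queries:
                        if sum(x != y for x, y in zip(seq, q)) <= max_mismatch:
                            total += cnt
                            break
            hits[source] = total
        c.library_hits = hits
    return candidates


def annotate_te_proximity(candidates: list[ArtsRNACandidate],
                          segments: dict[str, MatchSegment],
                          genes: dict[str, GeneModel]) -> list[ArtsRNACandidate]:
    """Flag candidates whose promoter-side match interval lies inside a TE
    or strictly closer than 1000 bp to one (999 bp away counts, 1000 does
    not)."""
    any_te = any(g.te_features for g in genes.values())
    if not any_te:
        logger.warning("no TE annotation available; te_within_1kb all false")
    for c in candidates:
        seg = segments.get(c.segment_id)
        if seg is None or seg.gene_id not in genes:
            c.te_within_1kb = False
            continue
        g = genes[seg.gene_id]
        # genomic coordinates of the candidate's match interval
        lo = g.promoter[0] + seg.promoter_start + c.offset
        hi = lo + c.length
        flag = False
        for (ts, te), _fam in g.te_features:
            gap = max(ts - hi, lo - te, 0)
            if gap < 1000:
                flag = True
                break
        c.te_within_1kb = flag
    return candidates


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def trans_report(hits: list[ScreenHit],
                 segments_by_gene: dict[str, list[MatchSegment]],
                 candidates_by_gene: dict[str, list[ArtsRNACandidate]],
                 eqtl_colocalized: dict[str, bool] | None = None,
                 ) -> pd.DataFrame:
    """Ranked trans-target table.

    One row per screened gene: screen evidence, number of perfect-identity
    segments, artsRNAs passing the AGO filter, library support per source,
    TE proximity, and the eQTL colocalization flag. Ranked by
    (colocalization, WT library support, best AGO score), descending.
    """
    rows = []
    for h in hits:
        segs = segments_by_gene.get(h.gene_id, [])
        cands = candidates_by_gene.get(h.gene_id, [])
        wt = sum(c.library_hits.get("WT", 0) for c in cands)
        dd = sum(c.library_hits.get("ddm1", 0) for c in cands)
        best_ago = max((max(c.ago_scores.values()) for c in cands if c.ago_scores),
                       default=0.0)
        ratio = wt / dd if wt and dd else np.nan
        rows.append({
            "gene_id": h.gene_id, "trait": h.trait_id,
            "qtl_chrom": h.qtl_chrom, "qtl_lo": h.qtl_lo, "qtl_hi": h.qtl_hi,
            "peak_marker": h.peak_marker, "probe_run": ";".join(h.probe_run),
            "n_segments": len(segs), "n_artsrnas": len(cands),
            "best_ago_score": best_ago, "wt_hits": wt, "ddm1_hits": dd,
            "wt_ddm1_ratio": ratio,
            "te_within_1kb": any(c.te_within_1kb for c in cands),
            "eqtl_colocalized": bool((eqtl_colocalized or {}).get(h.gene_id, False)),
        })
    cols = ["gene_id", "trait", "qtl_chrom", "qtl_lo", "qtl_hi", "peak_marker",
            "probe_run", "n_segments", "n_artsrnas", "best_ago_score",
            "wt_hits", "ddm1_hits", "wt_ddm1_ratio", "te_within_1kb",
            "eqtl_colocalized"]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values(["eqtl_colocalized", "wt_hits", "best_ago_score",
                             "gene_id"],
                            ascending=[False, False, False, True])
        # one row per gene: its best-supported QTL association
        df = df.drop_duplicates("gene_id", keep="first").reset_index(drop=True)
    return df
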
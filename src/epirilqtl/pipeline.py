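"""End-to-end orchestration: simulate -> preprocess -> map -> cis -> trans.

:func:`run_pipeline` executes the full chain on a synthetic study described
by a :class:`~epirilqtl.synthetic_data.SimulationConfig`, writing every
stage's tables plus a markdown summary. All thresholds default to the
package-wide conventions (1.5-LOD support intervals, 1000 permutations at
alpha 0.05, ML state boundary -0.3, |rho| > 0.2, artsRNA windows 21-24 nt,
AGO cutoff 0.5, TE proximity < 1000 bp). The run is a pure function of
(config, seed): identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cis_candidates, mapping, metabolome, methylation, synthetic_data, trans_srna
from .io_core import (
    TraitVector,
    read_annotation,
    write_epigenotypes,
    write_metabolites,
    write_probe_methylation,
    write_results,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "mapqtl", "cis", "trans", "report")


@dataclasses.dataclass
class PipelineOptions:
    """Analysis thresholds shared by every stage."""

    step_cM: float = 2.0
    n_perm: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    correlation_threshold: float = 0.2
    alpha_assoc: float = 0.05
    alpha_coseg: float = 0.05
    min_match: int = 21
    ago_min: float = 0.5
    ft_correct: bool = True


def _concat_peak_tables(scans) -> pd.DataFrame:
    frames = [s.peak_table() for s in scans]
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        return frames[0] if frames else pd.DataFrame()
    return pd.concat(nonempty, ignore_index=True)


def _log10_traits(matrix, prefix: str) -> dict[str, TraitVector]:
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for met in matrix.metabolites:
            vals = matrix.intensities[met]
            out[f"{prefix}{met}"] = TraitVector(
                trait_id=f"{prefix}{met}",
                values=np.log10(vals.where(vals > 0)),
                transform_log="log10")
    return out


def run_pipeline(cfg: synthetic_data.SimulationConfig, out_dir: str | Path,
                 seed: int | None = None,
                 options: PipelineOptions | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> Path:
    """Run the synthetic study end to end; returns the output directory."""
    t0 = time.time()
    opts = options or PipelineOptions()
    seed = cfg.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(cfg, seed=seed)
    tables: dict[str, pd.DataFrame] = {}
    summary: list[str] = ["# epiRIL pipeline summary", ""]

    # ------------------------------------------------------------- simulate
    epi = synthetic_data.simulate_epigenotypes(cfg, seed=seed)
    ft = synthetic_data.simulate_flowering_time(epi, cfg, seed=seed + 1)
    dmr_probes, reversion_truth = synthetic_data.simulate_probe_methylation(
        epi, probes_per_dmr=cfg.probes_per_dmr,
        reversion_rate=cfg.reversion_rate, noise_sd=cfg.probe_noise_sd,
        seed=seed + 2)
    leaf, truth_leaf, extra_leaf = synthetic_data.simulate_metabolome(
        epi, cfg, tissue="leaf", seed=seed + 3, flowering_time=ft)
    flower, truth_flower, extra_flower = synthetic_data.simulate_metabolome(
        epi, cfg, tissue="flower", seed=seed + 4, flowering_time=ft)
    seqsim = synthetic_data.simulate_sequences(cfg, seed=seed + 5)
    regions = synthetic_data.probe_regions_from_gene_table(
        seqsim.gene_table, promoter_len=cfg.promoter_len)
    gene_probes, parent_calls = synthetic_data.simulate_gene_probes(
        epi, regions, probes_per_region=cfg.probes_per_dmr,
        noise_sd=cfg.probe_noise_sd, seed=seed + 6)
    eqtl_truth = [synthetic_data.PlantedQtl(t.qtl_marker, t.target_gene,
                                            effect=1.0, sign=-1)
                  for t in cfg.trans_targets]
    ct_table = synthetic_data.simulate_expression(epi, cfg, eqtl=eqtl_truth,
                                                  ct_sd=0.3, seed=seed + 7)

    # simulation artifacts are the inputs of every later stage
    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    write_epigenotypes(epi, inputs / "epigenotypes.csv", inputs / "marker_map.csv")
    write_probe_methylation(dmr_probes, inputs / "dmr_probes.csv")
    write_probe_methylation(gene_probes, inputs / "gene_probes.csv")
    write_metabolites(leaf, inputs / "metabolites_leaf.csv")
    write_metabolites(flower, inputs / "metabolites_flower.csv")
    ft.values.rename("flowering_time").to_csv(inputs / "flowering_time.csv",
                                              index_label="line")
    parent_calls.to_csv(inputs / "parent_probe_calls.csv")
    ct_table.to_csv(inputs / "expression_ct.csv", index_label="line",
                    float_format="%.6f")
    seqsim.write(inputs / "genome.fa", inputs / "genes.gff3",
                 inputs / "srna_wt.fa", inputs / "srna_ddm1.fa")
    if "simulate" in stages:
        write_results({
            "truth_metabolome_leaf": truth_leaf,
            "truth_metabolome_flower": truth_flower,
            "truth_trans_targets": seqsim.truth,
            "truth_genes": seqsim.gene_table,
            "truth_reversion": reversion_truth.reset_index(names="line"),
        }, out / "truth", config=dataclasses.asdict(cfg), seed=seed)

    # ----------------------------------------------------------- preprocess
    leaf_bc = metabolome.batch_correct(leaf)
    flower_bc = metabolome.batch_correct(flower)
    if "preprocess" in stages:
        cv = pd.DataFrame({
            "leaf": metabolome.coefficient_of_variation(leaf_bc),
            "flower": metabolome.coefficient_of_variation(flower_bc),
        })
        tables["cv"] = cv.reset_index(names="metabolite")
        det = pd.DataFrame({
            "leaf": metabolome.classify_detection(leaf_bc, extra_leaf["parent_flags"]),
            "flower": metabolome.classify_detection(flower_bc, extra_flower["parent_flags"]),
        })
        tables["detection_classes"] = det.reset_index(names="metabolite")
        cors = []
        for (a, b) in ((leaf_bc, leaf_bc), (flower_bc, flower_bc), (leaf_bc, flower_bc)):
            cs = metabolome.correlation_summary(a, b, threshold=opts.correlation_threshold)
            cors.append((f"{cs.tissue_pair[0]}-{cs.tissue_pair[1]}",
                         cs.fraction_correlated, cs.fraction_negative))
        tables["correlation_summary"] = pd.DataFrame(
            cors, columns=["tissue_pair", "fraction_correlated", "fraction_negative"])
        summary += ["## Metabolome", "",
                    f"- {len(leaf_bc.metabolites)} leaf / "
                    f"{len(flower_bc.metabolites)} flower metabolites",
                    f"- correlated fractions: " + ", ".join(
                        f"{t}: {f:.0%}" for t, f, _ in cors), ""]

    # --------------------------------------------------------------- mapqtl
    scanpos = mapping.genotype_probabilities(epi, step_cM=opts.step_cM)
    traits = {**_log10_traits(leaf_bc, "leaf:"), **_log10_traits(flower_bc, "flower:")}
    scans = []
    if "mapqtl" in stages or "cis" in stages or "trans" in stages:
        for i, (tid, trait) in enumerate(sorted(traits.items())):
            if trait.dropna().shape[0] < 10:
                continue
            scans.append(mapping.scan_trait(trait, epi, scanpos,
                                            n_perm=opts.n_perm, alpha=opts.alpha,
                                            seed=seed + 100 + i,
                                            lod_drop=opts.lod_drop))
        peak_tab = _concat_peak_tables(scans)
        tables["qtl_peaks"] = peak_tab
        regions_tab, pairs_tab = mapping.pleiotropy_regions(
            scans, traits={k: v for k, v in traits.items()})
        tables["pleiotropy_regions"] = regions_tab
        tables["pleiotropy_pairs"] = pairs_tab
        if opts.ft_correct:
            ft_scans = []
            raw_traits = {}
            for m in (leaf_bc, flower_bc):
                for met in m.metabolites:
                    raw_traits[f"{m.tissue}:{met}"] = TraitVector(
                        trait_id=f"{m.tissue}:{met}", values=m.intensities[met])
            for i, (tid, rt) in enumerate(sorted(raw_traits.items())):
                try:
                    corr = metabolome.flowering_correct(rt, ft)
                except ValueError:
                    continue
                vals = corr.values
                logt = TraitVector(trait_id=tid, values=np.log10(vals.where(vals > 0)),
                                   transform_log="log10", ft_corrected=True,
                                   ft_source=ft.trait_id)
                if logt.dropna().shape[0] < 10:
                    continue
                ft_scans.append(mapping.scan_trait(
                    logt, epi, scanpos, n_perm=opts.n_perm, alpha=opts.alpha,
                    seed=seed + 100 + i, lod_drop=opts.lod_drop))
            tables["qtl_peaks_ft_corrected"] = _concat_peak_tables(ft_scans)
        summary += ["## QTL mapping", "",
                    f"- {int((peak_tab['lod'] >= peak_tab['threshold']).sum())} "
                    f"QTL for {peak_tab['trait'].nunique()} traits "
                    f"({len(scans)} traits scanned)",
                    f"- {int((peak_tab['effect_sign'] < 0).sum())} peaks with "
                    "negative effect sign (higher in ddm1-derived epigenotypes)",
                    ""]

    # ------------------------------------------------------------------ cis
    if "cis" in stages or "trans" in stages:
        genes, fasta = read_annotation(inputs / "genes.gff3", inputs / "genome.fa",
                                       promoter_len=cfg.promoter_len)
    if "cis" in stages:
        with_peaks = [s for s in scans if s.peaks]
        records = cis_candidates.run_funnel(
            genes, with_peaks, gene_probes, traits, epi,
            alpha_assoc=opts.alpha_assoc, alpha_coseg=opts.alpha_coseg)
        tables["cis_funnel"] = cis_candidates.funnel_table(records)
        counts = cis_candidates.funnel_counts(records)
        summary += ["## cis-candidate funnel", "",
                    "- stage counts: " + " -> ".join(
                        f"{k}={v}" for k, v in counts.items()), ""]

    # ---------------------------------------------------------------- trans
    if "trans" in stages:
        with_peaks = [s for s in scans if s.peaks]
        hits = trans_srna.screen_trans_genes(
            gene_probes, genes, epi, with_peaks, parent_calls, alpha=opts.alpha_assoc)
        gene_index = {g.gene_id: g for g in genes}
        segments_by_gene: dict[str, list[trans_srna.MatchSegment]] = {}
        candidates_by_gene: dict[str, list] = {}
        segment_index: dict[str, trans_srna.MatchSegment] = {}
        coloc: dict[str, bool] = {}
        pad = cfg.marker_phys_spacing // 4
        for h in hits:
            g = gene_index[h.gene_id]
            prom_seq = str(fasta[g.chrom][g.promoter[0]:g.promoter[1]])
            lo_bp, hi_bp = cis_candidates.interval_to_bp(
                epi.markers, h.qtl_chrom, h.qtl_lo, h.qtl_hi)
            qtl_seq = str(fasta[h.qtl_chrom][max(0, int(lo_bp) - pad):int(hi_bp) + pad])
            segs = trans_srna.find_match_segments(
                prom_seq, qtl_seq, min_match=opts.min_match, gene_id=h.gene_id,
                id_prefix=f"{h.gene_id}.{h.trait_id}.seg")
            # a gene can pass the screen against several QTL; evidence is
            # aggregated over all of its hits
            segments_by_gene.setdefault(h.gene_id, []).extend(segs)
            cands = []
            for s in segs:
                segment_index[s.segment_id] = s
                cands.extend(trans_srna.decompose_artsrnas(s))
            cands = trans_srna.score_ago_loading(cands, min_prob=opts.ago_min)
            cands = trans_srna.match_srna_library(
                cands, [seqsim.wt_library, seqsim.ddm1_library])
            cands = trans_srna.annotate_te_proximity(cands, segment_index, gene_index)
            candidates_by_gene.setdefault(h.gene_id, []).extend(cands)
            if h.gene_id in ct_table.columns:
                expr = mapping.qpcr_normalize(ct_table, ["SAND", "TIP41"], h.gene_id)
                escan = methylation.eqtl_scan(expr, epi, scanpos=scanpos,
                                              n_perm=opts.n_perm, alpha=opts.alpha,
                                              seed=seed + 999)
                coloc[h.gene_id] = coloc.get(h.gene_id, False) or \
                    mapping.colocalize(escan, (h.qtl_chrom, h.qtl_lo, h.qtl_hi))
        report = trans_srna.trans_report(hits, segments_by_gene,
                                         candidates_by_gene, coloc)
        tables["trans_report"] = report
        summary += ["## trans targets", "",
                    f"- {len(hits)} genes passed the 5-criteria screen; "
                    f"top gene: {report['gene_id'].iloc[0] if len(report) else 'none'}",
                    ""]

    # --------------------------------------------------------------- report
    write_results(tables, out, config=dataclasses.asdict(cfg), seed=seed)
    if "report" in stages:
        summary.append(f"_completed in {time.time() - t0:.1f}s_")
        (out / "report.md").write_text("\n".join(summary) + "\n")
    return out
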
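"""Ground-truth simulators for every pipeline stage.

The generators emulate the structure of an epiRIL (Col-0 x *ddm1-2*)
metabolomics study at desk scale: a 126-DMR marker map over five
chromosomes, two parental epialleles per marker inherited through a Markov
chain along each chromosome, probe-level methylation posteriors coupled to
the local epigenotype with a reversion parameter, log-normal metabolite
intensities with batch effects and planted epiQTL effects in the 4-41%
range, presence/absence (transgressive) metabolites, flowering-time
pleiotropy, promoters carrying TE-derived segments copied from QTL
intervals, and WT/ddm1 small-RNA libraries depleted over hypomethylated
loci.

Every generator is a pure function of (config, seed) and returns its data
together with a ground-truth table listing the planted signals; downstream
recovery tests read only those tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    CALL_COL,
    CALL_DDM1,
    EpigenotypeMap,
    MarkerMap,
    MetaboliteMatrix,
    ProbeMethylation,
    SRNALibrary,
    TraitVector,
    revcomp,
)
from .mapping import haldane_r


@dataclass
class PlantedQtl:
    """One planted marker -> trait effect.

    ``effect`` is the fractional change on the raw intensity scale (0.41
    means a 41% shift between epiallele groups); ``sign`` follows the
    package's effect-sign convention: -1 means the trait is higher in
    DDM1-derived epigenotypes.
    """

    marker_id: str
    trait_id: str
    effect: float
    sign: int = -1

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ValueError("planted effects must be positive fractions")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


@dataclass
class TransTarget:
    """A planted trans-regulatory link: QTL interval -> distal gene promoter."""

    qtl_marker: str
    target_gene: str
    segment_len: int = 30


@dataclass
class SimulationConfig:
    """All knobs of the synthetic epiRIL study.

    Defaults mirror the study design being emulated: 126 DMR markers over
    five chromosomes, DDM1 epiallele frequency 0.3 (the backcross design
    biases toward Col-0 epialleles), planted effects as fractional shifts,
    four measurement batches, and a detection floor at 1% of the
    per-metabolite median intensity.
    """

    n_lines: int = 100
    markers_per_chrom: tuple[int, ...] = (26, 25, 25, 25, 25)
    marker_spacing_cM: float = 4.0
    marker_phys_spacing: int = 20_000
    marker_phys_len: int = 2_000
    p_ddm1: float = 0.3
    reversion_rate: float = 0.1
    probes_per_dmr: int = 3
    probe_noise_sd: float = 0.05
    # metabolome
    n_metabolites: int = 50
    baseline_log10_mean: float = 3.0
    baseline_log10_sd: float = 0.3
    n_batches: int = 4
    batch_sd_log10: float = 0.05
    block_size: int = 10
    block_sd_log10: float = 0.08
    noise_sd_log10: float = 0.1
    detection_floor_frac: float = 0.01
    planted_qtl: list[PlantedQtl] = field(default_factory=list)
    n_transgressive: int = 2
    n_col_only: int = 2
    n_ddm1_only: int = 2
    # flowering time
    ft_base_days: float = 30.0
    ft_noise_sd: float = 1.5
    ft_qtl: list[PlantedQtl] = field(default_factory=list)
    ft_pleiotropy_metabolites: list[str] = field(default_factory=list)
    # sequences / trans targets
    trans_targets: list[TransTarget] = field(default_factory=list)
    n_decoy_genes: int = 10
    cis_targets: list[tuple[str, str]] = field(default_factory=list)  # (gene, marker)
    cis_decoys_per_target: int = 3
    promoter_len: int = 1000
    gene_len: int = 1000
    repeat_len: int = 400
    srna_mean_count: int = 50
    srna_depletion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_ddm1 < 1.0):
            raise ValueError("p_ddm1 must lie in (0,1)")
        if self.probe_noise_sd < 0:
            raise ValueError("probe noise sd must be >= 0")


# ---------------------------------------------------------------------------
# Marker map and epigenotypes
# ---------------------------------------------------------------------------


def default_marker_map(cfg: SimulationConfig) -> MarkerMap:
    """Evenly spaced DMR markers: 5 chromosomes, 126 markers by default."""
    rows = []
    k = 0
    for c, n_mark in enumerate(cfg.markers_per_chrom, start=1):
        for j in range(n_mark):
            start = (j + 1) * cfg.marker_phys_spacing
            rows.append((f"MM{k + 1:03d}", f"chr{c}", j * cfg.marker_spacing_cM,
                         start, start + cfg.marker_phys_len))
            k += 1
    return MarkerMap(pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos_cM", "phys_start", "phys_end"]))


def chain_transition(r: np.ndarray | float, p: float) -> tuple:
    """Two-state chain rates with stationary DDM1 frequency ``p``.

    Detailed balance with stationary (1-p, p) plus independence at r=1/2
    force T(COL->DDM1) = 2rp and T(DDM1->COL) = 2r(1-p); adjacent-marker
    discordance is then 4 r p (1-p).
    """
    r = np.asarray(r, float)
    return 2.0 * r * p, 2.0 * r * (1.0 - p)


def simulate_epigenotypes(cfg: SimulationConfig, seed: int | None = None,
                          markers: MarkerMap | None = None) -> EpigenotypeMap:
    """Simulate epiRIL epigenotypes along the marker map.

    Per chromosome a two-state Markov chain over the ordered markers: the
    first marker is DDM1 with probability ``p_ddm1``; transitions between
    adjacent markers use the Haldane recombination fraction for the cM gap
    with the detailed-balance rates of :func:`chain_transition`, so the
    stationary DDM1 frequency is preserved along the chromosome.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    markers = markers or default_marker_map(cfg)
    p = cfg.p_ddm1
    cols: dict[str, np.ndarray] = {}
    for chrom in markers.chroms:
        mtab = markers.chrom_markers(chrom)
        pos = mtab["pos_cM"].to_numpy(float)
        ids = mtab["marker_id"].tolist()
        state = (rng.random(cfg.n_lines) < p).astype(int)
        cols[ids[0]] = state.copy()
        for j in range(1, len(ids)):
            r = haldane_r(pos[j] - pos[j - 1])
            t01, t10 = chain_transition(r, p)
            u = rng.random(cfg.n_lines)
            switch = np.where(state == 0, u < t01, u < t10)
            state = np.where(switch, 1 - state, state)
            cols[ids[j]] = state.copy()
    lines = [f"L{i + 1:04d}" for i in range(cfg.n_lines)]
    calls = pd.DataFrame(
        {m: np.where(v == 1, CALL_DDM1, CALL_COL) for m, v in cols.items()},
        index=lines)
    return EpigenotypeMap(markers=markers, calls=calls)


# ---------------------------------------------------------------------------
# Probe methylation
# ---------------------------------------------------------------------------


def simulate_probe_methylation(epi: EpigenotypeMap,
                               probes_per_dmr: int = 3,
                               reversion_rate: float = 0.1,
                               noise_sd: float = 0.05,
                               seed: int = 0,
                               ) -> tuple[ProbeMethylation, pd.DataFrame]:
    """MeDIP-like probe posteriors coupled to the local epigenotype.

    The latent state of every probe in a DMR is methylated (post_M = 1) for
    COL lines and unmethylated for DDM1 lines, except that each (line, DMR)
    pair reverts DDM1 back to WT-like methylation with probability
    ``reversion_rate``. Emitted ``post_M = clip(latent + N(0, sd), 0, 1)``.

    Returns the probe matrix and a ground-truth line x marker table of
    reversion events.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    coded = epi.coded().to_numpy(float)  # lines x markers; DDM1=1
    n_lines, n_mark = coded.shape
    reverted = (rng.random((n_lines, n_mark)) < reversion_rate) & (coded == 1.0)
    latent = np.where(np.isnan(coded), 0.5, np.where(coded == 0.0, 1.0, 0.0))
    latent = np.where(reverted, 1.0, latent)

    probe_rows = []
    post_rows = []
    mtab = epi.markers.table
    for j in range(n_mark):
        row = mtab.iloc[j]
        width = max(1, (row["phys_end"] - row["phys_start"]) // (probes_per_dmr + 1))
        for k in range(probes_per_dmr):
            start = int(row["phys_start"] + k * width)
            probe_rows.append((f"{row['marker_id']}_p{k + 1}", row["chrom"],
                               start, start + min(width, 60)))
            noise = rng.normal(0.0, noise_sd, n_lines) if noise_sd > 0 else 0.0
            post_rows.append(np.clip(latent[:, j] + noise, 0.0, 1.0))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "start", "end"])
    post_m = pd.DataFrame(np.vstack(post_rows), index=probes["probe_id"],
                          columns=epi.calls.index)
    truth = pd.DataFrame(reverted, index=epi.calls.index,
                         columns=epi.markers.marker_ids)
    return ProbeMethylation(probes=probes, post_m=post_m), truth


def simulate_gene_probes(epi: EpigenotypeMap,
                         regions: pd.DataFrame,
                         probes_per_region: int = 3,
                         noise_sd: float = 0.05,
                         seed: int = 0,
                         ) -> tuple[ProbeMethylation, pd.DataFrame]:
    """Probes inside gene regions, optionally coupled to a driver marker.

    ``regions`` needs columns ``region_id, chrom, start, end, driver_marker``.
    A named driver couples the region to that DMR (methylated for COL lines,
    hypomethylated for DDM1 lines; parents polymorphic). An empty driver
    models the common non-DMR promoter: stably methylated in every line and
    both parents. The special driver ``"random"`` gives an independent
    per-line methylation state (a variable but unlinked region).

    Returns the epiRIL probe matrix and a parent table of per-probe post_M
    for the two parents (columns ``Col``, ``ddm1``).
    """
    rng = np.random.default_rng(seed)
    coded = epi.coded()
    probe_rows, post_rows, parent_rows = [], [], []
    for _, reg in regions.iterrows():
        driver = reg.get("driver_marker", "")
        driver = driver if isinstance(driver, str) else ""
        if driver == "random":
            latent = (rng.random(len(coded)) < 0.5).astype(float)
            parent = (1.0, 1.0)
        elif driver != "":
            g = coded[driver].to_numpy(float)
            latent = np.where(np.isnan(g), 0.5, 1.0 - g)  # DDM1 -> hypomethylated
            parent = (1.0, 0.0)
        else:
            latent = np.ones(len(coded))
            parent = (1.0, 1.0)
        width = max(1, (reg["end"] - reg["start"]) // (probes_per_region + 1))
        for k in range(probes_per_region):
            start = int(reg["start"] + k * width)
            pid = f"{reg['region_id']}_p{k + 1}"
            probe_rows.append((pid, reg["chrom"], start, start + min(width, 60)))
            noise = rng.normal(0.0, noise_sd, len(coded)) if noise_sd > 0 else 0.0
            post_rows.append(np.clip(latent + noise, 0.0, 1.0))
            parent_rows.append((pid, parent[0], parent[1]))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "start", "end"])
    post_m = pd.DataFrame(np.vstack(post_rows), index=probes["probe_id"],
                          columns=coded.index)
    parents = pd.DataFrame(parent_rows, columns=["probe_id", "Col", "ddm1"]
                           ).set_index("probe_id")
    return ProbeMethylation(probes=probes, post_m=post_m), parents


# ---------------------------------------------------------------------------
# Flowering time and metabolome
# ---------------------------------------------------------------------------


def simulate_flowering_time(epi: EpigenotypeMap, cfg: SimulationConfig,
                            seed: int = 0) -> TraitVector:
    """Flowering time in days, with optional planted marker effects."""
    rng = np.random.default_rng(seed)
    coded = epi.coded()
    ft = np.full(len(coded), cfg.ft_base_days, float)
    for q in cfg.ft_qtl:
        g = coded[q.marker_id].fillna(cfg.p_ddm1).to_numpy(float)
        delta = cfg.ft_base_days * q.effect
        ft = ft + (-q.sign) * delta * g
    ft = ft + rng.normal(0.0, cfg.ft_noise_sd, len(ft))
    ft = np.maximum(ft, 1.0)
    return TraitVector(trait_id="flowering_time",
                       values=pd.Series(ft, index=coded.index))


def metabolite_names(cfg: SimulationConfig) -> list[str]:
    return [f"m{i + 1:03d}" for i in range(cfg.n_metabolites)]


def simulate_metabolome(epi: EpigenotypeMap, cfg: SimulationConfig,
                        tissue: str = "leaf", seed: int = 0,
                        flowering_time: TraitVector | None = None,
                        ) -> tuple[MetaboliteMatrix, pd.DataFrame, dict]:
    """Log-normal metabolite intensities with planted epiQTL effects.

    log10 intensity = baseline + sum(planted effects x epiallele indicator)
    + batch offset + block-correlated noise + iid noise. A planted
    fractional effect f shifts the affected epiallele group by
    ``log10(1 + f)``, i.e. a (1+f)-fold raw-scale group ratio. Transgressive
    metabolites are emitted above the detection floor only in lines carrying
    a specific two-marker DDM1/DDM1 combination and are absent in both
    simulated parents. Metabolites listed in ``ft_pleiotropy_metabolites``
    are proportional to flowering time (their marker signal flows entirely
    through FT).

    Returns (matrix, ground-truth table, parent detection flags).
    """
    rng = np.random.default_rng(seed)
    names = metabolite_names(cfg)
    known = set(names)
    for q in cfg.planted_qtl:
        if q.trait_id not in known:
            raise ValueError(f"planted effect references unknown trait {q.trait_id!r}")
    coded = epi.coded()
    n = len(coded)
    baseline = rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd, len(names))
    log10 = np.tile(baseline, (n, 1))

    truth_rows = []
    for q in cfg.planted_qtl:
        j = names.index(q.trait_id)
        g = coded[q.marker_id].fillna(cfg.p_ddm1).to_numpy(float)
        # sign -1: trait higher in DDM1 lines
        log10[:, j] += (-q.sign) * np.log10(1.0 + q.effect) * g
        truth_rows.append((tissue, q.trait_id, q.marker_id, q.effect, q.sign, "qtl"))

    # batch structure: round-robin assignment, per-(batch, metabolite) offsets
    batches = np.array([f"B{i % cfg.n_batches + 1}" for i in range(n)])
    for b in np.unique(batches):
        off = rng.normal(0.0, cfg.batch_sd_log10, len(names))
        log10[batches == b] += off

    # tissue-block correlated noise: shared latent factor per metabolite block
    for start in range(0, len(names), cfg.block_size):
        factor = rng.normal(0.0, cfg.block_sd_log10, n)
        log10[:, start:start + cfg.block_size] += factor[:, None]
    log10 += rng.normal(0.0, cfg.noise_sd_log10, log10.shape)

    intensities = pd.DataFrame(10.0 ** log10, index=coded.index, columns=names)

    # flowering-time pleiotropy: intensity proportional to FT
    if cfg.ft_pleiotropy_metabolites:
        if flowering_time is None:
            raise ValueError("ft_pleiotropy_metabolites requires a flowering_time vector")
        ftv = flowering_time.values.reindex(coded.index).to_numpy(float)
        rel = ftv / np.mean(ftv)
        for mname in cfg.ft_pleiotropy_metabolites:
            if mname not in known:
                raise ValueError(f"ft pleiotropy references unknown trait {mname!r}")
            base = 10.0 ** (baseline[names.index(mname)]
                            + rng.normal(0.0, cfg.noise_sd_log10, n))
            intensities[mname] = base * rel
            truth_rows.append((tissue, mname, "flowering_time", np.nan, 0,
                               "ft_pleiotropy"))

    # parent detection flags
    parent_flags = pd.DataFrame(True, index=names, columns=["Col", "ddm1"])
    pool = [m for m in names
            if m not in {q.trait_id for q in cfg.planted_qtl}
            and m not in cfg.ft_pleiotropy_metabolites]
    cursor = 0
    for m in pool[cursor:cursor + cfg.n_col_only]:
        parent_flags.loc[m, "ddm1"] = False
        truth_rows.append((tissue, m, "", np.nan, 0, "col_only"))
    cursor += cfg.n_col_only
    for m in pool[cursor:cursor + cfg.n_ddm1_only]:
        parent_flags.loc[m, "Col"] = False
        truth_rows.append((tissue, m, "", np.nan, 0, "ddm1_only"))
    cursor += cfg.n_ddm1_only

    # transgressive metabolites: need a DDM1/DDM1 two-marker combination
    marker_ids = epi.markers.marker_ids
    for t in range(cfg.n_transgressive):
        if cursor >= len(pool):
            break
        m = pool[cursor]
        cursor += 1
        m1 = marker_ids[(7 * t) % len(marker_ids)]
        m2 = marker_ids[(7 * t + len(marker_ids) // 2) % len(marker_ids)]
        combo = ((coded[m1] == 1.0) & (coded[m2] == 1.0)).to_numpy()
        vals = intensities[m].to_numpy()
        floor = cfg.detection_floor_frac * np.median(vals)
        vals = np.where(combo, vals, floor / 10.0)
        intensities[m] = vals
        parent_flags.loc[m] = [False, False]
        truth_rows.append((tissue, m, f"{m1}+{m2}", np.nan, 0, "transgressive"))

    # detection floor -> missingness
    med = intensities.median(axis=0)
    floor = cfg.detection_floor_frac * med
    intensities = intensities.mask(intensities.lt(floor, axis=1))

    matrix = MetaboliteMatrix(tissue=tissue, intensities=intensities,
                              batch=pd.Series(batches, index=coded.index))
    truth = pd.DataFrame(truth_rows, columns=["tissue", "trait_id", "marker_id",
                                              "effect", "sign", "kind"])
    return matrix, truth, {"parent_flags": parent_flags}


# ---------------------------------------------------------------------------
# Sequences: genome, annotation, sRNA libraries
# ---------------------------------------------------------------------------

_ALPHABET = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, length)])


@dataclass
class SequenceSim:
    """Output of :func:`simulate_sequences`."""

    genome: dict[str, str]
    gff_rows: pd.DataFrame
    qtl_repeats: dict[str, tuple[str, int, int]]  # marker -> (chrom, start, end)
    wt_library: SRNALibrary
    ddm1_library: SRNALibrary
    truth: pd.DataFrame
    gene_table: pd.DataFrame | None = None  # gene_id, chrom, promoter_start, role, driver_marker

    def write(self, fasta_path, gff_path, wt_path, ddm1_path) -> None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in self.gff_rows.iterrows():
                attrs = f"ID={r['feature_id']}"
                if r["family"]:
                    attrs += f";family={r['family']}"
                fh.write("\t".join([r["chrom"], "sim", r["type"],
                                    str(r["start"] + 1), str(r["end"]),
                                    ".", r["strand"], ".", attrs]) + "\n")
        for lib, path in ((self.wt_library, wt_path), (self.ddm1_library, ddm1_path)):
            with open(path, "w") as fh:
                for i, (_, row) in enumerate(lib.records.iterrows()):
                    fh.write(f">sRNA_{i + 1}|count={int(row['count'])}\n"
                             f"{row['sequence']}\n")


def simulate_sequences(cfg: SimulationConfig, seed: int = 0,
                       markers: MarkerMap | None = None) -> SequenceSim:
    """Random genome with TE-like repeats in QTL intervals and planted
    promoter copies for the configured trans targets.

    Each QTL marker named by a :class:`TransTarget` receives a TE-like
    repeat inside its physical interval. For every trans target an exact
    copy of a repeat segment (``segment_len`` >= the largest artsRNA window)
    is inserted into the target gene's promoter, within 1000 bp of a short
    annotated TE feature. The WT library holds 24-nt reads sampled from the
    repeat regions with Poisson counts; the ddm1 library covers the same
    loci with the mean scaled down by ``srna_depletion``.
    """
    rng = np.random.default_rng(seed)
    markers = markers or default_marker_map(cfg)
    max_window = 24
    for t in cfg.trans_targets:
        if t.segment_len < max_window:
            raise ValueError(
                f"segment_len {t.segment_len} below the largest artsRNA window")

    mtab = markers.table.set_index("marker_id")
    genome = {}
    for chrom in markers.chroms:
        clen = int(markers.chrom_markers(chrom)["phys_end"].max() + 50_000)
        genome[chrom] = _random_seq(rng, clen)

    gff_rows = []
    qtl_repeats: dict[str, tuple[str, int, int]] = {}
    repeat_seq: dict[str, str] = {}
    for t in cfg.trans_targets:
        if t.qtl_marker in qtl_repeats:
            continue
        row = mtab.loc[t.qtl_marker]
        chrom = row["chrom"]
        start = int(row["phys_start"])
        rep = _random_seq(rng, cfg.repeat_len)
        seq = genome[chrom]
        genome[chrom] = seq[:start] + rep + seq[start + cfg.repeat_len:]
        qtl_repeats[t.qtl_marker] = (chrom, start, start + cfg.repeat_len)
        repeat_seq[t.qtl_marker] = rep
        gff_rows.append((chrom, "transposable_element", start,
                         start + cfg.repeat_len, "+", f"TE_{t.qtl_marker}", "qtl_repeat"))

    # genes: trans targets first, then decoys, placed beyond the marker map
    # (hence outside every QTL interval), then cis targets/decoys inside
    # marker intervals
    target_ids = [t.target_gene for t in cfg.trans_targets]
    decoy_ids = [f"G{i + 1:03d}" for i in range(cfg.n_decoy_genes)]
    all_ids = target_ids + [g for g in decoy_ids if g not in target_ids]
    chroms = markers.chroms
    gene_pos: dict[str, tuple[str, int]] = {}
    gene_rows = []
    spacing = cfg.promoter_len + cfg.gene_len + 2_000
    per_chrom_cursor = {c: int(markers.chrom_markers(c)["phys_end"].max() + 5_000)
                        for c in chroms}
    trans_driver = {t.target_gene: t.qtl_marker for t in cfg.trans_targets}
    for i, gid in enumerate(all_ids):
        chrom = chroms[i % len(chroms)]
        start = per_chrom_cursor[chrom]
        per_chrom_cursor[chrom] += spacing
        if start + spacing > len(genome[chrom]):
            genome[chrom] = genome[chrom] + _random_seq(rng, spacing * 4)
        gene_pos[gid] = (chrom, start)
        # plus-strand gene: promoter [start, start+promoter_len), body after
        body_start = start + cfg.promoter_len
        gff_rows.append((chrom, "gene", body_start, body_start + cfg.gene_len,
                         "+", gid, ""))
        role = "trans_target" if gid in trans_driver else "decoy"
        gene_rows.append((gid, chrom, start, role, trans_driver.get(gid, "")))

    # cis candidates: the causal gene sits at its driver marker; decoys sit
    # at neighbouring markers (still inside the 1.5-LOD interval, typically)
    for gid, mid in cfg.cis_targets:
        row = mtab.loc[mid]
        chrom = row["chrom"]
        start = int(row["phys_start"]) + 10
        gene_pos[gid] = (chrom, start)
        gff_rows.append((chrom, "gene", start + cfg.promoter_len,
                         start + cfg.promoter_len + cfg.gene_len, "+", gid, ""))
        gene_rows.append((gid, chrom, start, "cis_target", mid))
        cmt = markers.chrom_markers(chrom).reset_index(drop=True)
        pos_in_chrom = int(cmt.index[cmt["marker_id"] == mid][0])
        placed = 0
        for off in (1, -1, 2, -2, 3, -3):
            if placed >= cfg.cis_decoys_per_target:
                break
            k = pos_in_chrom + off
            if not (0 <= k < len(cmt)):
                continue
            nrow = cmt.iloc[k]
            dgid = f"{gid}_decoy{placed + 1}"
            dstart = int(nrow["phys_start"]) + 10
            gene_pos[dgid] = (chrom, dstart)
            gff_rows.append((chrom, "gene", dstart + cfg.promoter_len,
                             dstart + cfg.promoter_len + cfg.gene_len, "+", dgid, ""))
            gene_rows.append((dgid, chrom, dstart, "cis_decoy", ""))
            placed += 1

    truth_rows = []
    for t in cfg.trans_targets:
        chrom, start = gene_pos[t.target_gene]
        rep = repeat_seq[t.qtl_marker]
        off_in_rep = int(rng.integers(0, cfg.repeat_len - t.segment_len + 1))
        segment = rep[off_in_rep:off_in_rep + t.segment_len]
        # insert mid-promoter, with a short TE feature annotated just upstream
        prom_off = cfg.promoter_len // 2
        ins = start + prom_off
        seq = genome[chrom]
        genome[chrom] = seq[:ins] + segment + seq[ins + t.segment_len:]
        te_start = max(0, ins - 300)
        gff_rows.append((chrom, "transposable_element", te_start, te_start + 100,
                         "+", f"TE_{t.target_gene}", "promoter_te"))
        truth_rows.append((t.target_gene, t.qtl_marker, chrom, ins,
                           t.segment_len, segment))

    # sRNA libraries from repeat regions (24-nt reads, stride 2)
    wt_rows, ddm1_rows = [], []
    lam = float(cfg.srna_mean_count)
    for marker, rep in repeat_seq.items():
        for off in range(0, len(rep) - 24 + 1, 2):
            read = rep[off:off + 24]
            if rng.random() < 0.5:
                read = revcomp(read)
            wt = int(rng.poisson(lam))
            dd = int(rng.poisson(lam / cfg.srna_depletion))
            if wt >= 1:
                wt_rows.append((read, wt))
            if dd >= 1:
                ddm1_rows.append((read, dd))
    if not wt_rows:
        wt_rows = [("A" * 24, 1)]
    if not ddm1_rows:
        ddm1_rows = [("C" * 24, 1)]
    wt_lib = SRNALibrary("WT", pd.DataFrame(wt_rows, columns=["sequence", "count"]))
    ddm1_lib = SRNALibrary("ddm1", pd.DataFrame(ddm1_rows, columns=["sequence", "count"]))

    gff = pd.DataFrame(gff_rows, columns=["chrom", "type", "start", "end",
                                          "strand", "feature_id", "family"])
    truth = pd.DataFrame(truth_rows, columns=["target_gene", "qtl_marker", "chrom",
                                              "insert_pos", "segment_len", "segment"])
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "chrom",
                                                  "promoter_start", "role",
                                                  "driver_marker"])
    return SequenceSim(genome=genome, gff_rows=gff, qtl_repeats=qtl_repeats,
                       wt_library=wt_lib, ddm1_library=ddm1_lib, truth=truth,
                       gene_table=gene_table)


def probe_regions_from_gene_table(gene_table: pd.DataFrame,
                                  promoter_len: int = 1000) -> pd.DataFrame:
    """Promoter probe regions (for :func:`simulate_gene_probes`) from the
    gene table emitted by :func:`simulate_sequences`."""
    rows = [(r["gene_id"], r["chrom"], int(r["promoter_start"]),
             int(r["promoter_start"]) + promoter_len, r["driver_marker"])
            for _, r in gene_table.iterrows()]
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                       "driver_marker"])


def demo_config(seed: int = 0, n_lines: int = 100) -> SimulationConfig:
    """A fully featured synthetic study: planted metabolite QTL spanning the
    4-41% effect range, one flowering-time QTL plus an FT-pleiotropic
    metabolite, one cis causal gene and three trans targets with decoys."""
    return SimulationConfig(
        n_lines=n_lines,
        planted_qtl=[
            PlantedQtl("MM010", "m001", effect=0.41, sign=-1),
            PlantedQtl("MM040", "m002", effect=0.25, sign=+1),
            PlantedQtl("MM080", "m003", effect=0.12, sign=-1),
            PlantedQtl("MM110", "m004", effect=0.04, sign=-1),
        ],
        ft_qtl=[PlantedQtl("MM060", "flowering_time", effect=0.15, sign=-1)],
        ft_pleiotropy_metabolites=["m005"],
        cis_targets=[("CIS001", "MM010")],
        trans_targets=[
            TransTarget("MM010", "T001", segment_len=30),
            TransTarget("MM040", "T002", segment_len=40),
            TransTarget("MM080", "T003", segment_len=30),
        ],
        n_decoy_genes=10,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# qPCR expression
# ---------------------------------------------------------------------------


def simulate_expression(epi: EpigenotypeMap, cfg: SimulationConfig,
                        eqtl: list[PlantedQtl] | None = None,
                        ref_mean: float = 25.0, ct_sd: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """qPCR Ct table with reference genes SAND and TIP41 plus targets.

    Reference Ct ~ Normal(ref_mean, sd); for each planted eQTL the target's
    relative expression is ``(1 + effect)``-fold between epiallele groups
    (sign convention as elsewhere) and ``Ct_target = mean(Ct_refs) -
    log2(relative expression)``.
    """
    rng = np.random.default_rng(seed)
    coded = epi.coded()
    n = len(coded)
    out = pd.DataFrame(index=coded.index)
    out["SAND"] = ref_mean + (rng.normal(0, ct_sd, n) if ct_sd > 0 else 0.0)
    out["TIP41"] = ref_mean + (rng.normal(0, ct_sd, n) if ct_sd > 0 else 0.0)
    for q in (eqtl or []):
        g = coded[q.marker_id].fillna(cfg.p_ddm1).to_numpy(float)
        log2rel = (-q.sign) * np.log2(1.0 + q.effect) * g
        if ct_sd > 0:
            log2rel = log2rel + rng.normal(0, ct_sd, n)
        out[q.trait_id] = out[["SAND", "TIP41"]].mean(axis=1) - log2rel
    return out
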
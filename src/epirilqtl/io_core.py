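"""Domain types, coordinate conventions, and readers/writers.

Conventions used throughout the package:

* All genomic intervals are **0-based half-open** ``[start, end)`` internally.
  GFF3 input (1-based inclusive) is converted on read and back on write.
* Epialleles are the two parental methylation states of an epiRIL marker:
  ``COL`` (Col-0 wild type, methylated at the DMR) and ``DDM1`` (*ddm1-2*
  derived, hypomethylated). For statistics they are coded COL=0, DDM1=1.
* Genetic positions are in centimorgan (cM); physical positions in bp.
* RNA sequences are normalized to the DNA alphabet (U -> T) at ingest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CALL_COL = "COL"
CALL_DDM1 = "DDM1"
MISSING_TOKENS = {"NA", "", "NAN", "MISSING"}

HYPOMETHYLATED = "hypomethylated"
METHYLATED = "methylated"

DETECTION_CLASSES = ("both_parents", "col_only", "ddm1_only", "epiRIL_only")


class ParseError(ValueError):
    """Malformed interchange file; readers reject rather than coerce."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered DMR marker map over (typically five) chromosomes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker_id, chrom, pos_cM, phys_start, phys_end`` with
        physical coordinates as 0-based half-open bp intervals. Markers are
        sorted by (chrom, pos_cM) on construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker_id", "chrom", "pos_cM", "phys_start", "phys_end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ParseError(f"marker map missing columns: {missing}")
        t = self.table.copy()
        t["chrom"] = t["chrom"].astype(str)
        t = t.sort_values(["chrom", "pos_cM"], kind="mergesort").reset_index(drop=True)
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ParseError(f"duplicate marker ids: {dups}")
        if (t["pos_cM"] < 0).any():
            raise ParseError("negative cM position in marker map")
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos_cM"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ParseError(f"cM positions not strictly increasing on {chrom}")
            iv = grp[["phys_start", "phys_end"]].to_numpy()
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            if np.any(iv[:, 1] < iv[:, 0]):
                raise ParseError(f"inverted physical interval on {chrom}")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ParseError(f"overlapping marker intervals on {chrom}")
        self.table = t

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EpigenotypeMap:
    """Line x marker epiallele calls on a marker map.

    ``calls`` is indexed by line id with one column per marker, values in
    {COL, DDM1, NaN}. Column order follows the marker map.
    """

    markers: MarkerMap
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.markers.marker_ids
        missing = [m for m in self.calls.columns if m not in set(ids)]
        if missing:
            raise ParseError(f"markers in calls absent from map: {missing}")
        absent = [m for m in ids if m not in self.calls.columns]
        if absent:
            raise ParseError(f"markers in map absent from calls: {absent}")
        if self.calls.index.duplicated().any():
            dups = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ParseError(f"duplicate line ids: {dups}")
        bad = set(pd.unique(self.calls.values.ravel())) - {CALL_COL, CALL_DDM1} - {np.nan}
        bad = {b for b in bad if isinstance(b, str)}
        if bad:
            raise ParseError(f"unknown call symbols: {sorted(bad)}")
        self.calls = self.calls[ids]

    @property
    def lines(self) -> list[str]:
        return self.calls.index.tolist()

    def coded(self) -> pd.DataFrame:
        """Numeric coding COL=0.0, DDM1=1.0, missing=NaN."""
        vals = self.calls.to_numpy(dtype=object)
        out = np.full(vals.shape, np.nan)
        out[vals == CALL_COL] = 0.0
        out[vals == CALL_DDM1] = 1.0
        return pd.DataFrame(out, index=self.calls.index, columns=self.calls.columns)

    def ddm1_frequency(self) -> pd.Series:
        return self.coded().mean(axis=0, skipna=True)


@dataclass
class ProbeMethylation:
    """Per-probe methylation posteriors and derived ML scores.

    ``probes`` holds probe coordinates (``probe_id, chrom, start, end``);
    ``post_m`` is a probe x line matrix of P(methylated). The ML score is
    derived as ``ml = -post_U + post_M = 2*post_M - 1`` and lies in [-1, 1].
    """

    probes: pd.DataFrame
    post_m: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.probes.columns]
        if missing:
            raise ParseError(f"probe table missing columns: {missing}")
        self.probes = self.probes.reset_index(drop=True)
        if not self.probes["probe_id"].is_unique:
            raise ParseError("duplicate probe ids")
        if list(self.post_m.index) != self.probes["probe_id"].tolist():
            self.post_m = self.post_m.loc[self.probes["probe_id"]]
        vals = self.post_m.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < -1e-9 or np.nanmax(vals, initial=1.0) > 1 + 1e-9:
                raise ParseError("posterior probabilities outside [0, 1]")

    @property
    def lines(self) -> list[str]:
        return self.post_m.columns.tolist()

    @property
    def ml(self) -> pd.DataFrame:
        """ML score matrix, probes x lines, in [-1, 1]."""
        return 2.0 * self.post_m - 1.0


@dataclass
class MetaboliteMatrix:
    """Line x metabolite raw intensities with batch labels per sample.

    ``intensities`` is indexed by line id; ``batch`` is a per-line label
    aligned to that index. ``detection_class`` (optional) maps each
    metabolite to one of the four detection classes.
    """

    tissue: str
    intensities: pd.DataFrame
    batch: pd.Series
    detection_class: pd.Series | None = None
    batch_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.batch.index.equals(self.intensities.index):
            self.batch = self.batch.reindex(self.intensities.index)
        if self.batch.isna().any():
            bad = self.batch.index[self.batch.isna()].tolist()
            raise ParseError(f"samples without batch label: {bad}")
        vals = self.intensities.to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ParseError("negative raw intensity")
        if self.detection_class is not None:
            bad = set(self.detection_class.dropna()) - set(DETECTION_CLASSES)
            if bad:
                raise ParseError(f"unknown detection classes: {sorted(bad)}")

    @property
    def lines(self) -> list[str]:
        return self.intensities.index.tolist()

    @property
    def metabolites(self) -> list[str]:
        return self.intensities.columns.tolist()


@dataclass
class TraitVector:
    """A single quantitative trait over the population lines."""

    trait_id: str
    values: pd.Series
    transform_log: str = "raw"  # "raw" | "log10"
    ft_corrected: bool = False
    ft_source: str | None = None

    def __post_init__(self) -> None:
        if self.transform_log not in ("raw", "log10"):
            raise ValueError(f"transform_log must be raw|log10, got {self.transform_log}")
        if self.ft_corrected and self.ft_source is None:
            raise ValueError("ft_corrected traits must record the flowering-time source")
        self.values = self.values.astype(float)

    def dropna(self) -> pd.Series:
        return self.values.dropna()


@dataclass
class QtlPeak:
    """One called QTL peak with its 1.5-LOD support interval."""

    chrom: str
    pos_cM: float
    lod: float
    ci_lo: float
    ci_hi: float
    effect_size: float
    effect_sign: int

    def __post_init__(self) -> None:
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect_sign must be -1 or +1")
        if not (self.ci_lo <= self.pos_cM <= self.ci_hi):
            raise ValueError("support interval must contain the peak")


@dataclass
class QtlScanResult:
    """LOD profile over scan positions plus threshold and called peaks.

    ``positions`` has columns ``chrom, cM, is_pseudomarker`` (and
    ``marker_id`` where the position is an observed marker); ``lod`` is the
    aligned per-position LOD score.
    """

    trait_id: str
    positions: pd.DataFrame
    lod: np.ndarray
    threshold: float | None = None
    peaks: list[QtlPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lod = np.asarray(self.lod, float)
        if len(self.lod) != len(self.positions):
            raise ValueError("lod length must match positions")
        if np.nanmin(self.lod, initial=0.0) < -1e-9:
            raise ValueError("negative LOD score")

    def max_lod(self) -> float:
        return float(np.nanmax(self.lod)) if len(self.lod) else 0.0

    def peak_table(self) -> pd.DataFrame:
        cols = ["trait", "chrom", "peak_cM", "lod", "threshold", "ci_lo", "ci_hi",
                "effect_size", "effect_sign"]
        rows = [
            (self.trait_id, p.chrom, p.pos_cM, p.lod, self.threshold, p.ci_lo,
             p.ci_hi, p.effect_size, p.effect_sign)
            for p in self.peaks
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class GeneModel:
    """Gene with strand-aware promoter / body / downstream intervals.

    All intervals 0-based half-open. ``te_features`` lists transposable
    elements near the gene as ``((start, end), family)`` tuples.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    promoter: tuple[int, int]
    gene_body: tuple[int, int]
    downstream_1kb: tuple[int, int]
    te_features: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    downstream_clipped: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.promoter[1] != self.tss:
            raise ValueError("plus-strand promoter must abut the TSS")
        if self.strand == "-" and self.promoter[0] != self.tss + 1:
            raise ValueError("minus-strand promoter must abut the TSS")
        if not self.downstream_clipped and self.downstream_1kb[1] - self.downstream_1kb[0] != 1000:
            raise ValueError("downstream interval must span 1000 bp unless clipped")

    def regions(self) -> dict[str, tuple[int, int]]:
        return {
            "promoter": self.promoter,
            "gene_body": self.gene_body,
            "downstream": self.downstream_1kb,
        }


@dataclass
class SRNALibrary:
    """Small-RNA reads (collapsed to unique sequences) with counts."""

    source: str  # "WT" | "ddm1"
    records: pd.DataFrame  # columns sequence, count

    def __post_init__(self) -> None:
        if self.source not in ("WT", "ddm1"):
            raise ParseError(f"sRNA library source must be WT|ddm1, got {self.source}")
        if (self.records["count"] < 1).any():
            raise ParseError("sRNA read counts must be >= 1")
        self.records = self.records.assign(
            sequence=self.records["sequence"].str.upper().str.replace("U", "T")
        )

    def count_index(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for seq, cnt in zip(self.records["sequence"], self.records["count"]):
            out[seq] = out.get(seq, 0) + int(cnt)
        return out


@dataclass
class ArtsRNACandidate:
    """An in-silico small RNA cut from a QTL/promoter shared segment."""

    sequence: str
    strand: str
    segment_id: str
    offset: int
    ago_scores: dict[str, float] = field(default_factory=dict)
    library_hits: dict[str, int] = field(default_factory=dict)
    te_within_1kb: bool | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        for ago, s in self.ago_scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"{ago} score outside [0,1]: {s}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a marker map CSV (marker_id, chrom, pos_cM, phys_start, phys_end)."""
    return MarkerMap(pd.read_csv(path, dtype={"chrom": str}))


def read_epigenotypes(calls_path: str | Path, map_path: str | Path) -> EpigenotypeMap:
    """Read epigenotype calls plus marker map.

    The calls CSV has marker ids as header, line ids in the first column, and
    cells in {COL, DDM1, NA}. Unknown symbols raise :class:`ParseError`
    naming the offending (line, marker) cell.
    """
    markers = read_marker_map(map_path)
    raw = pd.read_csv(calls_path, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    calls = raw.copy()
    for col in calls.columns:
        for line, val in calls[col].items():
            if pd.isna(val):
                continue
            v = str(val).strip()
            if v.upper() in MISSING_TOKENS:
                calls.loc[line, col] = np.nan
            elif v in (CALL_COL, CALL_DDM1):
                calls.loc[line, col] = v
            else:
                raise ParseError(
                    f"unknown call symbol {v!r} at (line={line}, marker={col})"
                )
    return EpigenotypeMap(markers=markers, calls=calls)


def write_epigenotypes(epi: EpigenotypeMap, calls_path: str | Path,
                       map_path: str | Path | None = None) -> None:
    epi.calls.fillna("NA").to_csv(calls_path, index_label="line")
    if map_path is not None:
        epi.markers.table.to_csv(map_path, index=False)


def read_probe_methylation(path: str | Path) -> ProbeMethylation:
    """Read long-format probe posteriors.

    Columns: ``probe_id, chrom, start, end, line, post_U, post_M``. The two
    posteriors must sum to 1 within 1e-6 per row.
    """
    df = pd.read_csv(path, dtype={"chrom": str, "line": str})
    required = ["probe_id", "chrom", "start", "end", "line", "post_U", "post_M"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"probe posterior file missing columns: {missing}")
    bad = np.abs(df["post_U"] + df["post_M"] - 1.0) > 1e-6
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise ParseError(
            f"post_U + post_M != 1 for probe {row['probe_id']} line {row['line']}"
        )
    probes = (
        df[["probe_id", "chrom", "start", "end"]]
        .drop_duplicates("probe_id")
        .reset_index(drop=True)
    )
    post_m = df.pivot(index="probe_id", columns="line", values="post_M")
    post_m = post_m.loc[probes["probe_id"]]
    post_m.columns.name = None
    return ProbeMethylation(probes=probes, post_m=post_m)


def write_probe_methylation(pm: ProbeMethylation, path: str | Path) -> None:
    long = pm.post_m.reset_index().melt(
        id_vars="probe_id", var_name="line", value_name="post_M"
    )
    long["post_U"] = 1.0 - long["post_M"]
    long = long.merge(pm.probes, on="probe_id")
    cols = ["probe_id", "chrom", "start", "end", "line", "post_U", "post_M"]
    long[cols].to_csv(path, index=False, float_format="%.10g")


def read_metabolites(path: str | Path, tissue: str) -> MetaboliteMatrix:
    """Read a wide metabolite CSV: line id index, `batch` column, metabolites."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if "batch" not in df.columns:
        raise ParseError("metabolite matrix requires a 'batch' column")
    batch = df["batch"].astype(str)
    intensities = df.drop(columns=["batch"]).astype(float)
    return MetaboliteMatrix(tissue=tissue, intensities=intensities, batch=batch)


def write_metabolites(m: MetaboliteMatrix, path: str | Path) -> None:
    out = m.intensities.copy()
    out.insert(0, "batch", m.batch)
    out.to_csv(path, index_label="line", float_format="%.10g")


def read_traits(path: str | Path) -> dict[str, TraitVector]:
    """Read a wide trait CSV (line id index, one column per trait)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return {
        c: TraitVector(trait_id=c, values=df[c].astype(float)) for c in df.columns
    }


def read_srna_fasta(path: str | Path, source: str) -> SRNALibrary:
    """Read an sRNA FASTA whose headers carry counts (``>id|count=142``)."""
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        count = 1
        for tok in header.split("|"):
            if tok.startswith("count="):
                try:
                    count = int(tok.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"bad count in header {header!r}") from exc
        rows.append((str(rec.seq).upper().replace("U", "T"), count))
    return SRNALibrary(source=source, records=pd.DataFrame(rows, columns=["sequence", "count"]))


def read_annotation(gff_path: str | Path, fasta_path: str | Path,
                    promoter_len: int = 1000):
    """Read gene/TE annotation plus genome sequence.

    Parameters
    ----------
    gff_path : path
        GFF3 with ``gene`` and ``transposable_element`` features (1-based
        inclusive coordinates, converted to 0-based half-open internally).
    fasta_path : path
        Genome FASTA; indexed with pyfaidx for random access.
    promoter_len : int
        Promoter extent upstream of the TSS, strand-aware, clipped at
        chromosome bounds.

    Returns
    -------
    (list[GeneModel], pyfaidx.Fasta)
    """
    import gffutils
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    chrom_len = {name: len(fasta[name]) for name in fasta.keys()}

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    tes_by_chrom: dict[str, list[tuple[tuple[int, int], str]]] = {}
    for te in db.features_of_type("transposable_element"):
        fam = te.attributes.get("family", ["unknown"])[0]
        tes_by_chrom.setdefault(te.seqid, []).append(((te.start - 1, te.end), fam))

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        chrom = g.seqid
        if chrom not in chrom_len:
            raise ParseError(f"chromosome {chrom} absent from FASTA")
        clen = chrom_len[chrom]
        start0, end0 = g.start - 1, g.end  # GFF 1-based inclusive -> half-open
        if start0 < 0 or end0 > clen:
            raise ParseError(f"gene {g.id} beyond bounds of {chrom}")
        strand = g.strand
        if strand == "+":
            tss = start0
            promoter = (max(0, tss - promoter_len), tss)
            downstream = (end0, min(clen, end0 + 1000))
            clipped = downstream[1] - downstream[0] != 1000
        else:
            tss = end0 - 1
            promoter = (end0, min(clen, end0 + promoter_len))
            downstream = (max(0, start0 - 1000), start0)
            clipped = downstream[1] - downstream[0] != 1000
        window = (max(0, start0 - promoter_len - 1000), end0 + promoter_len + 1000)
        near_tes = [
            (iv, fam) for iv, fam in tes_by_chrom.get(chrom, [])
            if iv[0] < window[1] and window[0] < iv[1]
        ]
        gene_id = g.attributes.get("ID", [g.id])[0]
        genes.append(GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
            promoter=promoter, gene_body=(start0, end0),
            downstream_1kb=downstream, te_features=near_tes,
            downstream_clipped=clipped,
        ))
    return genes, fasta


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _config_hash(config: Mapping | None) -> str:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  config: Mapping | None = None, seed: int | None = None) -> list[Path]:
    """Write stage output tables as CSV with a run manifest.

    Column order is preserved as given; floats use a fixed ``%.10g`` format so
    identical inputs produce byte-identical files. The manifest records the
    config hash and seed for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out / f"{name}.csv"
        tables[name].to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "tables": [p.name for p in written],
    }
    mpath = out / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def scan_result_table(results: Iterable[QtlScanResult]) -> pd.DataFrame:
    """Concatenate peak tables of several scans (header-only when no peaks)."""
    frames = [r.peak_table() for r in results]
    if not frames:
        return QtlScanResult("", pd.DataFrame(columns=["chrom", "cM", "is_pseudomarker"]),
                             np.zeros(0)).peak_table()
    return pd.concat(frames, ignore_index=True)


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
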
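"""Readers, writers and in-memory containers for the pipeline's file formats.

Internal coordinates are 1-based positions for CpGs and SNPs (the Bismark /
VCF convention).  BED input is 0-based half-open and converted on read; BED
output converts back.  Methylation counts are assumed destranded
(CpG-collapsed) upstream; no strand merging is performed here.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "GenotypeMatrix",
    "FeatureAnnotation",
    "FormatError",
    "CELL_TYPES",
    "SAMPLE_SHEET_COLUMNS",
    "ACPA_NEGATIVE_MAX_OD",
    "ACPA_MEDIUM_MAX_OD",
    "acpa_group_from_od",
    "read_methylation_counts",
    "write_methylation_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "read_genotypes",
    "write_genotypes",
    "read_bed",
    "write_bed",
    "read_annotations",
    "write_annotations",
    "chrom_sort_key",
    "is_autosome",
]


class FormatError(ValueError):
    """A file violates its declared dialect."""


#: Blood cell subtypes carried as model covariates, in sample-sheet order.
CELL_TYPES = ["monocyte", "lymphocyte", "neutrophil", "eosinophil", "basophil"]

SAMPLE_SHEET_COLUMNS = (
    ["sample_id", "acpa_od", "acpa_group", "ra", "age", "sex", "smoking"]
    + [f"prop_{c}" for c in CELL_TYPES]
)

# ACPA optical-density cut points: <=20 negative, 20-60 medium, >60 high.
ACPA_NEGATIVE_MAX_OD = 20.0
ACPA_MEDIUM_MAX_OD = 60.0

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def acpa_group_from_od(od: float) -> str:
    if od <= ACPA_NEGATIVE_MAX_OD:
        return "negative"
    if od <= ACPA_MEDIUM_MAX_OD:
        return "medium"
    return "high"


def chrom_sort_key(chrom: str):
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


def is_autosome(chrom) -> np.ndarray:
    """Boolean mask of autosomal chromosome names."""
    arr = np.asarray(chrom, dtype=object)
    return np.array([c not in _SEX_CHROMS for c in arr], dtype=bool)


# ---------------------------------------------------------------------------
# Methylation counts
# ---------------------------------------------------------------------------

@dataclass
class MethylationMatrix:
    """Per-CpG, per-sample methylated and total read counts.

    ``meth`` and ``total`` are (n_cpgs, n_samples) integer arrays; a missing
    observation is encoded as ``total == 0``.  CpGs are grouped by chromosome
    (natural order) with strictly increasing positions within each.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        self.sample_ids = list(self.sample_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if self.meth.shape != (self.n_cpgs, self.n_samples):
            raise ValueError("meth shape mismatch")
        if self.total.shape != self.meth.shape:
            raise ValueError("total shape mismatch")
        if (self.meth < 0).any() or (self.meth > self.total).any():
            raise ValueError("require 0 <= meth_reads <= total_reads")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: dict[str, int] = {}
        prev_chrom = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c} appears in two blocks")
                seen[c] = 1
                prev_chrom, prev_pos = c, p
            else:
                if p <= prev_pos:
                    raise ValueError(
                        f"positions not strictly increasing on {c} at {p}"
                    )
                prev_pos = p

    def ratios(self) -> np.ndarray:
        """Methylation ratios with NaN where the observation is missing."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.meth / np.where(self.total == 0, np.nan, self.total)
        return r

    def keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos],
                                         names=["chrom", "pos"])

    def subset_cpgs(self, idx) -> "MethylationMatrix":
        return MethylationMatrix(self.chrom[idx], self.pos[idx],
                                 self.meth[idx], self.total[idx],
                                 self.sample_ids)

    def subset_samples(self, idx) -> "MethylationMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ids = [self.sample_ids[i] for i in idx]
        return MethylationMatrix(self.chrom, self.pos,
                                 self.meth[:, idx], self.total[:, idx], ids)


def _sort_cpg_index(index: pd.MultiIndex) -> pd.MultiIndex:
    order = sorted(range(len(index)),
                   key=lambda i: (chrom_sort_key(index[i][0]), index[i][1]))
    return index[order]


def read_methylation_counts(paths, sample_ids) -> MethylationMatrix:
    """Read Bismark-coverage files into a union-of-CpGs count matrix.

    Each file has tab-separated columns chrom, start (1-based), end,
    methylation %, count_methylated, count_unmethylated.  The percentage
    column is ignored in favour of the counts.  A CpG absent from a sample's
    file gets ``total = 0`` for that sample.
    """
    paths = list(paths)
    sample_ids = list(sample_ids)
    if len(paths) != len(sample_ids):
        raise ValueError("paths and sample_ids differ in length")
    if not paths:
        raise FormatError("no input files")

    frames = []
    for path in paths:
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, comment=None,
                names=["chrom", "start", "end", "pct", "meth", "unmeth"],
                dtype={"chrom": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"{path}: malformed coverage file: {exc}") from exc
        for col in ("start", "end", "meth", "unmeth"):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                line = int(bad.index[bad.isna()][0]) + 1
                raise FormatError(f"{path}: line {line}: non-numeric {col!r}")
            df[col] = bad.astype(np.int64)
        neg = (df["meth"] < 0) | (df["unmeth"] < 0)
        if neg.any():
            line = int(df.index[neg][0]) + 1
            raise FormatError(f"{path}: line {line}: negative read count")
        dup = df.duplicated(subset=["chrom", "start"])
        if dup.any():
            line = int(df.index[dup][0]) + 1
            raise FormatError(f"{path}: line {line}: duplicate position")
        frames.append(df)

    union = None
    for df in frames:
        idx = pd.MultiIndex.from_arrays([df["chrom"], df["start"]],
                                        names=["chrom", "pos"])
        union = idx if union is None else union.union(idx, sort=False)
    union = _sort_cpg_index(union)

    n, s = len(union), len(sample_ids)
    meth = np.zeros((n, s), dtype=np.int64)
    total = np.zeros((n, s), dtype=np.int64)
    for j, df in enumerate(frames):
        idx = pd.MultiIndex.from_arrays([df["chrom"], df["start"]])
        locs = union.get_indexer(idx)
        meth[locs, j] = df["meth"].to_numpy()
        total[locs, j] = df["meth"].to_numpy() + df["unmeth"].to_numpy()

    m = MethylationMatrix(
        union.get_level_values(0).to_numpy(dtype=object),
        union.get_level_values(1).to_numpy(),
        meth, total, sample_ids,
    )
    m.validate()
    return m


def write_methylation_counts(m: MethylationMatrix, outdir,
                             suffix: str = ".cov") -> list[str]:
    """Write one Bismark-coverage file per sample; returns the paths.

    Missing observations (total = 0) are omitted, matching what a
    methylation caller would emit.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for j, sid in enumerate(m.sample_ids):
        mask = m.total[:, j] > 0
        me = m.meth[mask, j]
        to = m.total[mask, j]
        df = pd.DataFrame({
            "chrom": m.chrom[mask],
            "start": m.pos[mask],
            "end": m.pos[mask],
            "pct": np.round(100.0 * me / to, 6),
            "meth": me,
            "unmeth": to - me,
        })
        path = os.path.join(outdir, f"{sid}{suffix}")
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(samples: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id")
    bad_sex = ~samples["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise FormatError(f"invalid sex value {samples.loc[bad_sex, 'sex'].iloc[0]!r}")
    bad_smoke = ~samples["smoking"].isin(["current", "past", "never"])
    if bad_smoke.any():
        raise FormatError("invalid smoking value")
    props = samples[[f"prop_{c}" for c in CELL_TYPES]].to_numpy(dtype=float)
    if (props < 0).any() or (props > 1).any():
        raise FormatError("cell proportions must lie in [0, 1]")
    sums = props.sum(axis=1)
    if (np.abs(sums - 1.0) > 0.01).any():
        raise FormatError("cell proportions must sum to 1 +/- 0.01")
    expected = samples["acpa_od"].map(acpa_group_from_od)
    bad = expected != samples["acpa_group"]
    if bad.any():
        sid = samples.loc[bad, "sample_id"].iloc[0]
        raise FormatError(f"sample {sid}: acpa_group inconsistent with acpa_od")


def read_sample_sheet(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "ra" in samples.columns:
        samples["ra"] = samples["ra"].astype(bool)
    validate_sample_sheet(samples)
    return samples.reset_index(drop=True)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    validate_sample_sheet(samples)
    samples.to_csv(path, sep="\t", index=False, columns=SAMPLE_SHEET_COLUMNS)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Per-SNP alt-allele dosage calls (0/1/2, NaN = missing) plus read depth."""

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray          # (n_snps, n_samples) float, NaN missing
    depth: np.ndarray           # (n_snps, n_samples) int
    sample_ids: list[str]
    biallelic: np.ndarray = field(default=None)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.sample_ids = list(self.sample_ids)
        if self.biallelic is None:
            self.biallelic = np.ones(len(self.pos), dtype=bool)
        else:
            self.biallelic = np.asarray(self.biallelic, dtype=bool)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_snps(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.chrom[idx], self.pos[idx], self.ids[idx],
                              self.ref[idx], self.alt[idx],
                              self.dosage[idx], self.depth[idx],
                              self.sample_ids, self.biallelic[idx])


def read_genotypes(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix via cyvcf2.

    GT is converted to alt-allele dosage (0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    ./. -> missing); multi-allelic records are kept but flagged
    ``biallelic = False`` for the SNP filter.  DP is retained per call.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if not vcf.contains("GT"):
        raise FormatError(f"{path}: no GT field in FORMAT")
    sample_ids = list(vcf.samples)
    chrom, pos, ids, ref, alt, bial = [], [], [], [], [], []
    dosage_rows, depth_rows = [], []
    last = {}
    for v in vcf:
        if v.CHROM in last and v.POS < last[v.CHROM]:
            raise FormatError(f"{path}: unsorted VCF at {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        ref.append(v.REF)
        alt.append(",".join(v.ALT) if v.ALT else ".")
        bial.append(len(v.ALT) == 1)
        # gts012=True: 0/1/2 = dosage, 3 = unknown
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            depth_rows.append(np.zeros(len(sample_ids), dtype=np.int64))
        else:
            dp = np.asarray(dp, dtype=float).reshape(-1)
            dp[~np.isfinite(dp)] = 0
            depth_rows.append(dp.astype(np.int64))
    vcf.close()
    if not pos:
        raise FormatError(f"{path}: empty VCF")
    return GenotypeMatrix(chrom, pos, ids, ref, alt,
                          np.vstack(dosage_rows), np.vstack(depth_rows),
                          sample_ids, np.asarray(bial))


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
"""


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write dosages as a plain-text VCF with GT and DP."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for i in range(g.n_snps):
            calls = []
            for j in range(g.n_samples):
                d = g.dosage[i, j]
                gt = gt_map.get(d, "./.") if np.isfinite(d) else "./."
                calls.append(f"{gt}:{int(g.depth[i, j])}")
            fh.write("\t".join([
                str(g.chrom[i]), str(int(g.pos[i])), str(g.ids[i]),
                str(g.ref[i]), str(g.alt[i]), ".", "PASS", ".", "GT:DP",
            ] + calls) + "\n")


# ---------------------------------------------------------------------------
# Interval annotations (BED)
# ---------------------------------------------------------------------------

#: Track files looked up by read_annotations / written by write_annotations.
ANNOTATION_TRACKS = [
    "cgi", "gene", "tss", "first_exon", "exon", "intron",
    "utr5", "utr3", "tes", "autoimmune",
]


@dataclass
class FeatureAnnotation:
    """Named interval tracks in 1-based inclusive coordinates.

    Each track is a DataFrame with columns chrom, start, end and optionally
    name and strand.  Point features (TSS, TES) have start == end.
    """

    tracks: dict[str, pd.DataFrame]

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tracks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tracks

    def validate(self) -> None:
        for name, df in self.tracks.items():
            if (df["start"] > df["end"]).any():
                raise ValueError(f"track {name}: interval with start > end")
            for _, sub in df.groupby("chrom", sort=False):
                if not sub["start"].is_monotonic_increasing:
                    raise ValueError(f"track {name}: intervals not sorted")


def read_bed(path, track_name: str = "") -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=cols[: _bed_ncols(path)], dtype={0: str})
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: invalid BED interval (start >= end)")
    out = df.copy()
    out["start"] = df["start"].astype(np.int64) + 1
    out["end"] = df["end"].astype(np.int64)
    out = out.sort_values(
        ["chrom", "start"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    return out


def _bed_ncols(path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.rstrip("\n").split("\t")), 6)
    return 3


def write_bed(df: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    out = df.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in out.columns]
    out.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_annotations(directory) -> FeatureAnnotation:
    """Load the standard annotation tracks (``<track>.bed``) from a directory.

    Missing track files are simply absent from the annotation; downstream
    flags for them are all-False.
    """
    tracks = {}
    for name in ANNOTATION_TRACKS:
        path = os.path.join(directory, f"{name}.bed")
        if os.path.exists(path):
            tracks[name] = read_bed(path, name)
    if not tracks:
        raise FormatError(f"{directory}: no annotation tracks found")
    ann = FeatureAnnotation(tracks)
    ann.validate()
    return ann


def write_annotations(ann: FeatureAnnotation, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    for name, df in ann.tracks.items():
        write_bed(df, os.path.join(directory, f"{name}.bed"))
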
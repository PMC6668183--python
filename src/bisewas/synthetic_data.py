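"""Synthetic MCC-Seq-like study generator with known ground truth.

Emulates a whole-blood targeted bisulfite-sequencing cohort: ACPA-negative,
medium-positive and high-positive subjects plus a small self-reported RA
group, per-CpG read counts with negative-binomial coverage, measured blood
cell proportions, and SNP genotypes that either confound the ACPA signal or
act as plain cis-meQTLs.  Every planted effect is recorded in a
:class:`GroundTruth` object so downstream stages can be scored against it.

The generative model for the methylation probability of CpG *i* in sample
*s* is

    logit p_is = b_i + beta_dose * dose_s            (dose-effect CpGs)
               + gamma * (neut_s - mean(neut))       (cell-driven CpGs)
               + theta * dosage_is                   (genotype-driven CpGs)

with dose 0/1/2 for ACPA negative/medium/high and 3 for RA (disease taken to
extend the dose trend), and reads ~ Binomial(total_is, p_is) or beta-binomial
when an intra-CpG correlation rho > 0 is requested.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import (
    CELL_TYPES,
    ACPA_NEGATIVE_MAX_OD,
    ACPA_MEDIUM_MAX_OD,
    FeatureAnnotation,
    GenotypeMatrix,
    MethylationMatrix,
    acpa_group_from_od,
    validate_sample_sheet,
    write_annotations,
    write_genotypes,
    write_methylation_counts,
    write_sample_sheet,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_validation_cohort",
    "write_dataset",
    "score_dmr_calls",
    "score_classifications",
]

# Whole-blood differential means (fractions) for the Dirichlet draw.
_CELL_MEANS = np.array([0.07, 0.30, 0.575, 0.045, 0.01])
_CELL_CONCENTRATION = 150.0


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Group sizes default to the discovery cohort design: 66 ACPA-negative,
    45 medium-positive and 18 high-positive subjects (63 ACPA-positive in
    total) plus 8 self-reported RA subjects.  Mean coverage defaults to the
    15x average of the targeted panel.
    """

    n_neg: int = 66
    n_med: int = 45
    n_high: int = 18
    n_ra: int = 8
    n_cpgs: int = 50_000
    n_chroms: int = 10
    mean_coverage: float = 15.0
    coverage_dispersion: float = 3.0   # NB size; smaller = more overdispersed
    n_true_dmrs: int = 20
    effect_logit: float = 1.0          # per ordinal ACPA step, logit scale
    n_confounded_dmrs: int = 20
    confound_slope: float = 2.0        # logit per alt allele at confounded CpGs
    dose_region_meqtls: bool = True    # give dose regions a neutral cis-meQTL
    cell_effect_logit: float = 1.0
    n_cell_cpgs: int = 200
    cell_acpa_shift: float = 0.0       # neutrophil mean shift per dose step
    covariate_confounding: bool = False  # skew smoking with ACPA dose
    overdispersion_rho: float = 0.0    # 0 = pure binomial
    baseline_logit: float | None = None  # fixed baseline for all CpGs if set
    n_meqtl_snps: int = 50
    n_null_snps: int = 150
    meqtl_slope_logit: float = 1.5
    island_size: int = 10
    island_frac: float = 0.4
    chrom_length: int = 10_000_000
    x_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_neg", "n_med", "n_high", "n_ra", "n_cpgs", "n_chroms",
                     "n_true_dmrs", "n_confounded_dmrs", "n_cell_cpgs",
                     "n_meqtl_snps", "n_null_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_neg + self.n_med + self.n_high + self.n_ra <= 0:
            raise ValueError("at least one sample group must be non-empty")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if self.n_chroms < 1:
            raise ValueError("need at least one autosome")

    @property
    def n_samples(self) -> int:
        return self.n_neg + self.n_med + self.n_high + self.n_ra


@dataclass
class GroundTruth:
    """Planted effects of a simulated study.

    ``true_dmr_intervals`` rows are (chrom, start, end, direction,
    mechanism) with direction in {hypo, hyper} and mechanism in
    {dose, genotype-confounded}; intervals span the first to last CpG of a
    planted island and are mutually exclusive between mechanisms.
    ``true_meqtl_pairs`` rows are (snp_id, cpg_chrom, cpg_pos, slope) with
    the slope on the logit scale per alt allele.
    """

    true_dmr_intervals: list[tuple] = field(default_factory=list)
    true_meqtl_pairs: list[tuple] = field(default_factory=list)
    baseline_logit: np.ndarray = None
    cell_cpg_index: np.ndarray = None
    confounded_snp_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "true_dmr_intervals": [list(t) for t in self.true_dmr_intervals],
            "true_meqtl_pairs": [list(t) for t in self.true_meqtl_pairs],
            "baseline_logit": np.asarray(self.baseline_logit).tolist(),
            "cell_cpg_index": np.asarray(self.cell_cpg_index).tolist(),
            "confounded_snp_ids": list(self.confounded_snp_ids),
        })


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass
class _Genome:
    chrom: np.ndarray
    pos: np.ndarray
    islands: list[tuple]            # (chrom, start_idx, end_idx) CpG spans
    baseline: np.ndarray
    dose_effect: np.ndarray         # per-CpG logit effect per dose step
    geno_slope: np.ndarray          # per-CpG logit effect per alt allele
    geno_snp: np.ndarray            # per-CpG index into SNP table, -1 = none
    cell_idx: np.ndarray
    truth: GroundTruth
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    snp_ids: np.ndarray
    snp_af: np.ndarray              # base allele frequency
    snp_af_dose_shift: np.ndarray   # AF shift per dose step (confounders)
    annotation: FeatureAnnotation


def _layout_genome(cfg: SimulationConfig, rng: np.random.Generator) -> _Genome:
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_x = int(round(cfg.n_cpgs * cfg.x_frac))
    n_auto = cfg.n_cpgs - n_x
    per_chrom = [n_auto // cfg.n_chroms] * cfg.n_chroms
    per_chrom[-1] += n_auto - sum(per_chrom)

    chrom_col, pos_col, islands = [], [], []
    for cname, n_c in zip(chroms, per_chrom, strict=True):
        c_chrom, c_pos, c_isl = _layout_chromosome(cfg, rng, cname, n_c)
        offset = sum(len(p) for p in pos_col)
        islands.extend((cname, offset + a, offset + b) for a, b in c_isl)
        chrom_col.append(np.full(len(c_pos), cname, dtype=object))
        pos_col.append(c_pos)
    if n_x > 0:
        c_chrom, c_pos, _ = _layout_chromosome(cfg, rng, "chrX", n_x)
        chrom_col.append(np.full(len(c_pos), "chrX", dtype=object))
        pos_col.append(c_pos)

    chrom_arr = np.concatenate(chrom_col)
    pos_arr = np.concatenate(pos_col)
    n = len(pos_arr)

    # Baseline methylation: islands hypomethylated, background hypermethylated,
    # unless a fixed baseline is requested.
    baseline = np.empty(n)
    in_island = np.zeros(n, dtype=bool)
    for _, a, b in islands:
        in_island[a:b] = True
    if cfg.baseline_logit is not None:
        baseline[:] = cfg.baseline_logit
    else:
        baseline[in_island] = rng.normal(-2.5, 0.7, in_island.sum())
        baseline[~in_island] = rng.normal(2.0, 0.9, (~in_island).sum())

    n_planted = cfg.n_true_dmrs + cfg.n_confounded_dmrs
    if n_planted > len(islands):
        raise ValueError(
            f"n_true_dmrs + n_confounded_dmrs = {n_planted} exceeds the "
            f"{len(islands)} available CpG islands")
    picked = rng.choice(len(islands), size=n_planted, replace=False)
    dose_islands = picked[: cfg.n_true_dmrs]
    conf_islands = picked[cfg.n_true_dmrs:]

    dose_effect = np.zeros(n)
    geno_slope = np.zeros(n)
    geno_snp = np.full(n, -1, dtype=np.int64)
    truth = GroundTruth(baseline_logit=baseline)

    snp_chrom, snp_pos, snp_ids = [], [], []
    snp_af, snp_shift = [], []

    def _add_snp(cname, p, af, shift):
        sid = f"snp_{len(snp_ids)}"
        snp_chrom.append(cname)
        snp_pos.append(int(p))
        snp_ids.append(sid)
        snp_af.append(af)
        snp_shift.append(shift)
        return sid

    for k, isl in enumerate(dose_islands):
        cname, a, b = islands[isl]
        sign = 1.0 if k % 2 == 0 else -1.0
        dose_effect[a:b] = sign * cfg.effect_logit
        if cfg.baseline_logit is None:
            baseline[a:b] = rng.normal(0.0, 0.4, b - a)
        truth.true_dmr_intervals.append(
            (cname, int(pos_arr[a]), int(pos_arr[b - 1]),
             "hyper" if sign > 0 else "hypo", "dose"))
        if cfg.dose_region_meqtls:
            # an ACPA-independent meQTL at the same CpGs keeps the region
            # genetically testable without confounding the dose signal
            slope = (1.0 if k % 3 else -1.0) * cfg.meqtl_slope_logit * 0.6
            p0 = max(1, pos_arr[a] + int(rng.integers(-10_000, 10_000)))
            sid = _add_snp(cname, p0, float(rng.uniform(0.2, 0.5)), 0.0)
            geno_slope[a:b] = slope
            geno_snp[a:b] = len(snp_ids) - 1
            for i in range(a, b):
                truth.true_meqtl_pairs.append(
                    (sid, cname, int(pos_arr[i]), slope))

    for k, isl in enumerate(conf_islands):
        cname, a, b = islands[isl]
        sign = 1.0 if k % 2 == 0 else -1.0
        slope = sign * cfg.confound_slope
        if cfg.baseline_logit is None:
            baseline[a:b] = rng.normal(0.0, 0.4, b - a)
        p0 = pos_arr[a] + int(rng.integers(-10_000, 10_000))
        # AF 0.2 in ACPA-negative rising 0.15 per dose step -> 0.5 at high
        sid = _add_snp(cname, max(1, p0), 0.2, 0.15)
        sidx = len(snp_ids) - 1
        geno_slope[a:b] = slope
        geno_snp[a:b] = sidx
        truth.true_dmr_intervals.append(
            (cname, int(pos_arr[a]), int(pos_arr[b - 1]),
             "hyper" if sign > 0 else "hypo", "genotype-confounded"))
        truth.confounded_snp_ids.append(sid)
        for i in range(a, b):
            truth.true_meqtl_pairs.append((sid, cname, int(pos_arr[i]), slope))

    # Plain cis-meQTL SNPs: genotype drives one mid-methylation background CpG.
    autosomal_bg = np.flatnonzero(~in_island & (chrom_arr != "chrX")
                                  & (geno_snp < 0) & (dose_effect == 0))
    rng.shuffle(autosomal_bg)
    n_meqtl = min(cfg.n_meqtl_snps, len(autosomal_bg))
    for k in range(n_meqtl):
        i = autosomal_bg[k]
        slope = (1.0 if k % 2 == 0 else -1.0) * cfg.meqtl_slope_logit
        if cfg.baseline_logit is None:
            baseline[i] = rng.normal(0.0, 0.4)
        p0 = max(1, int(pos_arr[i]) + int(rng.integers(-50_000, 50_000)))
        sid = _add_snp(chrom_arr[i], p0, float(rng.uniform(0.1, 0.5)), 0.0)
        geno_slope[i] = slope
        geno_snp[i] = len(snp_ids) - 1
        truth.true_meqtl_pairs.append((sid, chrom_arr[i], int(pos_arr[i]), slope))

    # Neutral SNPs with no methylation effect.
    for _ in range(cfg.n_null_snps):
        cname = chroms[int(rng.integers(0, cfg.n_chroms))]
        p0 = int(rng.integers(1, cfg.chrom_length))
        _add_snp(cname, p0, float(rng.uniform(0.1, 0.5)), 0.0)

    # Cell-type-driven CpGs on autosomal background, outside planted islands.
    pool = autosomal_bg[n_meqtl:]
    cell_idx = np.sort(pool[: cfg.n_cell_cpgs]).astype(np.int64)
    truth.cell_cpg_index = cell_idx
    if cfg.baseline_logit is None and len(cell_idx):
        baseline[cell_idx] = rng.normal(0.0, 0.4, len(cell_idx))

    order = np.lexsort((snp_pos, [_chrom_rank(c) for c in snp_chrom])) \
        if snp_ids else np.array([], dtype=int)
    annotation = _build_annotation(cfg, rng, chroms, chrom_arr, pos_arr,
                                   islands, np.asarray(snp_chrom, dtype=object)[order]
                                   if len(order) else np.array([], dtype=object),
                                   np.asarray(snp_pos)[order]
                                   if len(order) else np.array([], dtype=int))

    return _Genome(
        chrom=chrom_arr, pos=pos_arr, islands=islands, baseline=baseline,
        dose_effect=dose_effect, geno_slope=geno_slope,
        geno_snp=_reindex_snps(geno_snp, order), cell_idx=cell_idx,
        truth=truth,
        snp_chrom=np.asarray(snp_chrom, dtype=object)[order] if len(order) else np.array([], dtype=object),
        snp_pos=np.asarray(snp_pos, dtype=np.int64)[order] if len(order) else np.array([], dtype=np.int64),
        snp_ids=np.asarray(snp_ids, dtype=object)[order] if len(order) else np.array([], dtype=object),
        snp_af=np.asarray(snp_af)[order] if len(order) else np.array([]),
        snp_af_dose_shift=np.asarray(snp_shift)[order] if len(order) else np.array([]),
        annotation=annotation,
    )


def _chrom_rank(c: str) -> int:
    return 10_000 if c == "chrX" else int(c.replace("chr", ""))


def _reindex_snps(geno_snp: np.ndarray, order: np.ndarray) -> np.ndarray:
    if len(order) == 0:
        return geno_snp
    inv = np.empty(len(order), dtype=np.int64)
    inv[order] = np.arange(len(order))
    out = geno_snp.copy()
    mask = geno_snp >= 0
    out[mask] = inv[geno_snp[mask]]
    return out


def _layout_chromosome(cfg, rng, cname, n_c):
    """CpG positions: clustered islands plus dispersed background."""
    n_island_cpgs = int(round(n_c * cfg.island_frac))
    n_islands = max(0, n_island_cpgs // cfg.island_size)
    n_bg = n_c - n_islands * cfg.island_size

    island_starts = np.sort(rng.choice(
        np.arange(10_000, cfg.chrom_length - 10_000, 20_000),
        size=n_islands, replace=False)) if n_islands else np.array([], int)
    positions, spans = [], []
    for s in island_starts:
        gaps = rng.integers(15, 40, cfg.island_size - 1)
        pos = s + np.concatenate([[0], np.cumsum(gaps)])
        positions.append(pos)
        spans.append(pos)
    bg = rng.choice(np.arange(1, cfg.chrom_length), size=n_bg, replace=False) \
        if n_bg else np.array([], int)
    allpos = np.unique(np.concatenate(positions + [bg])
                       if positions or len(bg) else np.array([], int))
    # rare collisions between island and background positions reduce the count;
    # top up from fresh background draws
    while len(allpos) < n_c:
        extra = rng.integers(1, cfg.chrom_length, n_c - len(allpos))
        allpos = np.unique(np.concatenate([allpos, extra]))
    allpos = allpos[:n_c] if len(allpos) > n_c else allpos

    islands = []
    for pos in spans:
        a = int(np.searchsorted(allpos, pos[0]))
        b = int(np.searchsorted(allpos, pos[-1], side="right"))
        if b - a >= 3:
            islands.append((a, b))
    return cname, allpos.astype(np.int64), islands


def _build_annotation(cfg, rng, chroms, chrom_arr, pos_arr, islands,
                      snp_chrom, snp_pos) -> FeatureAnnotation:
    """Derive BED-style tracks: CGIs from the island layout, a simple gene
    model per chromosome, and autoimmune-SNP windows around a subset of SNPs."""
    cgi_rows = []
    for cname, a, b in islands:
        cgi_rows.append((cname, int(pos_arr[a]), int(pos_arr[b - 1])))
    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])

    gene_rows, tss_rows, tes_rows = [], [], []
    fex_rows, ex_rows, in_rows, u5_rows, u3_rows = [], [], [], [], []
    for cname in chroms + (["chrX"] if cfg.x_frac > 0 else []):
        n_genes = 30
        starts = np.sort(rng.choice(
            np.arange(50_000, cfg.chrom_length - 150_000, 5000),
            size=n_genes, replace=False))
        for gi, gs in enumerate(starts):
            glen = int(rng.integers(20_000, 100_000))
            ge = gs + glen
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"{cname}_g{gi}"
            gene_rows.append((cname, int(gs), int(ge), name, 0, strand))
            tss = gs if strand == "+" else ge
            tes = ge if strand == "+" else gs
            tss_rows.append((cname, int(tss), int(tss), name, 0, strand))
            tes_rows.append((cname, int(tes), int(tes), name, 0, strand))
            n_ex = int(rng.integers(3, 8))
            bounds = np.sort(rng.choice(np.arange(gs, ge), 2 * n_ex, replace=False))
            exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1]))
                     for k in range(n_ex)]
            if strand == "-":
                exons = exons[::-1]
            for k, (ea, eb) in enumerate(exons):
                if ea >= eb:
                    continue
                ex_rows.append((cname, ea, eb, name, 0, strand))
                if k == 0:
                    fex_rows.append((cname, ea, eb, name, 0, strand))
                    u5 = (ea, min(eb, ea + 200)) if strand == "+" \
                        else (max(ea, eb - 200), eb)
                    u5_rows.append((cname, u5[0], u5[1], name, 0, strand))
                if k == n_ex - 1:
                    u3 = (max(ea, eb - 300), eb) if strand == "+" \
                        else (ea, min(eb, ea + 300))
                    u3_rows.append((cname, u3[0], u3[1], name, 0, strand))
            ordered = sorted(exons)
            for (_, ea_end), (eb_start, _) in zip(ordered[:-1], ordered[1:]):
                if eb_start > ea_end + 1:
                    in_rows.append((cname, ea_end + 1, eb_start - 1, name, 0, strand))

    cols6 = ["chrom", "start", "end", "name", "score", "strand"]
    tracks = {
        "cgi": cgi,
        "gene": pd.DataFrame(gene_rows, columns=cols6),
        "tss": pd.DataFrame(tss_rows, columns=cols6),
        "tes": pd.DataFrame(tes_rows, columns=cols6),
        "first_exon": pd.DataFrame(fex_rows, columns=cols6),
        "exon": pd.DataFrame(ex_rows, columns=cols6),
        "intron": pd.DataFrame(in_rows, columns=cols6),
        "utr5": pd.DataFrame(u5_rows, columns=cols6),
        "utr3": pd.DataFrame(u3_rows, columns=cols6),
    }
    if len(snp_pos):
        pick = rng.random(len(snp_pos)) < 0.3
        ai = pd.DataFrame({
            "chrom": snp_chrom[pick],
            "start": np.maximum(1, snp_pos[pick] - 200),
            "end": snp_pos[pick] + 200,
        })
        tracks["autoimmune"] = ai
    from .io_formats import chrom_sort_key
    for name, df in tracks.items():
        tracks[name] = df.sort_values(
            ["chrom", "start"],
            key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        ).reset_index(drop=True)
    ann = FeatureAnnotation(tracks)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _truncated_lognormal(rng, mu, sigma, lo, hi, size):
    out = np.empty(size)
    remaining = np.arange(size)
    while len(remaining):
        draw = rng.lognormal(mu, sigma, len(remaining))
        ok = (draw > lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _simulate_samples(cfg: SimulationConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample sheet plus the latent dose vector (0/1/2, RA = 3)."""
    groups = (["negative"] * cfg.n_neg + ["medium"] * cfg.n_med
              + ["high"] * cfg.n_high)
    dose = np.array([0] * cfg.n_neg + [1] * cfg.n_med + [2] * cfg.n_high
                    + [3] * cfg.n_ra, dtype=float)

    od = np.concatenate([
        _truncated_lognormal(rng, np.log(8.0), 0.6, 0.0,
                             ACPA_NEGATIVE_MAX_OD, cfg.n_neg),
        _truncated_lognormal(rng, np.log(42.0), 0.25, ACPA_NEGATIVE_MAX_OD,
                             ACPA_MEDIUM_MAX_OD, cfg.n_med),
        ACPA_MEDIUM_MAX_OD + rng.lognormal(np.log(30.0), 0.7, cfg.n_high),
    ])
    # RA subjects: mostly ACPA-positive (medium-range OD), a couple negative.
    n_ra_neg = min(2, cfg.n_ra)
    ra_od = np.concatenate([
        _truncated_lognormal(rng, np.log(8.0), 0.6, 0.0,
                             ACPA_NEGATIVE_MAX_OD, n_ra_neg),
        _truncated_lognormal(rng, np.log(42.0), 0.25, ACPA_NEGATIVE_MAX_OD,
                             ACPA_MEDIUM_MAX_OD, cfg.n_ra - n_ra_neg),
    ])
    od = np.concatenate([od, ra_od])
    acpa_group = [acpa_group_from_od(v) for v in od]

    n = cfg.n_samples
    ra = np.array([False] * (n - cfg.n_ra) + [True] * cfg.n_ra)
    sex = np.where(rng.random(n) < 0.65, "F", "M")
    sex[ra] = "F"  # the RA group is all female in the emulated design
    age = rng.uniform(40.0, 70.0, n).round(1)

    smoke_p = np.array([0.20, 0.42, 0.38])
    if cfg.covariate_confounding:
        # current-smoker probability rises with ACPA dose
        smoking = []
        for d in np.minimum(dose, 2):
            p = smoke_p + np.array([0.15, 0.0, -0.15]) * d / 2.0
            p = np.clip(p, 0.01, None); p /= p.sum()
            smoking.append(rng.choice(["current", "past", "never"], p=p))
        smoking = np.array(smoking)
    else:
        smoking = rng.choice(["current", "past", "never"], size=n, p=smoke_p)

    props = np.empty((n, 5))
    for i in range(n):
        means = _CELL_MEANS.copy()
        if cfg.cell_acpa_shift != 0.0:
            shift = cfg.cell_acpa_shift * min(dose[i], 2)
            means[2] += shift          # neutrophil
            means[1] -= shift          # taken from lymphocyte
            means = np.clip(means, 1e-3, None)
            means /= means.sum()
        props[i] = rng.dirichlet(means * _CELL_CONCENTRATION)

    samples = pd.DataFrame({
        "sample_id": [f"S{i + 1:03d}" for i in range(n)],
        "acpa_od": np.round(od, 2),
        "acpa_group": acpa_group,
        "ra": ra,
        "age": age,
        "sex": sex,
        "smoking": smoking,
    })
    for k, c in enumerate(CELL_TYPES):
        samples[f"prop_{c}"] = props[:, k]
    validate_sample_sheet(samples)
    return samples, dose


def _simulate_genotypes(genome: _Genome, dose: np.ndarray, rng,
                        sample_ids: list[str]) -> GenotypeMatrix:
    n_snps, n = len(genome.snp_pos), len(dose)
    dosage = np.empty((n_snps, n))
    d_eff = np.minimum(dose, 2.0)
    for i in range(n_snps):
        af = np.clip(genome.snp_af[i] + genome.snp_af_dose_shift[i] * d_eff,
                     0.01, 0.99)
        dosage[i] = rng.binomial(2, af)
    depth = rng.negative_binomial(8, 8 / (8 + 30.0), size=(n_snps, n))
    missing = rng.random((n_snps, n)) < 0.02
    dosage[missing] = np.nan
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, n_snps)]
    alt = np.array([bases[(list(bases).index(r) + 1 + rng.integers(0, 3)) % 4]
                    for r in ref], dtype=object)
    return GenotypeMatrix(genome.snp_chrom, genome.snp_pos, genome.snp_ids,
                          ref, alt, dosage, depth, sample_ids)


def _simulate_counts(cfg, genome: _Genome, dose, props, geno_dosage, rng
                     ) -> tuple[np.ndarray, np.ndarray]:
    n_cpgs, n = len(genome.pos), len(dose)
    nb_r = cfg.coverage_dispersion
    total = rng.negative_binomial(
        nb_r, nb_r / (nb_r + cfg.mean_coverage), size=(n_cpgs, n))

    eta = np.repeat(genome.baseline[:, None], n, axis=1)
    has_dose = genome.dose_effect != 0
    if has_dose.any():
        eta[has_dose] += np.outer(genome.dose_effect[has_dose], dose)
    neut = props[:, 2]
    if len(genome.cell_idx):
        centred = neut - neut.mean()
        eta[genome.cell_idx] += cfg.cell_effect_logit * centred[None, :]
    has_geno = genome.geno_snp >= 0
    if has_geno.any():
        dos = geno_dosage[genome.geno_snp[has_geno]]
        dos = np.nan_to_num(dos, nan=0.0)  # untyped samples sit at reference
        eta[has_geno] += genome.geno_slope[has_geno, None] * dos

    p = expit(eta)
    if cfg.overdispersion_rho > 0:
        rho = cfg.overdispersion_rho
        scale = (1.0 - rho) / rho
        a = np.clip(p * scale, 1e-6, None)
        b = np.clip((1.0 - p) * scale, 1e-6, None)
        p = rng.beta(a, b)
    meth = rng.binomial(total, p)
    return meth, total


def simulate_dataset(config: SimulationConfig):
    """Generate a complete synthetic study.

    Returns ``(methylation, samples, genotypes, annotation, truth)``; the
    same seed yields byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = _layout_genome(config, rng)
    samples, dose = _simulate_samples(config, rng)
    props = samples[[f"prop_{c}" for c in CELL_TYPES]].to_numpy()
    genotypes = _simulate_genotypes(genome, dose, rng, list(samples["sample_id"]))
    meth, total = _simulate_counts(config, genome, dose, props,
                                   genotypes.dosage, rng)
    m = MethylationMatrix(genome.chrom, genome.pos, meth, total,
                          list(samples["sample_id"]))
    m.validate()
    return m, samples, genotypes, genome.annotation, genome.truth


def simulate_validation_cohort(config: SimulationConfig, n_cases: int = 9,
                               n_controls: int = 13, case_dose: float = 2.0,
                               seed: int | None = None):
    """Simulate an independent case/control cohort sharing the discovery
    study's genome and planted effects.

    Emulates the small T-cell validation design: cases carry the planted
    dose effects at strength ``case_dose`` (in ordinal-step units) and the
    genotype-confounded machinery operates with case status in place of
    ACPA dose.  Returns ``(methylation, samples, truth)`` where the sample
    sheet flags cases in the ``ra`` column and truth is shared with the
    discovery dataset generated from ``config``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = _layout_genome(config, rng)          # same genome as discovery
    rng2 = np.random.default_rng(config.seed + 1 if seed is None else seed)

    n = n_cases + n_controls
    dose = np.array([0.0] * n_controls + [case_dose] * n_cases)
    sample_ids = [f"V{i + 1:03d}" for i in range(n)]

    od = np.concatenate([
        _truncated_lognormal(rng2, np.log(8.0), 0.6, 0.0,
                             ACPA_NEGATIVE_MAX_OD, n_controls),
        _truncated_lognormal(rng2, np.log(42.0), 0.25, ACPA_NEGATIVE_MAX_OD,
                             ACPA_MEDIUM_MAX_OD, n_cases),
    ])
    props = rng2.dirichlet(_CELL_MEANS * _CELL_CONCENTRATION, size=n)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "acpa_od": np.round(od, 2),
        "acpa_group": [acpa_group_from_od(v) for v in od],
        "ra": [False] * n_controls + [True] * n_cases,
        "age": rng2.uniform(25.0, 65.0, n).round(1),
        "sex": rng2.choice(["F", "M"], size=n, p=[0.7, 0.3]),
        "smoking": rng2.choice(["current", "past", "never"], size=n,
                               p=[0.2, 0.4, 0.4]),
    })
    for k, c in enumerate(CELL_TYPES):
        samples[f"prop_{c}"] = props[:, k]
    validate_sample_sheet(samples)

    genotypes = _simulate_genotypes(genome, dose, rng2, sample_ids)
    meth, total = _simulate_counts(config, genome, dose, props,
                                   genotypes.dosage, rng2)
    m = MethylationMatrix(genome.chrom, genome.pos, meth, total, sample_ids)
    m.validate()
    return m, samples, genome.truth


def _overlaps(chrom, start, end, interval) -> bool:
    c, a, b = interval[0], interval[1], interval[2]
    return chrom == c and start <= b and a <= end


def score_dmr_calls(dmrs, truth: GroundTruth) -> dict:
    """Recovery and false-discovery proportion of called DMRs against the
    planted intervals (>= 1 bp overlap)."""
    planted = truth.true_dmr_intervals
    recovered = sum(
        1 for iv in planted
        if any(_overlaps(d.chrom, d.start, d.end, iv) for d in dmrs))
    false = sum(
        1 for d in dmrs
        if not any(_overlaps(d.chrom, d.start, d.end, iv) for iv in planted))
    return {
        "n_planted": len(planted),
        "n_called": len(dmrs),
        "n_recovered": recovered,
        "recovery": recovered / len(planted) if planted else np.nan,
        "n_false": false,
        "fdp": false / len(dmrs) if dmrs else 0.0,
    }


def score_classifications(classifications, truth: GroundTruth) -> dict:
    """Accuracy of gDMR/ngDMR labels for called DMRs overlapping planted
    regions: genotype-confounded regions should label gDMR, dose regions
    ngDMR."""
    want = {tuple(iv[:3]): ("gDMR" if iv[4] == "genotype-confounded"
                            else "ngDMR")
            for iv in truth.true_dmr_intervals}
    n = correct = 0
    for cl in classifications:
        for iv, expected in want.items():
            if _overlaps(cl.chrom, cl.start, cl.end, iv):
                n += 1
                correct += cl.label == expected
                break
    return {"n_scored": n, "n_correct": correct,
            "accuracy": correct / n if n else np.nan}


def write_dataset(outdir, methylation: MethylationMatrix,
                  samples: pd.DataFrame, genotypes: GenotypeMatrix,
                  annotation: FeatureAnnotation, truth: GroundTruth) -> None:
    """Write a simulated study in the pipeline's on-disk layout."""
    os.makedirs(outdir, exist_ok=True)
    write_methylation_counts(methylation, os.path.join(outdir, "counts"))
    write_sample_sheet(samples, os.path.join(outdir, "samples.tsv"))
    write_genotypes(genotypes, os.path.join(outdir, "genotypes.vcf"))
    write_annotations(annotation, os.path.join(outdir, "annotations"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
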
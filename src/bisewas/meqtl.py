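"""cis-meQTL mapping and genotype-adjusted refits of the EWAS models.

meQTLs are mapped with an additive ordinary-least-squares model of the
per-sample methylation ratio on alt-allele dosage, no covariates, for every
SNP-CpG pair within the cis window (250 kb by default, i.e. a 500-kb
window around each CpG).  CpGs entering the scan must be observed in more
than half the cohort and have methylation-ratio variance in the top half of
those candidates.  Pair-level p-values are corrected with
Benjamini-Hochberg; a genome-wide subset at p < 5e-8 is also flagged.

For genotype adjustment, each significant DMC's lead meQTL dosage is added
to the original binomial model and the fit repeated; a DMC remains
significant when its Bonferroni-adjusted p-value (over the refitted DMCs)
stays below the threshold.  DMRs are then classified as ngDMR (membership
criteria re-satisfied after adjustment), gDMR (testable but criteria lost)
or untestable (no member CpG has a significant meQTL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .dmr import DmrRecord
from .ewas import ModelSpec, run_ewas
from .io_formats import GenotypeMatrix, MethylationMatrix

__all__ = [
    "GeneticClassification",
    "select_meqtl_cpgs",
    "map_cis_meqtls",
    "adjust_and_classify",
]

MEQTL_COLUMNS = ["snp_id", "snp_chrom", "snp_pos", "cpg_chrom", "cpg_pos",
                 "slope", "t_stat", "p_value", "q_value", "n", "genome_wide"]


@dataclass
class GeneticClassification:
    """Genotype-adjustment outcome for one DMR."""

    dmr_index: int
    chrom: str
    start: int
    end: int
    label: str                      # 'gDMR' | 'ngDMR' | 'untestable'
    n_members: int = 0
    n_members_with_meqtl: int = 0
    n_members_significant_adjusted: int = 0
    lead_snps: list = field(default_factory=list)


def select_meqtl_cpgs(m: MethylationMatrix, min_call_frac: float = 0.5
                      ) -> np.ndarray:
    """Indices of CpGs eligible for the meQTL scan: observed in more than
    ``min_call_frac`` of samples and ratio variance in the top half."""
    observed = (m.total > 0).sum(axis=1)
    enough = observed > min_call_frac * m.n_samples
    ratios = m.ratios()
    with np.errstate(invalid="ignore"):
        var = np.nanvar(ratios, axis=1)
    var = np.where(enough, var, np.nan)
    if not enough.any():
        return np.array([], dtype=np.int64)
    cutoff = np.nanmedian(var[enough])
    keep = enough & (var >= cutoff)
    return np.flatnonzero(keep)


def map_cis_meqtls(m: MethylationMatrix, g: GenotypeMatrix,
                   window: int = 250_000, gw_p: float = 5e-8,
                   selected: np.ndarray = None) -> pd.DataFrame:
    """Test every SNP-CpG pair within ``window`` bp by simple OLS.

    Returns a DataFrame with slope (methylation-ratio change per alt
    allele), t-statistic, p-value, BH q-value and a genome-wide flag.
    Pairs with constant dosage or constant methylation among the complete
    observations are skipped (counted in ``df.attrs['n_skipped']``).
    """
    if list(m.sample_ids) != list(g.sample_ids):
        raise ValueError("methylation and genotype sample ids differ")
    if selected is None:
        selected = select_meqtl_cpgs(m)
    selected = np.asarray(selected, dtype=np.int64)

    ratios = m.ratios()[selected]
    cpg_chrom = m.chrom[selected]
    cpg_pos = m.pos[selected]

    rows = []
    n_skipped = 0
    for si in range(g.n_snps):
        chrom_mask = cpg_chrom == g.chrom[si]
        if not chrom_mask.any():
            continue
        idx = np.flatnonzero(chrom_mask
                             & (np.abs(cpg_pos - g.pos[si]) <= window))
        if len(idx) == 0:
            continue
        d = g.dosage[si]
        R = ratios[idx]
        ok = np.isfinite(d)[None, :] & np.isfinite(R)
        n = ok.sum(axis=1)
        dz = np.where(np.isfinite(d), d, 0.0)
        Rz = np.where(ok, R, 0.0)
        Dz = np.where(ok, dz[None, :], 0.0)
        sum_d = Dz.sum(axis=1)
        sum_r = Rz.sum(axis=1)
        sum_dd = (Dz * Dz).sum(axis=1)
        sum_dr = (Dz * Rz).sum(axis=1)
        sum_rr = (Rz * Rz).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sxx = sum_dd - sum_d ** 2 / n
            sxy = sum_dr - sum_d * sum_r / n
            syy = sum_rr - sum_r ** 2 / n
        valid = (n >= 3) & (sxx > 1e-12) & (syy > 1e-12)
        n_skipped += int(len(idx) - valid.sum())
        if not valid.any():
            continue
        v = np.flatnonzero(valid)
        slope = sxy[v] / sxx[v]
        dfree = n[v] - 2
        resid = np.maximum(syy[v] - slope * sxy[v], 0.0)
        se = np.sqrt(resid / dfree / sxx[v])
        with np.errstate(divide="ignore"):
            tstat = np.where(se > 0, slope / se, np.inf * np.sign(slope))
        pval = 2.0 * t_dist.sf(np.abs(tstat), dfree)
        for k, ci in enumerate(idx[v]):
            rows.append((g.ids[si], g.chrom[si], int(g.pos[si]),
                         cpg_chrom[ci], int(cpg_pos[ci]),
                         float(slope[k]), float(tstat[k]), float(pval[k]),
                         int(n[v][k])))

    df = pd.DataFrame(rows, columns=["snp_id", "snp_chrom", "snp_pos",
                                     "cpg_chrom", "cpg_pos", "slope",
                                     "t_stat", "p_value", "n"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["genome_wide"] = df["p_value"] < gw_p
    else:
        df["q_value"] = []
        df["genome_wide"] = []
    df = df[MEQTL_COLUMNS]
    df.attrs["n_skipped"] = n_skipped
    return df


# ---------------------------------------------------------------------------
# Genotype adjustment and gDMR/ngDMR classification
# ---------------------------------------------------------------------------

def _lead_meqtls(sig: pd.DataFrame) -> dict[tuple, list]:
    """Per-CpG candidate lead meQTLs ordered by p, then distance, then SNP
    position."""
    if not len(sig):
        return {}
    sig = sig.copy()
    sig["distance"] = np.abs(sig["snp_pos"] - sig["cpg_pos"])
    sig = sig.sort_values(["p_value", "distance", "snp_pos"],
                          kind="mergesort")
    out: dict[tuple, list] = {}
    for row in sig.itertuples(index=False):
        out.setdefault((row.cpg_chrom, row.cpg_pos), []).append(row)
    return out


def adjust_and_classify(dmcs: pd.DataFrame, dmrs: list[DmrRecord],
                        meqtls: pd.DataFrame, m: MethylationMatrix,
                        samples: pd.DataFrame, spec: ModelSpec,
                        meqtl_q: float = 0.01, sig_threshold: float = 0.01,
                        correction: str = "bonferroni",
                        dmr_rule: str = "criteria",
                        max_missing_frac: float = 0.3,
                        genotypes: GenotypeMatrix = None
                        ) -> tuple[pd.DataFrame, list[GeneticClassification]]:
    """Refit each DMC with its lead meQTL dosage and classify DMRs.

    ``dmcs`` are the significant CpGs of the original model; ``meqtls`` the
    cis scan output (q filtering at ``meqtl_q`` happens here).  The lead
    SNP is the smallest-p significant meQTL for the CpG; a lead with more
    than ``max_missing_frac`` missing dosages falls through to the next
    candidate, and a CpG with no usable meQTL keeps its unadjusted result.

    Returns the per-DMC adjusted table and one classification per DMR:
    ngDMR when >= 3 consecutive members stay significant with unchanged
    direction after adjustment (or, with ``dmr_rule='any'``, when any
    member does), gDMR when testable but no longer qualifying, untestable
    when no member CpG has a significant meQTL.
    """
    if genotypes is None:
        raise ValueError("genotypes matrix is required for adjustment refits")
    if correction not in ("bonferroni", "qvalue"):
        raise ValueError("correction must be 'bonferroni' or 'qvalue'")
    if dmr_rule not in ("criteria", "any"):
        raise ValueError("dmr_rule must be 'criteria' or 'any'")

    sig_meqtls = meqtls[meqtls["q_value"] < meqtl_q]
    leads = _lead_meqtls(sig_meqtls)
    snp_row = {sid: i for i, sid in enumerate(genotypes.ids)}
    keys = pd.MultiIndex.from_arrays([m.chrom, m.pos])

    records = []
    refit_p = []
    by_lead: dict[str, list[int]] = {}
    for row in dmcs.itertuples(index=False):
        key = (row.chrom, row.pos)
        cand = leads.get(key, [])
        lead = None
        for c in cand:
            dos = genotypes.dosage[snp_row[c.snp_id]]
            if np.mean(~np.isfinite(dos)) <= max_missing_frac:
                lead = c
                break
        rec = {
            "chrom": row.chrom, "pos": row.pos,
            "beta_unadjusted": row.beta, "p_unadjusted": row.p_value,
            "direction_unadjusted": int(np.sign(row.beta)),
            "lead_snp": lead.snp_id if lead is not None else "",
            "has_meqtl": len(cand) > 0,
            "adjusted": False,
            "beta_adjusted": row.beta,
            "p_adjusted_raw": row.p_value,
            "converged": True,
        }
        if lead is not None:
            by_lead.setdefault(lead.snp_id, []).append(len(records))
            refit_p.append(len(records))
        records.append(rec)

    # refit in batches: all DMCs sharing a lead SNP in one scan
    for snp_id, rec_idx in by_lead.items():
        locs = keys.get_indexer([(records[i]["chrom"], records[i]["pos"])
                                 for i in rec_idx])
        res = run_ewas(m, samples, spec,
                       extra_covariate=genotypes.dosage[snp_row[snp_id]],
                       cpg_index=locs)
        for i, (_, r) in zip(rec_idx, res.iterrows()):
            records[i]["adjusted"] = True
            records[i]["converged"] = bool(r["converged"])
            records[i]["beta_adjusted"] = float(r["beta"])
            records[i]["p_adjusted_raw"] = float(r["p_value"])

    adj = pd.DataFrame(records)
    if len(adj):
        adj["p_corrected"] = adj["p_unadjusted"]
        n_refit = len(refit_p)
        if n_refit:
            idx = np.asarray(refit_p)
            raw = adj.loc[idx, "p_adjusted_raw"].to_numpy(dtype=float)
            raw = np.where(np.isfinite(raw), raw, 1.0)
            if correction == "bonferroni":
                adj.loc[idx, "p_corrected"] = np.minimum(raw * n_refit, 1.0)
            else:
                adj.loc[idx, "p_corrected"] = multipletests(
                    raw, method="fdr_bh")[1]
        # unadjusted members keep their original (q-significant) status
        adj["significant_adjusted"] = np.where(
            adj["adjusted"],
            adj["converged"] & (adj["p_corrected"] < sig_threshold)
            & (np.sign(adj["beta_adjusted"])
               == adj["direction_unadjusted"]),
            True)
    else:
        adj["p_corrected"] = []
        adj["significant_adjusted"] = []

    by_key = {(r.chrom, r.pos): r for r in adj.itertuples(index=False)}
    classifications = []
    for di, d in enumerate(dmrs):
        members = [by_key.get((d.chrom, p)) for p in d.member_pos]
        with_meqtl = [mm for mm in members if mm is not None and mm.has_meqtl]
        cls = GeneticClassification(
            dmr_index=di, chrom=d.chrom, start=d.start, end=d.end,
            label="untestable", n_members=d.n_cpgs,
            n_members_with_meqtl=len(with_meqtl),
            lead_snps=sorted({mm.lead_snp for mm in with_meqtl if mm.lead_snp}),
        )
        if not with_meqtl:
            classifications.append(cls)
            continue
        ok = [bool(mm.significant_adjusted) if mm is not None else False
              for mm in members]
        cls.n_members_significant_adjusted = int(sum(
            bool(mm.significant_adjusted) for mm in members if mm is not None))
        if dmr_rule == "any":
            survives = any(ok)
        else:
            survives = _longest_true_run(ok) >= 3
        cls.label = "ngDMR" if survives else "gDMR"
        classifications.append(cls)
    return adj, classifications


def _longest_true_run(flags) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def classifications_to_frame(classifications) -> pd.DataFrame:
    return pd.DataFrame([{
        "dmr_index": c.dmr_index, "chrom": c.chrom, "start": c.start,
        "end": c.end, "label": c.label, "n_members": c.n_members,
        "n_members_with_meqtl": c.n_members_with_meqtl,
        "n_members_significant_adjusted": c.n_members_significant_adjusted,
        "lead_snps": ",".join(c.lead_snps),
    } for c in classifications])
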
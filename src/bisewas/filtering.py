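"""CpG and SNP inclusion rules applied before association testing.

CpG rules, in order: drop sex-chromosome CpGs; mask observations below the
depth threshold (they carry too little measurement accuracy and are treated
as missing by every downstream model); drop CpGs observed at sufficient
depth in fewer than ``min_samples`` samples; drop non-variable CpGs
(standard deviation of the per-sample methylation ratio equal to zero over
the unmasked samples, or fewer than two unmasked samples).

SNP rules: keep bi-allelic records only; genotype calls below the depth
threshold are set missing; keep SNPs whose post-masking call rate exceeds
``min_call_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MethylationMatrix, is_autosome

__all__ = ["FilterReport", "filter_cpgs", "filter_snps"]

CPG_RULES = ["sex_chromosome", "low_sample_coverage", "non_variable"]
SNP_RULES = ["non_biallelic", "low_depth", "low_call_rate"]


@dataclass
class FilterReport:
    """Per-rule removal counts; rules were applied in listed order and each
    removed item is attributed to the first rule it violated."""

    rules: list[str]
    removed: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def __post_init__(self):
        for r in self.rules:
            self.removed.setdefault(r, 0)

    def reconciles(self) -> bool:
        return self.n_input == self.n_output + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{r}", self.removed[r]) for r in self.rules]
        rows.append(("output", self.n_output))
        return pd.DataFrame(rows, columns=["rule", "count"])


def filter_cpgs(m: MethylationMatrix, min_depth: int = 15,
                min_samples: int = 30) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the EWAS CpG inclusion rules.

    Returns the retained matrix (with sub-threshold observations masked to
    ``total = 0``) and a :class:`FilterReport`.
    """
    if m.n_cpgs == 0:
        raise ValueError("empty methylation matrix")
    if min_samples > m.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds cohort size {m.n_samples}")

    report = FilterReport(CPG_RULES, n_input=m.n_cpgs)

    autosomal = is_autosome(m.chrom)
    deep = m.total >= min_depth
    n_deep = deep.sum(axis=1)
    enough = n_deep >= min_samples

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(deep, m.meth / np.where(m.total == 0, 1, m.total),
                         np.nan)
    sd = np.nanstd(np.where(deep, ratio, np.nan), axis=1)
    variable = (n_deep >= 2) & (sd > 0)

    keep = autosomal & enough & variable
    report.removed["sex_chromosome"] = int((~autosomal).sum())
    report.removed["low_sample_coverage"] = int((autosomal & ~enough).sum())
    report.removed["non_variable"] = int((autosomal & enough & ~variable).sum())
    report.n_output = int(keep.sum())

    out = m.subset_cpgs(keep)
    mask = deep[keep]
    out = MethylationMatrix(out.chrom, out.pos,
                            np.where(mask, out.meth, 0),
                            np.where(mask, out.total, 0),
                            out.sample_ids)
    assert report.reconciles()
    return out, report


def filter_snps(g: GenotypeMatrix, min_depth: int = 10,
                min_call_rate: float = 0.7) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the meQTL SNP inclusion rules (bi-allelic, depth, call rate)."""
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")

    report = FilterReport(SNP_RULES, n_input=g.n_snps)

    deep = g.depth >= min_depth
    called_raw = np.isfinite(g.dosage)
    called = called_raw & deep
    rate = called.mean(axis=1)
    rate_raw = called_raw.mean(axis=1)

    biallelic = g.biallelic
    pass_rate = rate > min_call_rate
    # attribute a call-rate failure to depth masking when the raw calls alone
    # would have passed
    depth_fail = biallelic & ~pass_rate & (rate_raw > min_call_rate)
    rate_fail = biallelic & ~pass_rate & ~(rate_raw > min_call_rate)

    keep = biallelic & pass_rate
    report.removed["non_biallelic"] = int((~biallelic).sum())
    report.removed["low_depth"] = int(depth_fail.sum())
    report.removed["low_call_rate"] = int(rate_fail.sum())
    report.n_output = int(keep.sum())

    out = g.subset_snps(keep)
    dosage = out.dosage.copy()
    dosage[~deep[keep]] = np.nan
    out = GenotypeMatrix(out.chrom, out.pos, out.ids, out.ref, out.alt,
                         dosage, out.depth, out.sample_ids, out.biallelic)
    assert report.reconciles()
    return out, report
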
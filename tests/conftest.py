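import numpy as np
import pytest

from bisewas.filtering import filter_cpgs, filter_snps
from bisewas.ewas import make_model_spec, run_ewas
from bisewas.dmr import call_dmrs
from bisewas.meqtl import adjust_and_classify, map_cis_meqtls
from bisewas.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_study():
    """A 5k-CpG study with planted effects for fast unit tests."""
    cfg = SimulationConfig(n_cpgs=5000, n_true_dmrs=8, n_confounded_dmrs=8,
                           n_cell_cpgs=50, n_meqtl_snps=20, n_null_snps=50,
                           seed=101)
    m, samples, genotypes, annotation, truth = simulate_dataset(cfg)
    return dict(config=cfg, m=m, samples=samples, genotypes=genotypes,
                annotation=annotation, truth=truth)


@pytest.fixture(scope="session")
def null_study():
    """5000 CpGs, 130 non-RA samples equivalent, no planted effects."""
    cfg = SimulationConfig(n_cpgs=5000, effect_logit=0.0, n_true_dmrs=0,
                           n_confounded_dmrs=0, cell_effect_logit=0.0,
                           n_cell_cpgs=0, n_meqtl_snps=0, seed=11)
    m, samples, genotypes, annotation, truth = simulate_dataset(cfg)
    m_filt, _ = filter_cpgs(m)
    return dict(config=cfg, m=m, m_filt=m_filt, samples=samples,
                genotypes=genotypes, truth=truth)


@pytest.fixture(scope="session")
def default_run():
    """The full default study pushed through the whole pipeline once.

    Shared by the heavier end-to-end checks to keep the suite fast.
    """
    cfg = SimulationConfig(seed=1)
    m, samples, genotypes, annotation, truth = simulate_dataset(cfg)
    m_filt, cpg_report = filter_cpgs(m)
    kept = set(zip(m_filt.chrom, m_filt.pos))
    keep = np.fromiter(((c, p) in kept for c, p in zip(m.chrom, m.pos)),
                       bool, m.n_cpgs)
    m_raw = m.subset_cpgs(keep)

    spec = make_model_spec("IV", samples)
    results = run_ewas(m_filt, samples, spec)
    dmrs = call_dmrs(results)
    genotypes_filt, snp_report = filter_snps(genotypes)
    meqtls = map_cis_meqtls(m_raw, genotypes_filt)
    dmcs = results[results["q_value"] < 0.01]
    adjusted, classifications = adjust_and_classify(
        dmcs, dmrs, meqtls, m_filt, samples, spec,
        genotypes=genotypes_filt)
    return dict(config=cfg, m=m, m_filt=m_filt, m_raw=m_raw,
                samples=samples, genotypes=genotypes_filt,
                annotation=annotation, truth=truth, spec=spec,
                results=results, dmrs=dmrs, meqtls=meqtls, dmcs=dmcs,
                adjusted=adjusted, classifications=classifications,
                cpg_report=cpg_report, snp_report=snp_report)
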
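"""Per-CpG binomial regression EWAS with Wald tests, Storey q-values and the
genomic-control inflation factor.

The response at each CpG is the (methylated, unmethylated) read-count pair,
modelled as a binomial with a logit link; the coefficient of interest is the
phenotype predictor (ACPA status, ordinal ACPA dose, or case/control) and
p-values come from Wald z-statistics.  Five model specifications are
supported:

    I    ACPA-positive vs ACPA-negative; age, sex, smoking
    II   model I plus the five measured blood-cell proportions
    III  self-reported RA vs all others; age, sex, smoking, cell proportions
    IV   ordinal ACPA dose (negative/medium/high = 0/1/2); covariates as II
    V    case vs control with no covariates (small validation cohorts)

Smoking enters as two indicators (current, past; never = reference).  The
five cell proportions sum to one, so basophil is dropped as the reference
fraction to keep the design full-rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .io_formats import CELL_TYPES, MethylationMatrix, is_autosome

__all__ = [
    "ModelSpec",
    "QValueModel",
    "CollinearityError",
    "make_model_spec",
    "build_design",
    "fit_binomial_glm",
    "run_ewas",
    "estimate_qvalues",
    "genomic_lambda",
    "summarize_dmcs",
    "MODEL_NAMES",
]

MODEL_NAMES = ("I", "II", "III", "IV", "V")

RESULT_COLUMNS = ["chrom", "pos", "beta", "se", "wald_z", "p_value",
                  "q_value", "n_used", "direction", "converged", "methdiff"]


class CollinearityError(ValueError):
    """Design matrix rank-deficient after pruning constant columns."""


@dataclass
class ModelSpec:
    """One EWAS model: predictor, covariates and sample mask.

    ``contrast``/``reference`` name the sample groups pooled to report the
    plain methylation difference alongside the model coefficient.
    """

    name: str
    predictor: str
    covariates: list[str]
    sample_mask: np.ndarray
    contrast: np.ndarray = None
    reference: np.ndarray = None

    def validate(self, samples: pd.DataFrame) -> None:
        s = getattr(self, "_samples", samples)
        vals = s.loc[self.sample_mask, self.predictor]
        if vals.nunique() < 2:
            raise ValueError(
                f"model {self.name}: predictor {self.predictor!r} constant "
                "on the masked samples")


def make_model_spec(name: str, samples: pd.DataFrame) -> ModelSpec:
    """Construct the named model specification for a sample sheet."""
    name = name.upper()
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    s = samples.copy()
    s["acpa_pos"] = (s["acpa_group"] != "negative").astype(float)
    s["acpa_dose"] = s["acpa_group"].map(
        {"negative": 0.0, "medium": 1.0, "high": 2.0})
    s["case"] = s["ra"].astype(float)
    not_ra = ~s["ra"].to_numpy()

    base_cov = ["age", "sex", "smoking"]
    cells = [f"prop_{c}" for c in CELL_TYPES]
    if name == "I":
        spec = ModelSpec("I", "acpa_pos", base_cov, not_ra)
    elif name == "II":
        spec = ModelSpec("II", "acpa_pos", base_cov + cells, not_ra)
    elif name == "III":
        spec = ModelSpec("III", "case", base_cov + cells,
                         np.ones(len(s), dtype=bool))
    elif name == "IV":
        spec = ModelSpec("IV", "acpa_dose", base_cov + cells, not_ra)
    else:  # V
        spec = ModelSpec("V", "case", [], np.ones(len(s), dtype=bool))

    grp = s["acpa_group"].to_numpy()
    if name in ("I", "II"):
        spec.contrast = spec.sample_mask & (grp != "negative")
        spec.reference = spec.sample_mask & (grp == "negative")
    elif name == "IV":
        spec.contrast = spec.sample_mask & (grp == "high")
        spec.reference = spec.sample_mask & (grp == "negative")
    else:  # III, V: cases vs the rest
        case = s["case"].to_numpy() == 1.0
        spec.contrast = spec.sample_mask & case
        spec.reference = spec.sample_mask & ~case
    spec._samples = s  # augmented sheet reused by build_design
    return spec


def build_design(samples: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[np.ndarray, list[str], int]:
    """Dense design matrix for the masked samples.

    Returns (X, column names, index of the predictor column).  Categorical
    covariates are expanded here; the predictor is always the last column.
    """
    s = getattr(spec, "_samples", None)
    if s is None or len(s) != len(samples):
        s = samples.copy()
        s["acpa_pos"] = (s["acpa_group"] != "negative").astype(float)
        s["acpa_dose"] = s["acpa_group"].map(
            {"negative": 0.0, "medium": 1.0, "high": 2.0})
        s["case"] = s["ra"].astype(float)
    s = s.loc[spec.sample_mask]

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(s))}
    for cov in spec.covariates:
        if cov == "sex":
            cols["sex_M"] = (s["sex"] == "M").to_numpy(float)
        elif cov == "smoking":
            cols["smoking_current"] = (s["smoking"] == "current").to_numpy(float)
            cols["smoking_past"] = (s["smoking"] == "past").to_numpy(float)
        elif cov == "prop_basophil":
            continue  # reference fraction; proportions sum to one
        else:
            cols[cov] = s[cov].to_numpy(float)
    cols[spec.predictor] = s[spec.predictor].to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names, len(names) - 1


@dataclass
class _Fit:
    beta: float = np.nan
    se: float = np.nan
    z: float = np.nan
    p: float = np.nan
    n_used: int = 0
    converged: bool = False
    coef: np.ndarray = None


def _irls(meth, total, X, target_idx, max_iter=50, tol=1e-10):
    """Maximum-likelihood logit-link binomial fit via iteratively reweighted
    least squares; grouped (count) parameterisation."""
    n = total.astype(float)
    y = meth / n
    p0 = (meth.sum() + 0.5) / (n.sum() + 1.0)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(p0 / (1 - p0))
    H = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = n * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        Xw = X * w[:, None]
        H = Xw.T @ X
        try:
            new = np.linalg.solve(H, Xw.T @ z)
        except np.linalg.LinAlgError:
            return _Fit()
        if not np.all(np.isfinite(new)):
            return _Fit()
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            break
    else:
        return _Fit(coef=beta)
    if np.abs(beta[target_idx]) > 15.0:   # (quasi-)separation in the predictor
        return _Fit(coef=beta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return _Fit(coef=beta)
    se = float(np.sqrt(max(cov[target_idx, target_idx], 0.0)))
    b = float(beta[target_idx])
    if se == 0.0 or not np.isfinite(se):
        return _Fit(coef=beta)
    z_stat = b / se
    return _Fit(beta=b, se=se, z=z_stat, p=2.0 * norm.sf(abs(z_stat)),
                n_used=len(y), converged=True, coef=beta)


def _prune_and_check(X, names, target_idx):
    """Drop constant non-intercept columns; error if still rank-deficient."""
    keep = [0] + [j for j in range(1, X.shape[1])
                  if np.ptp(X[:, j]) > 0]
    if target_idx not in keep:
        raise ValueError(f"predictor {names[target_idx]!r} constant across samples")
    Xk = X[:, keep]
    r = np.linalg.matrix_rank(Xk)
    if r < Xk.shape[1]:
        # name the collinear columns via QR pivoting on the correlation pattern
        _, R = np.linalg.qr(Xk)
        small = np.abs(np.diag(R)) < 1e-8 * max(1.0, np.abs(np.diag(R)).max())
        bad = [names[keep[j]] for j in np.flatnonzero(small)]
        raise CollinearityError(f"rank-deficient design; collinear columns: {bad}")
    return Xk, [names[j] for j in keep], keep.index(target_idx)


def fit_binomial_glm(meth, total, design, target="predictor",
                     column_names=None) -> dict:
    """Fit one per-CpG binomial GLM and return the Wald summary.

    ``design`` is either an (n, p) array whose last column is the predictor,
    or a DataFrame whose column ``target`` is the predictor.  Samples with
    ``total == 0`` are excluded.  Raises on a constant predictor or a
    rank-deficient design; returns ``converged=False`` for separated or
    non-converged fits.
    """
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    if isinstance(design, pd.DataFrame):
        column_names = list(design.columns)
        target_idx = column_names.index(target)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        column_names = column_names or [f"x{j}" for j in range(X.shape[1])]
        target_idx = X.shape[1] - 1 if target == "predictor" \
            else column_names.index(target)

    obs = total > 0
    meth, total, X = meth[obs], total[obs], X[obs]
    if len(np.unique(X[:, target_idx])) < 2:
        raise ValueError(
            f"predictor {column_names[target_idx]!r} constant across samples")
    Xk, kept_names, t_idx = _prune_and_check(X, column_names, target_idx)
    fit = _irls(meth, total, Xk, t_idx)
    return {
        "beta": fit.beta, "se": fit.se, "wald_z": fit.z, "p_value": fit.p,
        "n_used": int(obs.sum()), "converged": fit.converged,
        "coef": fit.coef, "coef_names": kept_names,
    }


def _pooled_group_ratio(meth, total, mask):
    tot = total[:, mask].sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(tot > 0, meth[:, mask].sum(axis=1) / tot, np.nan)


def run_ewas(m: MethylationMatrix, samples: pd.DataFrame, spec: ModelSpec,
             q_threshold: float = 0.01, extra_covariate: np.ndarray = None,
             cpg_index=None, dispersion_warning: float = 2.0) -> pd.DataFrame:
    """Fit the model at every testable CpG.

    Returns one row per CpG with Wald statistics, the pooled-contrast
    methylation difference, and Storey q-values computed over the autosomal
    converged tests.  Per-CpG failures (constant predictor, separation,
    non-convergence) yield ``converged = False`` rows rather than aborting.

    ``extra_covariate`` (per-sample, NaN = missing) supports genotype
    adjustment refits; ``cpg_index`` restricts the scan to a subset of rows.
    """
    spec.validate(samples)
    X_full, names, t_idx = build_design(samples, spec)
    mask = np.asarray(spec.sample_mask, dtype=bool)
    if extra_covariate is not None:
        extra = np.asarray(extra_covariate, dtype=float)[mask]
        X_full = np.insert(X_full, X_full.shape[1] - 1, extra, axis=1)
        names = names[:-1] + ["genotype_dosage"] + names[-1:]
        t_idx = X_full.shape[1] - 1

    rows = np.arange(m.n_cpgs) if cpg_index is None else np.asarray(cpg_index)
    meth = m.meth[:, mask]
    total = m.total[:, mask]

    diff = (_pooled_group_ratio(m.meth[rows], m.total[rows], spec.contrast)
            - _pooled_group_ratio(m.meth[rows], m.total[rows], spec.reference))

    g_idx = names.index("genotype_dosage") if extra_covariate is not None else -1
    out = np.full((len(rows), 6), np.nan)  # beta, se, z, p, n_used, converged
    pearson_excess = 0
    for k, i in enumerate(rows):
        obs = total[i] > 0
        if g_idx >= 0:
            obs &= np.isfinite(X_full[:, g_idx])
        n_obs = int(obs.sum())
        if n_obs < 3:
            continue
        Xo = X_full[obs]
        if len(np.unique(Xo[:, t_idx])) < 2:
            continue
        try:
            Xk, _, tk = _prune_and_check(Xo, names, t_idx)
        except (ValueError, CollinearityError):
            continue
        fit = _irls(meth[i, obs].astype(float), total[i, obs].astype(float),
                    Xk, tk)
        if fit.converged:
            out[k] = (fit.beta, fit.se, fit.z, fit.p, n_obs, 1.0)
            mu = np.clip(expit(Xk @ fit.coef), 1e-12, 1 - 1e-12)
            tot = total[i, obs].astype(float)
            pear = np.sum((meth[i, obs] - tot * mu) ** 2
                          / (tot * mu * (1 - mu)))
            df = n_obs - Xk.shape[1]
            if df > 0 and pear / df > dispersion_warning:
                pearson_excess += 1
        else:
            out[k, 4] = n_obs
            out[k, 5] = 0.0

    res = pd.DataFrame({
        "chrom": m.chrom[rows],
        "pos": m.pos[rows],
        "beta": out[:, 0],
        "se": out[:, 1],
        "wald_z": out[:, 2],
        "p_value": out[:, 3],
        "q_value": np.nan,
        "n_used": out[:, 4],
        "direction": np.sign(np.nan_to_num(out[:, 0])).astype(int),
        "converged": out[:, 5] == 1.0,
        "methdiff": diff,
    })
    testable = res["converged"] & is_autosome(res["chrom"])
    if testable.any():
        q, _ = estimate_qvalues(res.loc[testable, "p_value"].to_numpy())
        res.loc[testable, "q_value"] = q
    if pearson_excess > 0.1 * max(1, int(testable.sum())):
        warnings.warn(
            f"{pearson_excess} CpGs show Pearson chi2/df > {dispersion_warning}: "
            "counts may be overdispersed relative to the binomial model")
    return res


def summarize_dmcs(results: pd.DataFrame, q_threshold: float = 0.01) -> dict:
    sig = results["q_value"] < q_threshold
    return {
        "n_tested": int(results["converged"].sum()),
        "n_dmcs": int(sig.sum()),
        "n_hypo": int((sig & (results["beta"] < 0)).sum()),
        "n_hyper": int((sig & (results["beta"] > 0)).sum()),
    }


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

@dataclass
class QValueModel:
    pi0: float
    lambda_grid: np.ndarray
    m: int
    pi0_raw: np.ndarray = None


def _natural_spline_basis(x, knots):
    """Natural cubic spline basis (truncated-power construction); the two
    boundary knots absorb the linearity constraints."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    kK, kK1 = k[-1], k[-2]

    def d(j):
        num = (np.maximum(x - k[j], 0) ** 3
               - np.maximum(x - kK, 0) ** 3)
        return num / (kK - k[j])

    cols = [x]
    dK1 = d(len(k) - 2)
    for j in range(len(k) - 2):
        cols.append(d(j) - dK1)
    return np.column_stack(cols)


def estimate_qvalues(p_values, pi0: float | None = None,
                     lambda_grid=None) -> tuple[np.ndarray, QValueModel]:
    """Storey FDR q-values.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on
    a lambda grid of 0.05..0.90, smoothed with a natural cubic spline (3 df)
    and read off at the largest lambda, clamped to (0, 1].  Pass ``pi0`` to
    fix it (e.g. 1.0 reproduces Benjamini-Hochberg).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.901, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    pi0_raw = np.array([(p > lam).sum() / (m * (1.0 - lam))
                        for lam in lambda_grid])
    if pi0 is None:
        if len(lambda_grid) >= 4:
            knots = np.quantile(lambda_grid, [0.0, 1 / 3, 2 / 3, 1.0])
            B = np.column_stack([np.ones_like(lambda_grid),
                                 _natural_spline_basis(lambda_grid, knots)])
            coef, *_ = np.linalg.lstsq(B, pi0_raw, rcond=None)
            Bq = np.column_stack([np.ones(1),
                                  _natural_spline_basis(
                                      lambda_grid[-1:], knots)])
            pi0_hat = float((Bq @ coef)[0])
        else:
            pi0_hat = float(pi0_raw[-1])
        pi0_hat = min(max(pi0_hat, 1.0 / m), 1.0)
    else:
        if not 0 < pi0 <= 1:
            raise ValueError("pi0 must lie in (0, 1]")
        pi0_hat = float(pi0)

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0_hat * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, QValueModel(pi0_hat, lambda_grid, m, pi0_raw)


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------

def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor: median of the chi-square(1)
    statistics implied by the p-values over the null median (~0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value list")
    stats = chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(stats) / chi2.ppf(0.5, df=1))
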
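"""Per-probe cell-type-specific association models.

The workhorse is the interaction model fitted probe-by-probe by ordinary
least squares with **no intercept** (the cell-type fractions sum to one,
so an intercept would be collinear):

    x_c = sum_k f_k mu_kc + sum_k f_k y beta_kc + z rho + e

where x_c is the probe's methylation (M-values for inference, betas for
interpretation), f_k the cell-type fractions, y the phenotype, z the
covariates.  mu_kc are the cell-type-specific mean levels; the
interaction coefficients beta_kc — the phenotype effect on methylation
*within* cell type k — are the quantities of interest, tested with
two-sided t-tests on n - 2K - q residual degrees of freedom.

Also provided: the cell-type-adjusted standard EWAS (phenotype main
effect only, proportions as covariates) used as a comparator, and the
reverse formulation for outcomes measured after the methylation sample

    y = sum_k f_k nu*_k + sum_k f_k x_c gamma*_kc + z rho* + e*

which asks instead whether the composition–outcome association is
modulated by the probe's methylation level.

The design matrix of the interaction model is identical across probes, so
all probes are fitted in a single batched linear solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    BETA,
    CellProportions,
    MethylationMatrix,
    PhenotypeTable,
    align_samples,
)

__all__ = [
    "CellSpecificEwasResult",
    "ReverseFitResult",
    "StandardEwasResult",
    "fit_celldmc",
    "fit_standard_ewas",
    "fit_reverse_interaction",
    "bh_fdr",
    "bonferroni_threshold",
]


def _batched_ols(x: np.ndarray, y: np.ndarray):
    """OLS of many responses on one design.

    Parameters
    ----------
    x : (n, p) design matrix, shared by all responses.
    y : (n, m) response matrix, one column per probe.

    Returns
    -------
    coef, se : (p, m) arrays, NaN for inestimable (collinear) columns.
    df : residual degrees of freedom n - rank(X).
    estimable : (p,) boolean mask of identifiable coefficients.

    Rank deficiency is resolved by pivoted QR: columns beyond the numerical
    rank are dropped from the fit and their coefficients reported missing
    rather than fabricated.
    """
    n, p = x.shape
    # order-preserving rank detection: a column is redundant when it lies in
    # the span of the columns before it (aliasing resolved left-to-right, as
    # in standard linear-model software)
    estimable = np.zeros(p, dtype=bool)
    basis: list[np.ndarray] = []
    rel_tol = 1e-8
    for j in range(p):
        v = x[:, j].astype(float).copy()
        nrm0 = np.linalg.norm(v)
        for u in basis:
            v -= (u @ v) * u
        nrm = np.linalg.norm(v)
        if nrm0 > 0 and nrm > rel_tol * nrm0:
            basis.append(v / nrm)
            estimable[j] = True
    rank = int(estimable.sum())

    xr = x[:, estimable]
    coef_r, _, _, _ = np.linalg.lstsq(xr, y, rcond=None)
    resid = y - xr @ coef_r
    df = n - rank
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, rank={rank})")
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(xr.T @ xr)
    var_scale = np.diag(xtx_inv)
    se_r = np.sqrt(var_scale[:, None] * sigma2[None, :])

    coef = np.full((p, y.shape[1]), np.nan)
    se = np.full((p, y.shape[1]), np.nan)
    coef[estimable] = coef_r
    se[estimable] = se_r
    return coef, se, df, estimable


def _t_pvalues(coef: np.ndarray, se: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


@dataclass
class CellSpecificEwasResult:
    """Tidy per-(probe, cell type) interaction results.

    ``table`` columns: probe, cell_type, mu, estimate, se, t, p, fdr,
    clipped.  ``covariate_effects`` holds the per-probe rho estimates.
    """

    table: pd.DataFrame
    covariate_effects: pd.DataFrame
    scale: str
    df_resid: int
    fdr_family: str = "per_cell_type"
    metadata: dict = field(default_factory=dict)

    @property
    def n_probes(self) -> int:
        return self.table["probe"].nunique()

    def significant(self, fdr_cut: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr_cut]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ReverseFitResult:
    """Per-(probe, cell type) results of the reverse interaction model."""

    table: pd.DataFrame  # probe, cell_type, nu, estimate(gamma*), se, t, p, fdr
    covariate_effects: pd.DataFrame
    df_resid: int
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class StandardEwasResult:
    """Per-probe phenotype main-effect results, composition-adjusted."""

    table: pd.DataFrame  # probe, estimate, se, t, p, fdr
    df_resid: int
    reference_cell_type: str = ""
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _interaction_design(
    props: CellProportions, pheno: PhenotypeTable
) -> tuple[np.ndarray, list[str]]:
    f = props.fractions.to_numpy()
    y = pheno.y
    z = pheno.z
    x = np.hstack([f, f * y[:, None], z])
    names = (
        [f"mu:{ct}" for ct in props.cell_types]
        + [f"beta:{ct}" for ct in props.cell_types]
        + [f"rho:{c}" for c in pheno.covariates]
    )
    return x, names


def fit_celldmc(
    matrix: MethylationMatrix,
    props: CellProportions,
    pheno: PhenotypeTable,
    fdr_family: str = "per_cell_type",
) -> CellSpecificEwasResult:
    """Fit the no-intercept interaction model at every probe.

    Parameters
    ----------
    matrix
        Probe x sample methylation; M-scale for inference (the
        conventional choice), beta-scale for interpretable effect sizes —
        on the beta scale estimates are clipped to [-1, 1] and flagged,
        since a methylation proportion cannot change by more than one.
    props
        Normalized cell-type fractions (rows on the simplex).
    pheno
        Phenotype and covariates; samples must match the matrix.
    fdr_family
        ``"per_cell_type"`` (default): Benjamini–Hochberg across probes
        separately within each cell type; ``"pooled"``: one family over
        all probe x cell-type tests.
    """
    matrix, props, pheno = align_samples(matrix, props, pheno)
    k = len(props.cell_types)
    q = len(pheno.covariates)
    n = matrix.n_samples
    if n <= 2 * k + q:
        raise ValueError(f"need n > 2K + q = {2 * k + q}, got n = {n}")
    x, names = _interaction_design(props, pheno)
    y_resp = matrix.values.to_numpy().T  # n x P
    coef, se, df, estimable = _batched_ols(x, y_resp)
    t, p = _t_pvalues(coef, se, df)

    probes = matrix.probe_ids
    rows = []
    for j, ct in enumerate(props.cell_types):
        mu_i, b_i = j, k + j
        est = coef[b_i]
        clipped = np.zeros(len(probes), dtype=bool)
        if matrix.scale == BETA:
            clipped = np.abs(est) > 1
            est = np.clip(est, -1.0, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "probe": probes,
                    "cell_type": ct,
                    "mu": coef[mu_i],
                    "estimate": est,
                    "se": se[b_i],
                    "t": t[b_i],
                    "p": p[b_i],
                    "clipped": clipped,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["fdr"] = _apply_fdr(table, fdr_family)

    cov_eff = pd.DataFrame(
        coef[2 * k:].T, index=probes, columns=pheno.covariates
    )
    return CellSpecificEwasResult(
        table=table,
        covariate_effects=cov_eff,
        scale=matrix.scale,
        df_resid=df,
        fdr_family=fdr_family,
        metadata={
            "n_samples": n,
            "phenotype": pheno.phenotype,
            "phenotype_coding": "binary phenotypes coded 0=control, 1=case; sex 0/1",
            "design_columns": names,
            "estimable": dict(zip(names, estimable.tolist())),
        },
    )


def _apply_fdr(table: pd.DataFrame, fdr_family: str) -> np.ndarray:
    if fdr_family == "pooled":
        return bh_fdr(table["p"].to_numpy())
    if fdr_family == "per_cell_type":
        out = np.full(len(table), np.nan)
        for _, idx in table.groupby("cell_type", sort=False).groups.items():
            out[np.asarray(idx)] = bh_fdr(table.loc[idx, "p"].to_numpy())
        return out
    raise ValueError("fdr_family must be 'per_cell_type' or 'pooled'")


def fit_standard_ewas(
    matrix: MethylationMatrix,
    props: CellProportions,
    pheno: PhenotypeTable,
    reference_cell_type: str | None = None,
) -> StandardEwasResult:
    """Composition-adjusted EWAS of the phenotype main effect.

    Per probe: OLS of x_c on {intercept, y, covariates, f_k for k != ref};
    one cell type is dropped because the fractions sum to one and would
    otherwise be collinear with the intercept.  The test (and its t
    statistic) is invariant to which type is dropped.
    """
    matrix, props, pheno = align_samples(matrix, props, pheno)
    cts = props.cell_types
    ref = reference_cell_type if reference_cell_type is not None else cts[-1]
    if ref not in cts:
        raise KeyError(f"unknown reference cell type {ref!r}")
    f = props.fractions.drop(columns=[ref]).to_numpy()
    n = matrix.n_samples
    x = np.hstack([np.ones((n, 1)), pheno.y[:, None], pheno.z, f])
    coef, se, df, estimable = _batched_ols(x, matrix.values.to_numpy().T)
    t, p = _t_pvalues(coef, se, df)
    table = pd.DataFrame(
        {
            "probe": matrix.probe_ids,
            "estimate": coef[1],
            "se": se[1],
            "t": t[1],
            "p": p[1],
        }
    )
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return StandardEwasResult(
        table=table,
        df_resid=df,
        reference_cell_type=ref,
        metadata={"n_samples": n, "phenotype": pheno.phenotype},
    )


def fit_reverse_interaction(
    matrix: MethylationMatrix,
    props: CellProportions,
    pheno: PhenotypeTable,
) -> ReverseFitResult:
    """Fit the reverse model (outcome on composition x methylation).

    Intended for continuous outcomes measured *after* the methylation
    sample; a warning is emitted for binary phenotypes.  The design varies
    with the probe (columns f_k * x_c), so probes are fitted one at a time.
    """
    matrix, props, pheno = align_samples(matrix, props, pheno)
    yvals = pheno.y
    uniq = np.unique(yvals)
    if uniq.size <= 2 and set(np.round(uniq, 12)).issubset({0.0, 1.0}):
        warnings.warn(
            "reverse interaction model applied to a binary phenotype; it is "
            "intended for continuous outcomes measured after sampling",
            UserWarning,
            stacklevel=2,
        )
    f = props.fractions.to_numpy()
    z = pheno.z
    k = f.shape[1]
    probes = matrix.probe_ids
    xmat = matrix.values.to_numpy()  # P x n

    recs = []
    cov_rows = np.full((len(probes), z.shape[1]), np.nan)
    df_out = None
    for i, probe in enumerate(probes):
        xc = xmat[i]
        design = np.hstack([f, f * xc[:, None], z])
        coef, se, df, estimable = _batched_ols(design, yvals[:, None])
        df_out = df
        t, p = _t_pvalues(coef, se, df)
        cov_rows[i] = coef[2 * k:, 0]
        for j, ct in enumerate(props.cell_types):
            recs.append(
                (probe, ct, coef[j, 0], coef[k + j, 0], se[k + j, 0],
                 t[k + j, 0], p[k + j, 0])
            )
    table = pd.DataFrame(
        recs, columns=["probe", "cell_type", "nu", "estimate", "se", "t", "p"]
    )
    table["fdr"] = _apply_fdr(table, "per_cell_type")
    cov_eff = pd.DataFrame(cov_rows, index=probes, columns=pheno.covariates)
    return ReverseFitResult(
        table=table,
        covariate_effects=cov_eff,
        df_resid=int(df_out),
        metadata={"n_samples": matrix.n_samples, "phenotype": pheno.phenotype},
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family and restored as missing.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests
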
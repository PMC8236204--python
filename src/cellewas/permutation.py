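"""Genome-wide permutation null for the interaction tests.

Permutation tests for interaction terms are delicate: permuting the raw
phenotype breaks its association with the covariates and with the
main-effect structure, inflating the null.  The consistent
residual-permutation scheme avoids this: first fit, per probe, a model
*without* any interaction terms, take the residuals R = x_c - x_hat_c,
then apply ONE random re-ordering of samples to every probe's residual
vector (so the cross-probe correlation structure is preserved exactly),
and refit the interaction model using the permuted residuals as the
response.  Repeating this (default 100 times) yields replicate
genome-wide null distributions of interaction p-values against which the
observed distribution can be compared (QQ envelope, genomic inflation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellProportions, MethylationMatrix, PhenotypeTable, align_samples
from .ewas import _batched_ols, _t_pvalues, _interaction_design

__all__ = [
    "PermutationNull",
    "fit_null_residuals",
    "permute_residuals",
    "permutation_null_distribution",
    "qq_summary",
    "genomic_inflation",
]


@dataclass
class PermutationNull:
    """Replicate-indexed genome-wide null interaction p-values.

    ``pvalues`` has shape (n_replicates, n_probes * K): each row pools the
    interaction p-values of all probes and cell types for one shared
    sample re-ordering.
    """

    pvalues: np.ndarray
    n_replicates: int
    seeds: list[int] = field(default_factory=list)
    null_model: str = "with-main"

    def pooled(self) -> np.ndarray:
        return self.pvalues.ravel()

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.pvalues)
        df.insert(0, "replicate", np.arange(self.n_replicates))
        df.to_csv(path, sep="\t", index=False)


def fit_null_residuals(
    matrix: MethylationMatrix,
    props: CellProportions,
    pheno: PhenotypeTable,
    null_model: str = "with-main",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the no-interaction model per probe and return (fitted, residuals).

    The design is {f_1..f_K, y, z} with no intercept when
    ``null_model="with-main"`` (the phenotype main effect is retained so
    only the interaction structure is destroyed by permutation), or
    {f_1..f_K, z} with ``"without-main"``.  Both matrices are probe x
    sample.
    """
    matrix, props, pheno = align_samples(matrix, props, pheno)
    f = props.fractions.to_numpy()
    if null_model == "with-main":
        x0 = np.hstack([f, pheno.y[:, None], pheno.z])
    elif null_model == "without-main":
        x0 = np.hstack([f, pheno.z])
    else:
        raise ValueError("null_model must be 'with-main' or 'without-main'")
    y_resp = matrix.values.to_numpy().T  # n x P
    coef, _, _, estimable = _batched_ols(x0, y_resp)
    fitted = x0[:, estimable] @ coef[estimable]
    resid = y_resp - fitted
    return fitted.T, resid.T


def permute_residuals(
    residuals: np.ndarray, seed=None, permutation: np.ndarray | None = None
) -> np.ndarray:
    """Apply one shared sample re-ordering to every probe's residuals.

    ``seed`` may be an integer, a Generator, or ``None``; the same
    permutation of columns (samples) is used for all rows (probes), which
    preserves the cross-probe residual correlation matrix exactly.  An
    explicit ``permutation`` (e.g. the identity, for testing) overrides
    the random draw.
    """
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(residuals.shape[1])
    else:
        permutation = np.asarray(permutation)
        if sorted(permutation.tolist()) != list(range(residuals.shape[1])):
            raise ValueError("permutation must re-order all sample indices")
    return residuals[:, permutation]


def permutation_null_distribution(
    matrix: MethylationMatrix,
    props: CellProportions,
    pheno: PhenotypeTable,
    n_perm: int = 100,
    seed: int = 0,
    null_model: str = "with-main",
    add_back_fitted: bool = False,
) -> PermutationNull:
    """Build the genome-wide interaction null by residual permutation.

    For each of ``n_perm`` replicates: permute the null-model residuals
    with one shared re-ordering, optionally add the fitted values back
    (``add_back_fitted=True``), refit the interaction model with the
    result as the response, and pool all probe x cell-type interaction
    p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    matrix, props, pheno = align_samples(matrix, props, pheno)
    fitted, resid = fit_null_residuals(matrix, props, pheno, null_model=null_model)
    x, _ = _interaction_design(props, pheno)
    k = len(props.cell_types)
    n_probes = matrix.n_probes

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_perm)]
    out = np.empty((n_perm, n_probes * k))
    for r, child in enumerate(child_seeds):
        rp = permute_residuals(resid, child)
        resp = rp + fitted if add_back_fitted else rp
        coef, se, df, _ = _batched_ols(x, resp.T)
        _, p = _t_pvalues(coef[k:2 * k], se[k:2 * k], df)
        out[r] = p.ravel()
    return PermutationNull(
        pvalues=out, n_replicates=n_perm, seeds=child_seeds, null_model=null_model
    )


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic inflation factor lambda: median chi-square ratio.

    Converts two-sided p-values to 1-df chi-square quantiles and divides
    the observed median by the null median (0.4549...).
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def qq_summary(observed_p: np.ndarray, null: PermutationNull) -> pd.DataFrame:
    """Observed-vs-expected quantile table with a permutation envelope.

    Returns one row per order statistic of the observed p-values with
    columns ``expected`` (-log10 uniform quantile), ``observed``
    (-log10 observed), and ``null_lo`` / ``null_hi`` (pointwise min/max of
    the replicate nulls interpolated to the same ranks).  The table's
    ``attrs['lambda']`` carries the genomic inflation factor of the
    observed distribution.
    """
    obs = np.sort(np.asarray(observed_p, dtype=float))
    obs = obs[~np.isnan(obs)]
    if obs.size == 0 or null.pvalues.size == 0:
        raise ValueError("qq_summary requires non-empty inputs")
    m = obs.size
    expected_q = (np.arange(1, m + 1) - 0.5) / m

    null_sorted = np.sort(null.pvalues, axis=1)
    n_null = null_sorted.shape[1]
    null_ranks = (np.arange(1, n_null + 1) - 0.5) / n_null
    # interpolate each replicate's quantile function onto the observed ranks
    interp = np.vstack(
        [np.interp(expected_q, null_ranks, row) for row in null_sorted]
    )
    tiny = np.finfo(float).tiny
    table = pd.DataFrame(
        {
            "expected": -np.log10(expected_q),
            "observed": -np.log10(np.maximum(obs, tiny)),
            "null_lo": -np.log10(np.maximum(interp.max(axis=0), tiny)),
            "null_hi": -np.log10(np.maximum(interp.min(axis=0), tiny)),
        }
    )
    table.attrs["lambda"] = genomic_inflation(obs)
    return table
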
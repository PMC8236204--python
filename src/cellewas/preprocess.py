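"""Probe-level quality filters and the beta <-> M-value transforms.

The M-value is the base-2 logit of the methylation proportion (beta),
M = log2(beta / (1 - beta)); it is the preferred response scale for linear
modelling because its variance is far more homoscedastic across the [0, 1]
range than the beta scale.  Betas are clipped into [eps, 1 - eps] before
the logit so that simulated values of exactly 0 or 1 stay finite.

Probe exclusion applies, in a fixed order, the standard array QC rules:
non-CpG probes, sex-chromosome probes, probes failing detection
(p > 0.05) in at least 5% of samples, probes with a common SNP
(MAF >= 5%) at the target CpG or single-base extension, and known
cross-reactive probes.  A probe triggering several rules is counted under
the first one, so the per-rule counts sum to the number removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BETA, MVALUE, MethylationMatrix, ScaleError

__all__ = [
    "DEFAULT_EPSILON",
    "FilterParams",
    "beta_to_m",
    "m_to_beta",
    "beta_to_m_array",
    "m_to_beta_array",
    "filter_probes",
]

#: Default logit clipping; array betas are never exactly 0/1 after
#: normalization but synthetic data can be.
DEFAULT_EPSILON = 1e-6

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y", "23", "24"})


def beta_to_m_array(beta: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def m_to_beta_array(m: np.ndarray) -> np.ndarray:
    p = np.exp2(np.asarray(m, dtype=float))
    return p / (1.0 + p)


def beta_to_m(
    matrix: MethylationMatrix, epsilon: float = DEFAULT_EPSILON
) -> MethylationMatrix:
    """Logit-transform a beta matrix to M-values.

    Raises :class:`ScaleError` if the input is already on the M scale.
    """
    if matrix.scale != BETA:
        raise ScaleError("beta_to_m expects a beta-scale matrix")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    vals = beta_to_m_array(matrix.values.to_numpy(), epsilon)
    return MethylationMatrix(
        pd.DataFrame(vals, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale=MVALUE,
    )


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse-logit an M-value matrix back to betas."""
    if matrix.scale != MVALUE:
        raise ScaleError("m_to_beta expects an M-scale matrix")
    vals = m_to_beta_array(matrix.values.to_numpy())
    return MethylationMatrix(
        pd.DataFrame(vals, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale=BETA,
    )


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the probe-exclusion rules."""

    detection_p: float = 0.05
    max_failed_fraction: float = 0.05  # inclusive: >= 5% failing samples
    drop_sex_chromosomes: bool = True


RULE_ORDER = (
    "non_cpg",
    "sex_chromosome",
    "detection_failure",
    "snp_maf_ge_5pct",
    "cross_reactive",
)


def filter_probes(
    matrix: MethylationMatrix,
    manifest: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    params: FilterParams = FilterParams(),
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Apply the ordered probe-exclusion rules.

    Parameters
    ----------
    matrix
        Probe x sample methylation values (any scale).
    manifest
        Probe annotation indexed by probe ID with columns ``probe_class``,
        ``chromosome``, ``snp_maf_ge_5pct``, ``cross_reactive``.
    detection_p
        Optional probe x sample detection p-values; when omitted the
        detection rule removes nothing.

    Returns
    -------
    (filtered matrix, report)
        The report has one row per rule with the count of probes removed
        by that rule (first-rule attribution) plus a ``retained`` row.
    """
    probes = matrix.probe_ids
    missing = probes.difference(manifest.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} matrix probes absent from manifest: "
            f"{sorted(missing)[:10]}"
        )
    man = manifest.loc[probes]

    if detection_p is not None:
        dp = detection_p.reindex(index=probes, columns=matrix.sample_ids)
        if dp.isna().any().any():
            raise ValueError("detection_p must cover every matrix probe and sample")
        failed_frac = (dp.to_numpy() > params.detection_p).mean(axis=1)
    else:
        failed_frac = np.zeros(len(probes))

    triggers = {
        "non_cpg": (man["probe_class"] != "CpG").to_numpy(),
        "sex_chromosome": (
            man["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()
            if params.drop_sex_chromosomes
            else np.zeros(len(probes), dtype=bool)
        ),
        # boundary inclusive: failing in exactly 5% of samples removes the probe
        "detection_failure": failed_frac >= params.max_failed_fraction,
        "snp_maf_ge_5pct": man["snp_maf_ge_5pct"].astype(bool).to_numpy(),
        "cross_reactive": man["cross_reactive"].astype(bool).to_numpy(),
    }

    removed = np.zeros(len(probes), dtype=bool)
    counts = {}
    for rule in RULE_ORDER:
        hit = triggers[rule] & ~removed
        counts[rule] = int(hit.sum())
        removed |= hit

    keep = ~removed
    filtered = MethylationMatrix(matrix.values.loc[keep], scale=matrix.scale)
    report = pd.DataFrame(
        {
            "rule": [*RULE_ORDER, "retained"],
            "n_probes": [*[counts[r] for r in RULE_ORDER], int(keep.sum())],
        }
    )
    return filtered, report
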
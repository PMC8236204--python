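"""Synthetic cord-blood methylation mixtures with known ground truth.

Bulk methylation of whole cord blood is, to good approximation, a convex
combination of the methylation profiles of its constituent cell types
weighted by the (unknown) cell-type fractions of each sample.  This module
generates such mixtures from scratch — pure per-cell-type profiles,
Dirichlet-distributed compositions calibrated to a real term-delivery
cohort, a binary exposure (gestational-diabetes-like, ~8.4% prevalence) or
a continuous outcome (BMI-z-like), standard perinatal covariates, and
cell-type-specific phenotype effects spiked at known probes — so that every
downstream stage (deconvolution, interaction EWAS, permutation null) can be
tested against an exact ground truth.

Mixing can be performed on the methylation-proportion (beta) scale, which
is how physical mixtures combine, or on the M-value (base-2 logit) scale,
which is the scale on which the interaction model is fitted and on which
spiked coefficients are recovered exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    BETA,
    MVALUE,
    CORD_BLOOD_CELL_TYPES,
    CORD_BLOOD_MEAN_PROPORTIONS,
    CORD_BLOOD_PROPORTION_SDS,
    CellProportions,
    MethylationMatrix,
    PhenotypeTable,
)
from .preprocess import beta_to_m_array, m_to_beta_array

__all__ = [
    "CovariateSpec",
    "EffectSpec",
    "SimulationConfig",
    "PureProfiles",
    "SimulatedDataset",
    "fit_dirichlet_concentration",
    "simulate_pure_profiles",
    "simulate_proportions",
    "simulate_dataset",
    "write_dataset",
    "DEFAULT_COVARIATES",
    "DEFAULT_DIRICHLET_CONCENTRATION",
]

#: Default covariate generators: maternal age (years), current smoking in
#: early pregnancy, primiparity, gestational age at birth (weeks) and child
#: sex (male=1), with moments matching a typical term-delivery cohort.
DEFAULT_COVARIATES: dict[str, tuple] = {
    "maternal_age": ("normal", 28.5, 4.2),
    "smoking": ("bernoulli", 0.076),
    "parity": ("bernoulli", 0.48),
    "gestational_age": ("normal", 39.5, 1.0),
    "child_sex": ("bernoulli", 0.545),
}


def fit_dirichlet_concentration(
    means: Sequence[float], sds: Sequence[float]
) -> float:
    """Least-squares Dirichlet concentration matching per-type SDs.

    Under a Dirichlet with alpha_k = mean_k * c the marginal SD of
    component k is sqrt(mean_k (1 - mean_k) / (c + 1)).  The closed-form
    least-squares fit of the common factor 1/sqrt(c+1) to the target SDs
    gives c directly.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    a = np.sqrt(m * (1 - m))
    t = float((s * a).sum() / (a * a).sum())
    return 1.0 / t**2 - 1.0


#: Concentration fitted to the default cord-blood composition means/SDs
#: (least-squares over the seven per-type SDs); see ``fit_dirichlet_concentration``.
DEFAULT_DIRICHLET_CONCENTRATION: float = 44.49


@dataclass(frozen=True)
class EffectSpec:
    """A cell-type-specific phenotype effect spiked at one probe.

    ``effect`` is the per-unit-phenotype shift of the pure methylation
    value of ``cell_type`` at ``probe``, expressed on ``scale``
    (``"M"`` or ``"beta"``).
    """

    probe: str
    cell_type: str
    effect: float
    scale: str = MVALUE


#: A covariate distribution: ("normal", mean, sd) or ("bernoulli", p).
CovariateSpec = tuple


@dataclass
class SimulationConfig:
    """All knobs of the generator; one integer seed governs every draw.

    Attributes
    ----------
    n_samples, n_probes
        Cohort and array size.
    cell_types
        Ordered labels; default the seven cord-blood types.
    dirichlet_mean
        Mean composition (sums to 1); default calibrated to a real cohort.
    dirichlet_concentration
        Precision of the Dirichlet; default least-squares-fitted (44.49) to
        the cohort's per-type SDs.  ``math.inf`` collapses every sample to
        the mean composition.
    markers_per_type
        Number of probes per cell type carrying a large (>= 0.5)
        between-type beta difference; the default 100 yields the canonical
        7 x 100 = 700-probe reference panel.
    phenotype
        ``"binary"`` (Bernoulli exposure, prevalence ``case_fraction``) or
        ``"continuous"`` (standard-normal outcome).
    case_fraction
        Prevalence of the binary exposure; default 0.084.
    effects
        Spiked cell-type-specific phenotype effects (ground truth).
    covariate_effects
        Optional per-covariate coefficient applied, on the mixing scale, to
        every probe (lets covariate-recovery tests exercise the rho terms).
    noise_sd
        SD of i.i.d. Gaussian measurement noise added to the bulk signal on
        the mixing scale.
    within_type_sd
        SD of per-sample biological deviation of each pure profile, on the
        mixing scale (0 disables; the magnitude in real tissue is unknown
        and deliberately left caller-controlled).
    mixing_scale
        ``"M"`` (exact coefficient recovery by the interaction model) or
        ``"beta"`` (physical mixing of proportions).
    phenotype_proportion_corr
        Optional ``(cell_type, r)`` inducing correlation r between the
        continuous phenotype and that cell type's fraction.
    """

    n_samples: int = 275
    n_probes: int = 1000
    cell_types: tuple[str, ...] = CORD_BLOOD_CELL_TYPES
    dirichlet_mean: tuple[float, ...] = tuple(
        CORD_BLOOD_MEAN_PROPORTIONS[k] for k in CORD_BLOOD_CELL_TYPES
    )
    dirichlet_concentration: float = DEFAULT_DIRICHLET_CONCENTRATION
    markers_per_type: int = 100
    phenotype: str = "binary"
    case_fraction: float = 0.084
    effects: tuple[EffectSpec, ...] = ()
    covariate_effects: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, CovariateSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    noise_sd: float = 0.5
    within_type_sd: float = 0.0
    mixing_scale: str = MVALUE
    phenotype_proportion_corr: tuple[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ValueError("at least two cell types are required")
        if len(self.dirichlet_mean) != len(self.cell_types):
            raise ValueError("dirichlet_mean length must match cell_types")
        if not math.isclose(sum(self.dirichlet_mean), 1.0, abs_tol=1e-9):
            raise ValueError("dirichlet_mean must sum to 1")
        if not self.dirichlet_concentration > 0:
            raise ValueError("dirichlet_concentration must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.noise_sd < 0 or self.within_type_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.mixing_scale not in (BETA, MVALUE):
            raise ValueError("mixing_scale must be 'beta' or 'M'")
        if self.phenotype not in ("binary", "continuous"):
            raise ValueError("phenotype must be 'binary' or 'continuous'")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)


@dataclass
class PureProfiles:
    """Per-cell-type mean methylation profiles on the beta scale.

    ``baseline`` is cell_type x probe; ``marker_types`` maps each designed
    marker probe to the cell type it discriminates (non-marker probes share
    one common baseline across all types).
    """

    cell_types: tuple[str, ...]
    baseline: pd.DataFrame
    marker_types: pd.Series

    def __post_init__(self) -> None:
        arr = self.baseline.to_numpy()
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("pure profiles must be beta values in [0, 1]")
        if not self.baseline.columns.is_unique:
            raise ValueError("probe IDs must be unique")

    @property
    def probe_ids(self) -> pd.Index:
        return self.baseline.columns

    @property
    def marker_probes(self) -> pd.Index:
        return self.marker_types.index


@dataclass
class SimulatedDataset:
    """A complete simulated study with its generating ground truth."""

    methylation: MethylationMatrix
    true_proportions: CellProportions
    phenotypes: PhenotypeTable
    truth: pd.DataFrame  # columns: probe, cell_type, effect, scale
    config: SimulationConfig


def simulate_pure_profiles(config: SimulationConfig) -> PureProfiles:
    """Draw pure per-cell-type beta profiles with designed marker structure.

    The first ``K * markers_per_type`` probes are markers: for each cell
    type, half are hypermethylated in that type (beta ~ U(0.85, 0.95)
    against U(0.05, 0.15) elsewhere) and half hypomethylated (the
    reverse), guaranteeing a between-type beta difference >= 0.5.  All
    remaining probes share a single baseline value across cell types.
    """
    k = config.n_cell_types
    n_markers = k * config.markers_per_type
    if config.n_probes < n_markers:
        raise ValueError(
            f"n_probes={config.n_probes} cannot host {n_markers} marker probes "
            f"({k} types x {config.markers_per_type})"
        )
    rng = np.random.default_rng(_child_seed(config.seed, "profiles"))
    probes = pd.Index([f"cg{i:08d}" for i in range(config.n_probes)], name="probe_id")
    # common baseline, broadcast to all types
    base = rng.uniform(0.05, 0.95, size=config.n_probes)
    values = np.tile(base, (k, 1))

    marker_map: dict[str, str] = {}
    pos = 0
    per = config.markers_per_type
    n_hyper = (per + 1) // 2
    for t_idx, ct in enumerate(config.cell_types):
        for j in range(per):
            hyper = j < n_hyper
            target = rng.uniform(0.85, 0.95) if hyper else rng.uniform(0.05, 0.15)
            others = rng.uniform(0.05, 0.15) if hyper else rng.uniform(0.85, 0.95)
            values[:, pos] = others
            values[t_idx, pos] = target
            marker_map[probes[pos]] = ct
            pos += 1
    baseline = pd.DataFrame(values, index=list(config.cell_types), columns=probes)
    marker_types = pd.Series(marker_map, name="cell_type")
    marker_types.index.name = "probe_id"
    return PureProfiles(tuple(config.cell_types), baseline, marker_types)


def simulate_proportions(config: SimulationConfig) -> CellProportions:
    """Draw per-sample compositions from Dirichlet(mean * concentration)."""
    mean = np.asarray(config.dirichlet_mean, dtype=float)
    samples = pd.Index(
        [f"S{i:05d}" for i in range(config.n_samples)], name="sample_id"
    )
    if math.isinf(config.dirichlet_concentration):
        frac = np.tile(mean, (config.n_samples, 1))
    else:
        rng = np.random.default_rng(_child_seed(config.seed, "proportions"))
        alpha = mean * config.dirichlet_concentration
        frac = rng.dirichlet(alpha, size=config.n_samples)
    df = pd.DataFrame(frac, index=samples, columns=list(config.cell_types))
    return CellProportions(df)


def _simulate_phenotype_covariates(
    config: SimulationConfig, props: CellProportions
) -> PhenotypeTable:
    rng = np.random.default_rng(_child_seed(config.seed, "phenotype"))
    n = config.n_samples
    cols: dict[str, np.ndarray] = {}
    if config.phenotype == "binary":
        y = (rng.uniform(size=n) < config.case_fraction).astype(float)
    else:
        y = rng.standard_normal(n)
        if config.phenotype_proportion_corr is not None:
            ct, r = config.phenotype_proportion_corr
            f = props.fractions[ct].to_numpy()
            fz = (f - f.mean()) / f.std()
            y = r * fz + math.sqrt(max(0.0, 1 - r**2)) * y
    cols["phenotype"] = y
    for name, spec in config.covariates.items():
        kind = spec[0]
        if kind == "normal":
            cols[name] = spec[1] + spec[2] * rng.standard_normal(n)
        elif kind == "bernoulli":
            cols[name] = (rng.uniform(size=n) < spec[1]).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
    df = pd.DataFrame(cols, index=props.sample_ids)
    return PhenotypeTable(df, phenotype="phenotype", covariates=list(config.covariates))


def simulate_dataset(
    config: SimulationConfig, profiles: PureProfiles | None = None
) -> SimulatedDataset:
    """Assemble bulk mixtures with spiked cell-type-specific effects.

    The bulk signal at probe c of sample i is sum_k f_ki * v_kci where
    v_kci is the pure value of cell type k on the mixing scale, shifted by
    y_i * effect for any spiked (probe, cell type), plus optional
    within-type biological deviation; i.i.d. Gaussian measurement noise is
    added on the mixing scale, and covariate effects (if any) enter
    additively.  When mixing on the M scale the interaction model holds
    exactly by construction.
    """
    if profiles is None:
        profiles = simulate_pure_profiles(config)
    if tuple(profiles.cell_types) != tuple(config.cell_types):
        raise ValueError("profiles and config disagree on cell types")
    props = simulate_proportions(config)
    pheno = _simulate_phenotype_covariates(config, props)
    rng = np.random.default_rng(_child_seed(config.seed, "mixing"))

    k = config.n_cell_types
    n = config.n_samples
    p = len(profiles.probe_ids)
    y = pheno.y
    frac = props.fractions.to_numpy()  # n x K

    pure_beta = profiles.baseline.to_numpy()  # K x P
    if config.mixing_scale == MVALUE:
        pure = beta_to_m_array(pure_beta)
    else:
        pure = pure_beta.copy()

    # delta[k, c] holds the spiked per-unit-phenotype shift on the mixing scale
    probe_pos = {pid: i for i, pid in enumerate(profiles.probe_ids)}
    type_pos = {ct: i for i, ct in enumerate(config.cell_types)}
    truth_rows = []
    delta = np.zeros((k, p))
    for eff in config.effects:
        if eff.probe not in probe_pos:
            raise KeyError(f"spiked probe {eff.probe!r} not in profiles")
        ci, ki = probe_pos[eff.probe], type_pos[eff.cell_type]
        if eff.scale == config.mixing_scale:
            delta[ki, ci] += eff.effect
        elif eff.scale == BETA and config.mixing_scale == MVALUE:
            # shift the pure beta, re-express the per-unit shift in M
            b0 = pure_beta[ki, ci]
            b1 = b0 + eff.effect
            if not 0 <= b1 <= 1:
                raise ValueError(
                    f"beta-scale effect at probe {eff.probe!r} pushes the pure "
                    f"value to {b1:.3f}, outside [0, 1]"
                )
            delta[ki, ci] += float(beta_to_m_array(np.array(b1)) - pure[ki, ci])
        else:
            raise ValueError(
                f"cannot spike an M-scale effect when mixing on the beta scale "
                f"(probe {eff.probe!r})"
            )
        truth_rows.append(
            {"probe": eff.probe, "cell_type": eff.cell_type,
             "effect": eff.effect, "scale": eff.scale}
        )
        if config.mixing_scale == BETA:
            worst = pure_beta[ki, ci] + delta[ki, ci] * (
                y.max() if eff.effect > 0 else y.min()
            )
            if not -1e-9 <= worst <= 1 + 1e-9:
                raise ValueError(
                    f"beta-scale effect at probe {eff.probe!r} pushes the pure "
                    f"value to {worst:.3f}, outside [0, 1]"
                )

    # bulk = F @ pure (+ per-sample spiked shifts + biological deviation)
    bulk = frac @ pure
    if delta.any():
        spiked_cols = np.flatnonzero(delta.any(axis=0))
        # contribution of spikes: sum_k f_ki * y_i * delta_kc
        bulk[:, spiked_cols] += (frac * y[:, None]) @ delta[:, spiked_cols]
    if config.within_type_sd > 0:
        # per-sample deviation of each pure profile around its mean
        dev = rng.normal(0.0, config.within_type_sd, size=(n, k, p))
        bulk += np.einsum("nk,nkp->np", frac, dev)
    if config.covariate_effects:
        z = pheno.data[list(config.covariate_effects)].to_numpy(dtype=float)
        rho = np.array([config.covariate_effects[c] for c in config.covariate_effects])
        bulk += (z @ rho)[:, None]
    if config.noise_sd > 0:
        bulk += rng.normal(0.0, config.noise_sd, size=(n, p))
    if config.mixing_scale == BETA:
        bulk = np.clip(bulk, 0.0, 1.0)

    matrix = MethylationMatrix(
        pd.DataFrame(bulk.T, index=profiles.probe_ids, columns=props.sample_ids),
        scale=config.mixing_scale,
    )
    truth = pd.DataFrame(truth_rows, columns=["probe", "cell_type", "effect", "scale"])
    return SimulatedDataset(matrix, props, pheno, truth, config)


def make_manifest(
    probe_ids: Sequence[str],
    chromosomes: Sequence[str] | None = None,
    spacing: int = 1000,
) -> pd.DataFrame:
    """All-clean manifest for simulated probes, laid out along chromosomes."""
    n = len(probe_ids)
    if chromosomes is None:
        chromosomes = [f"chr{1 + (i % 22)}" for i in range(n)]
    positions = [spacing * (1 + i // 22) for i in range(n)]
    df = pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "chromosome": list(chromosomes),
            "position": positions,
            "probe_class": "CpG",
            "snp_maf_ge_5pct": False,
            "cross_reactive": False,
        }
    )
    return df.set_index("probe_id", drop=False)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write the dataset as plain TSV plus a key/value config file."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.methylation.to_tsv(out / "methylation.tsv")
    ds.true_proportions.to_tsv(out / "true_proportions.tsv")
    ds.phenotypes.to_tsv(out / "samples.tsv")
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    make_manifest(ds.methylation.probe_ids).to_csv(out / "manifest.csv", index=False)
    with open(out / "config.txt", "w") as fh:
        fh.write("[simulation]\n")
        for key, val in asdict(ds.config).items():
            fh.write(f"{key} = {val!r}\n")


def _child_seed(seed: int, stream: str) -> np.random.SeedSequence:
    """Independent, reproducible stream per simulation stage."""
    return np.random.SeedSequence(seed, spawn_key=(zlib.crc32(stream.encode()),))
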
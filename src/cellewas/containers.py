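"""Core in-memory containers shared across the pipeline.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that every stage of the pipeline (simulation, preprocessing,
deconvolution, association testing) exchanges the same objects and the
TSV/CSV round-trips are trivial.

Conventions
-----------
* Methylation matrices are probe x sample (probes as rows).
* Cell-proportion tables are sample x cell type, rows on the simplex.
* Phenotype tables are sample x column with one designated phenotype
  column and an explicit list of covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BETA = "beta"
MVALUE = "M"

#: The seven cord-blood cell types resolved by the default reference design,
#: in canonical order: B cells, CD4+ T cells, CD8+ T cells, granulocytes,
#: monocytes, natural killer cells and nucleated red blood cells.
CORD_BLOOD_CELL_TYPES: tuple[str, ...] = (
    "B", "CD4T", "CD8T", "Gran", "Mono", "NK", "nRBC",
)

#: Typical estimated cord-blood cell-type composition (fractions) in a
#: term-delivery cohort; used as the default Dirichlet mean.
CORD_BLOOD_MEAN_PROPORTIONS: dict[str, float] = {
    "B": 0.095,
    "CD4T": 0.158,
    "CD8T": 0.126,
    "Gran": 0.399,
    "Mono": 0.090,
    "NK": 0.020,
    "nRBC": 0.112,
}

#: Between-sample standard deviations (fractions) that accompany the
#: composition means above.
CORD_BLOOD_PROPORTION_SDS: dict[str, float] = {
    "B": 0.030,
    "CD4T": 0.053,
    "CD8T": 0.034,
    "Gran": 0.092,
    "Mono": 0.026,
    "NK": 0.026,
    "nRBC": 0.059,
}


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong scale."""


@dataclass
class MethylationMatrix:
    """Probe x sample methylation values with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame with probe IDs as the index and sample IDs as columns.
    scale
        ``"beta"`` for methylation proportions in [0, 1] or ``"M"`` for
        the base-2 logit of the proportion.
    """

    values: pd.DataFrame
    scale: str = BETA

    def __post_init__(self) -> None:
        if self.scale not in (BETA, MVALUE):
            raise ScaleError(f"unknown scale {self.scale!r}; expected 'beta' or 'M'")
        if not self.values.index.is_unique:
            raise ValueError("probe IDs must be unique")
        arr = self.values.to_numpy()
        if self.scale == BETA and arr.size:
            lo, hi = np.nanmin(arr), np.nanmax(arr)
            if lo < 0 or hi > 1:
                raise ValueError(
                    f"beta-scale values must lie in [0, 1]; found range [{lo}, {hi}]"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = BETA) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(df, scale=scale)


@dataclass
class CellProportions:
    """Sample x cell-type fraction table.

    ``fractions`` holds the working (possibly normalized) values; ``raw``
    optionally retains the pre-normalization non-negative weights produced
    by constrained projection.
    """

    fractions: pd.DataFrame
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.fractions.to_numpy() < -1e-12).any():
            raise ValueError("cell-type fractions must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index

    @property
    def n_samples(self) -> int:
        return self.fractions.shape[0]

    def is_normalized(self, tol: float = 1e-8) -> bool:
        return bool(np.allclose(self.fractions.sum(axis=1).to_numpy(), 1.0, atol=tol))

    def to_tsv(self, path: str | Path) -> None:
        out = self.fractions.copy()
        if self.raw is not None:
            raw = self.raw.add_suffix("_raw")
            out = pd.concat([out, raw], axis=1)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellProportions":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        raw_cols = [c for c in df.columns if c.endswith("_raw")]
        raw = None
        if raw_cols:
            raw = df[raw_cols].rename(columns=lambda c: c[: -len("_raw")])
            df = df.drop(columns=raw_cols)
        return cls(df, raw=raw)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype and covariates.

    ``phenotype`` names the column holding the outcome / exposure of
    interest (binary 0/1 or continuous); ``covariates`` lists the adjustment
    columns, all of which must be complete for analyzed samples.
    """

    data: pd.DataFrame
    phenotype: str
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in [self.phenotype, *self.covariates] if c not in self.data.columns]
        if missing:
            raise KeyError(f"phenotype table lacks columns: {missing}")
        if self.data[self.phenotype].isna().any():
            raise ValueError("missing phenotype values; drop those samples first")
        if self.data[self.covariates].isna().any().any():
            raise ValueError("missing covariate values; drop those samples first")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def y(self) -> np.ndarray:
        return self.data[self.phenotype].to_numpy(dtype=float)

    @property
    def z(self) -> np.ndarray:
        """Covariate matrix (n x q); empty second dimension when no covariates."""
        return self.data[self.covariates].to_numpy(dtype=float).reshape(len(self.data), -1)

    def dropna(self) -> "PhenotypeTable":
        keep = self.data[[self.phenotype, *self.covariates]].notna().all(axis=1)
        return PhenotypeTable(self.data.loc[keep], self.phenotype, list(self.covariates))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def align_samples(
    matrix: MethylationMatrix,
    props: CellProportions,
    pheno: PhenotypeTable,
) -> tuple[MethylationMatrix, CellProportions, PhenotypeTable]:
    """Align the three inputs on a common sample ordering.

    Raises
    ------
    ValueError
        If the three objects do not cover an identical sample set.
    """
    s_m = set(matrix.sample_ids)
    s_p = set(props.sample_ids)
    s_y = set(pheno.sample_ids)
    if not (s_m == s_p == s_y):
        raise ValueError(
            "sample sets differ between methylation matrix, proportions and "
            f"phenotypes (sizes {len(s_m)}, {len(s_p)}, {len(s_y)})"
        )
    order = list(matrix.sample_ids)
    return (
        matrix,
        CellProportions(props.fractions.loc[order], raw=None if props.raw is None else props.raw.loc[order]),
        PhenotypeTable(pheno.data.loc[order], pheno.phenotype, list(pheno.covariates)),
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest CSV with the canonical field names.

    Expected columns: ``probe_id``, ``chromosome``, ``position``,
    ``probe_class`` (CpG / non-CpG), ``snp_maf_ge_5pct``, ``cross_reactive``.
    """
    df = pd.read_csv(path)
    required = {"probe_id", "chromosome", "position", "probe_class",
                "snp_maf_ge_5pct", "cross_reactive"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"manifest lacks columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ValueError("manifest probe IDs must be unique")
    return df.set_index("probe_id", drop=False)
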
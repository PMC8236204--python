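"""Reference-based cell-type deconvolution by constrained projection.

Each bulk sample's beta values at a panel of marker CpGs are projected
onto the reference profiles by non-negative least squares,

    min_{w >= 0} || beta_markers - Panel^T w ||^2,

and the raw weights are then explicitly renormalized to the simplex,
f_k = w_k / sum_j w_j, mirroring the two-stage estimate-then-normalize
procedure used with cord-blood reference panels.  The panel itself is
built from pure profiles by taking, per cell type, the most
hypermethylated and most hypomethylated one-vs-rest discriminating
probes (default 50 + 50, giving the canonical 700-probe panel for seven
cell types).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import BETA, CellProportions, MethylationMatrix
from .simulate import PureProfiles

__all__ = [
    "ReferencePanel",
    "select_reference_probes",
    "estimate_proportions",
    "normalize_proportions",
    "deconvolve",
]


@dataclass
class ReferencePanel:
    """Marker-probe reference: cell_type x marker matrix of mean betas."""

    profiles: pd.DataFrame  # cell_type x marker probes

    def __post_init__(self) -> None:
        arr = self.profiles.to_numpy()
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("reference panel values must be betas in [0, 1]")
        if np.linalg.matrix_rank(arr) < len(self.profiles):
            raise ValueError("reference panel is rank-deficient")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def marker_probes(self) -> pd.Index:
        return self.profiles.columns

    def to_csv(self, path: str | Path) -> None:
        # rows = marker probes, columns = cell types
        self.profiles.T.to_csv(path, index_label="probe_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferencePanel":
        df = pd.read_csv(path, index_col="probe_id")
        return cls(df.T)


def select_reference_probes(
    profiles: PureProfiles, n_per_type: int = 100
) -> ReferencePanel:
    """Rank probes by one-vs-rest mean beta difference and build the panel.

    For each cell type the top ``n_per_type/2`` hypermethylated (largest
    positive difference) and ``n_per_type/2`` hypomethylated (largest
    negative difference) probes are taken, without replacement across
    types, yielding at most K * n_per_type markers.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be a positive count")
    base = profiles.baseline  # cell_type x probe
    k = len(profiles.cell_types)
    arr = base.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            if np.array_equal(arr[i], arr[j]):
                raise ValueError(
                    f"pure profiles of {profiles.cell_types[i]!r} and "
                    f"{profiles.cell_types[j]!r} are identical; no "
                    "discriminating probes exist"
                )
    n_hyper = (n_per_type + 1) // 2
    n_hypo = n_per_type - n_hyper
    taken: set[str] = set()
    selected: list[str] = []
    for i, ct in enumerate(profiles.cell_types):
        others = np.delete(arr, i, axis=0).mean(axis=0)
        score = pd.Series(arr[i] - others, index=base.columns)
        avail = score.drop(labels=[p for p in taken if p in score.index])
        ranked = avail.sort_values()
        hyper = list(ranked.index[-n_hyper:]) if n_hyper else []
        hypo = list(ranked.index[:n_hypo]) if n_hypo else []
        chosen = hypo + hyper
        taken.update(chosen)
        selected.extend(chosen)
    panel = base[selected]
    return ReferencePanel(panel)


def estimate_proportions(
    betas: MethylationMatrix, panel: ReferencePanel
) -> CellProportions:
    """Per-sample non-negative least-squares projection onto the panel.

    Returns *raw* (unnormalized) weights in ``fractions``; apply
    :func:`normalize_proportions` to place them on the simplex.
    """
    if betas.scale != BETA:
        raise ValueError("deconvolution operates on beta-scale values")
    missing = panel.marker_probes.difference(betas.probe_ids)
    if len(missing):
        raise KeyError(
            f"{len(missing)} marker probes missing from matrix: "
            f"{sorted(missing)[:10]}"
        )
    a = panel.profiles.T.to_numpy()  # markers x K
    sub = betas.values.loc[panel.marker_probes]  # markers x samples
    w = np.empty((sub.shape[1], a.shape[1]))
    b_all = sub.to_numpy()
    for s in range(sub.shape[1]):
        w[s], _ = nnls(a, b_all[:, s])
    raw = pd.DataFrame(w, index=betas.sample_ids, columns=panel.cell_types)
    return CellProportions(raw.copy(), raw=raw)


def normalize_proportions(props: CellProportions) -> CellProportions:
    """Renormalize raw weights to sum to 1 per sample."""
    raw = props.raw if props.raw is not None else props.fractions
    totals = raw.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = list(raw.index[zero])
        raise ValueError(f"all-zero raw proportions for samples: {bad[:10]}")
    frac = raw.div(totals, axis=0)
    return CellProportions(frac, raw=raw)


def deconvolve(
    betas: MethylationMatrix, panel: ReferencePanel
) -> CellProportions:
    """Estimate and renormalize in one call."""
    return normalize_proportions(estimate_proportions(betas, panel))
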
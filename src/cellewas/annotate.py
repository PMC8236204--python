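"""Gene-relative probe annotation and locus-level result summaries.

Probes are assigned, strand-aware and in 1-based inclusive coordinates,
to one of four regions relative to a caller-supplied gene model:

* ``upstream_regulatory`` — within 1,500 bp upstream of the transcription
  start site, or inside the 5' UTR;
* ``downstream_regulatory`` — inside the 3' UTR;
* ``gene_body`` — anywhere else within [start, end];
* ``intergenic`` — none of the above.

When a probe hits several genes, all gene IDs are reported and the most
regulatory label wins (upstream > downstream > body).  Gene models can be
read from GFF3 or BED12; BED's 0-based half-open coordinates are
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ewas import CellSpecificEwasResult, bonferroni_threshold

__all__ = [
    "GeneModel",
    "read_bed12",
    "read_gff3",
    "classify_probe_region",
    "annotate_probes",
    "summarize_loci",
    "manhattan_table",
    "UPSTREAM_WINDOW",
]

log = logging.getLogger(__name__)

#: Size of the promoter-proximal window upstream of the TSS (bp).
UPSTREAM_WINDOW = 1500

_LABEL_PRIORITY = {"upstream_regulatory": 0, "downstream_regulatory": 1, "gene_body": 2}


@dataclass
class GeneModel:
    """One gene's coordinates, 1-based inclusive.

    ``utr5`` / ``utr3`` are lists of (start, end) intervals; they may be
    empty when the annotation does not resolve UTRs.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def upstream_window(self) -> tuple[int, int]:
        """1,500 bp promoter-proximal window, strand-aware, TSS-exclusive."""
        if self.strand == "+":
            return (self.tss - UPSTREAM_WINDOW, self.tss - 1)
        return (self.tss + 1, self.tss + UPSTREAM_WINDOW)


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read BED12 gene models, inferring UTRs from thickStart/thickEnd.

    BED is 0-based half-open; coordinates are converted to 1-based
    inclusive here.  The thick (CDS) region splits the transcript into a
    5' and a 3' UTR by strand; fully non-coding entries (thickStart ==
    thickEnd) yield no UTRs.
    """
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError("BED12 requires at least 6 columns")
            chrom, cstart, cend, name, _, strand = f[:6]
            start0, end0 = int(cstart), int(cend)
            start, end = start0 + 1, end0  # to 1-based inclusive
            utr5: list[tuple[int, int]] = []
            utr3: list[tuple[int, int]] = []
            if len(f) >= 8:
                thick_s0, thick_e0 = int(f[6]), int(f[7])
                if thick_e0 > thick_s0:  # coding
                    left = (start, thick_s0) if thick_s0 >= start0 + 1 else None
                    right = (thick_e0 + 1, end) if thick_e0 + 1 <= end else None
                    if strand == "+":
                        if left and left[0] <= left[1]:
                            utr5.append(left)
                        if right and right[0] <= right[1]:
                            utr3.append(right)
                    else:
                        if left and left[0] <= left[1]:
                            utr3.append(left)
                        if right and right[0] <= right[1]:
                            utr5.append(right)
            models.append(GeneModel(name, chrom, strand, start, end, utr5, utr3))
    return models


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene + UTR features from a GFF3 file (1-based inclusive already).

    ``gene`` features define the models; ``five_prime_UTR`` /
    ``three_prime_UTR`` features are attached via their ``Parent`` chain
    (resolved through mRNA/transcript features by ``gffutils``).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        m = GeneModel(gene.id, gene.seqid, gene.strand, gene.start, gene.end)
        for utr in db.children(gene, featuretype="five_prime_UTR"):
            m.utr5.append((utr.start, utr.end))
        for utr in db.children(gene, featuretype="three_prime_UTR"):
            m.utr3.append((utr.start, utr.end))
        models.append(m)
    return models


def classify_probe_region(
    chromosome: str,
    position: int,
    models: list[GeneModel],
) -> tuple[str, list[str]]:
    """Assign one probe to its gene-relative region.

    Returns ``(label, gene_ids)`` with label in {upstream_regulatory,
    downstream_regulatory, gene_body, intergenic, unplaced}.  Probes on a
    chromosome absent from the models are labelled ``unplaced`` with a
    warning in the log.
    """
    chroms = {m.chromosome for m in models}
    if chromosome not in chroms:
        log.warning("probe chromosome %s not present in gene models", chromosome)
        return "unplaced", []
    hits: list[tuple[str, str]] = []
    for m in models:
        if m.chromosome != chromosome:
            continue
        label = None
        lo, hi = m.upstream_window()
        if lo <= position <= hi or any(s <= position <= e for s, e in m.utr5):
            label = "upstream_regulatory"
        elif any(s <= position <= e for s, e in m.utr3):
            label = "downstream_regulatory"
        elif m.start <= position <= m.end:
            label = "gene_body"
        if label is not None:
            hits.append((label, m.gene_id))
    if not hits:
        return "intergenic", []
    best = min(hits, key=lambda h: _LABEL_PRIORITY[h[0]])[0]
    return best, sorted({g for _, g in hits})


def annotate_probes(
    manifest: pd.DataFrame, models: list[GeneModel]
) -> pd.DataFrame:
    """Classify every manifest probe; returns probe_id, region, gene_ids."""
    rows = []
    for pid, rec in manifest.iterrows():
        label, gids = classify_probe_region(
            rec["chromosome"], int(rec["position"]), models
        )
        rows.append({"probe_id": pid, "region": label, "gene_ids": ",".join(gids)})
    return pd.DataFrame(rows).set_index("probe_id")


def summarize_loci(
    results: CellSpecificEwasResult,
    fdr_cut: float = 0.05,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Locus-level significance bookkeeping.

    One row per probe significant (FDR < ``fdr_cut``) in at least one cell
    type, with the number of significant cell types, a Bonferroni flag at
    ``bonferroni_alpha / n_probes`` on the raw p, and — for beta-scale
    fits — hyper/hypo flags where the estimated effect saturated at +1/-1
    (a complete methylated/unmethylated shift in that cell type).
    """
    tab = results.table
    n_probes = tab["probe"].nunique()
    sig = tab[tab["fdr"] < fdr_cut]
    if sig.empty:
        return pd.DataFrame(
            columns=[
                "probe", "n_sig_cell_types", "cell_types", "min_p",
                "bonferroni", "hyper_shift", "hypo_shift",
            ]
        )
    bonf = bonferroni_threshold(bonferroni_alpha, n_probes)
    rows = []
    for probe, grp in sig.groupby("probe", sort=False):
        hyper = bool(((grp["clipped"]) & (grp["estimate"] > 0)).any()) if "clipped" in grp else False
        hypo = bool(((grp["clipped"]) & (grp["estimate"] < 0)).any()) if "clipped" in grp else False
        rows.append(
            {
                "probe": probe,
                "n_sig_cell_types": len(grp),
                "cell_types": ",".join(grp["cell_type"]),
                "min_p": float(grp["p"].min()),
                "bonferroni": bool((grp["p"] < bonf).any()),
                "hyper_shift": hyper,
                "hypo_shift": hypo,
            }
        )
    return pd.DataFrame(rows)


def manhattan_table(
    results: CellSpecificEwasResult,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Genome-ordered table of -log10 p per probe x cell type.

    Rows are sorted by (chromosome, position); the Bonferroni line value
    at ``alpha / n_tests`` (default n_tests = number of probes) is stored
    in ``attrs['bonferroni_line']``.  Rows with missing p-values are
    dropped and their count logged.
    """
    tab = results.table.merge(
        manifest[["chromosome", "position"]],
        left_on="probe",
        right_index=True,
        how="left",
    )
    n_missing = int(tab["p"].isna().sum())
    if n_missing:
        log.info("manhattan_table: dropping %d rows with missing p", n_missing)
        tab = tab.dropna(subset=["p"])
    tab = tab.assign(neg_log10_p=-np.log10(tab["p"].clip(lower=np.finfo(float).tiny)))

    def _chrom_key(c: str) -> tuple[int, str]:
        s = str(c).removeprefix("chr")
        return (0, f"{int(s):02d}") if s.isdigit() else (1, s)

    tab = tab.assign(_key=tab["chromosome"].map(_chrom_key))
    tab = tab.sort_values(["_key", "position"]).drop(columns="_key")
    out = tab[
        ["probe", "cell_type", "chromosome", "position", "p", "neg_log10_p"]
    ].reset_index(drop=True)
    nt = n_tests if n_tests is not None else results.table["probe"].nunique()
    out.attrs["bonferroni_line"] = bonferroni_threshold(alpha, nt)
    out.attrs["n_dropped_missing_p"] = n_missing
    return out
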
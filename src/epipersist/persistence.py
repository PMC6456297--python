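"""Germline-to-soma DMR persistence analysis.

DMR sets from two tissues (e.g., mutant sperm vs control sperm and
offspring bone marrow vs control bone marrow) computed on the same 100-bp
tile grid are intersected by exact tile identity; the overlap is tested
against the hypergeometric expectation over the covered-tile universe, and
shared DMRs are classified by sign concordance of their methylation deltas.
Concordant-hypermethylated shared DMRs form the 'persistent' set — the
candidate unit of inherited methylation state — which can then be tested
for recurrence in further tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats

CONC_HYPER, CONC_HYPO, DISCORDANT = "concordant-hyper", "concordant-hypo", "discordant"


def intersect_dmrs(sperm: pd.DataFrame, soma: pd.DataFrame) -> pd.DataFrame:
    """Shared DMRs: tiles significant in BOTH sets, matched by tile id.

    Inputs are significant-DMR frames (post-masking, post-thinning) with
    columns (tile_id, chrom, start, end, delta).  The result carries both
    deltas and a concordance class per shared tile: concordant-hyper when
    both deltas are positive, concordant-hypo when both negative,
    discordant otherwise.
    """
    for frame, name in ((sperm, "sperm"), (soma, "soma")):
        if "tile_id" not in frame.columns:
            raise ValueError(f"{name} frame lacks tile_id")
    widths_a = (sperm["end"] - sperm["start"]).max() if len(sperm) else None
    widths_b = (soma["end"] - soma["start"]).max() if len(soma) else None
    if widths_a is not None and widths_b is not None and widths_a != widths_b:
        raise ValueError("DMR sets use different tiling widths")
    merged = sperm.merge(
        soma[["tile_id", "delta"]], on="tile_id", suffixes=("_sperm", "_soma")
    ).rename(columns={"delta_sperm": "delta_sperm", "delta_soma": "delta_soma"})
    ds, dm = merged["delta_sperm"].to_numpy(), merged["delta_soma"].to_numpy()
    concordance = np.where(
        (ds > 0) & (dm > 0), CONC_HYPER, np.where((ds < 0) & (dm < 0), CONC_HYPO, DISCORDANT)
    )
    merged["concordance"] = concordance
    return merged[["tile_id", "chrom", "start", "end", "delta_sperm", "delta_soma", "concordance"]]


def overlap_enrichment(shared: int, sperm_n: int, soma_n: int, universe: int) -> stats.OverlapTestResult:
    """Hypergeometric enrichment of the shared-DMR count over the universe."""
    return stats.hypergeom_overlap(universe, sperm_n, soma_n, shared)


@dataclass
class PersistenceReport:
    """Summary of the sperm-soma DMR intersection."""

    universe: int
    sperm_dmrs: int
    soma_dmrs: int
    shared: int
    overlap: stats.OverlapTestResult
    pearson: stats.TestResult | None
    counts: dict[str, int]
    fractions: dict[str, float]
    persistent: pd.DataFrame = field(repr=False)

    def to_text(self) -> str:
        lines = [
            f"covered-tile universe: {self.universe}",
            f"sperm DMRs: {self.sperm_dmrs}",
            f"soma DMRs: {self.soma_dmrs}",
            f"shared DMRs: {self.shared} (expected {self.overlap.expected:.1f}, "
            f"hypergeometric p = {self.overlap.p:.3g})",
        ]
        if self.pearson is not None:
            lines.append(f"delta correlation: R = {self.pearson.statistic:.3f}, p = {self.pearson.p:.3g}")
        for cls in (CONC_HYPER, CONC_HYPO, DISCORDANT):
            lines.append(
                f"{cls}: {self.counts.get(cls, 0)} ({100 * self.fractions.get(cls, 0.0):.0f}%)"
            )
        lines.append(f"persistent DMRs (concordant-hyper): {len(self.persistent)}")
        return "\n".join(lines)


def classify_persistence(
    shared: pd.DataFrame,
    universe: int | None = None,
    sperm_n: int | None = None,
    soma_n: int | None = None,
) -> PersistenceReport:
    """Concordance classification and persistence summary of shared DMRs.

    Pearson R is computed over (delta_sperm, delta_soma) of ALL shared
    DMRs; the persistent set is the concordant-hyper subset.  When the
    margins (universe and the two DMR counts) are provided, the
    hypergeometric overlap test is included.
    """
    k = len(shared)
    counts = {cls: int((shared["concordance"] == cls).sum()) for cls in (CONC_HYPER, CONC_HYPO, DISCORDANT)} if k else {}
    fractions = {cls: c / k for cls, c in counts.items()} if k else {}
    persistent = (
        shared[shared["concordance"] == CONC_HYPER].reset_index(drop=True)
        if k
        else shared.copy()
    )
    pearson = None
    if k >= 3 and shared["delta_sperm"].std() > 0 and shared["delta_soma"].std() > 0:
        pearson = stats.pearson_r(shared["delta_sperm"], shared["delta_soma"])
    if universe is not None and sperm_n is not None and soma_n is not None:
        overlap = overlap_enrichment(k, sperm_n, soma_n, universe)
    else:
        overlap = stats.OverlapTestResult(0, 0, 0, k, float("nan"), float("nan"))
    return PersistenceReport(
        universe=universe or 0,
        sperm_dmrs=sperm_n or 0,
        soma_dmrs=soma_n or 0,
        shared=k,
        overlap=overlap,
        pearson=pearson,
        counts=counts,
        fractions=fractions,
        persistent=persistent,
    )


@dataclass
class CrossTissueResult:
    """Recurrence of the persistent set in a further tissue's DMRs."""

    tissue: str
    persistent_n: int
    overlap_n: int
    fraction: float
    odds_ratio: float
    fisher_p: float
    pearson: stats.TestResult | None


def cross_tissue(
    persistent: pd.DataFrame,
    tissue_dmrs: pd.DataFrame,
    universe: int,
    tissue: str = "tissue",
) -> CrossTissueResult:
    """Overlap of persistent DMRs with another tissue's DMR set.

    The 2x2 table crosses persistent-set membership with tissue-DMR
    membership over the covered-tile universe; reported are the overlap
    fraction of the persistent set, the Fisher odds ratio and p (odds
    ratio may be infinite when the tissue set contains the whole
    persistent set), and the Pearson correlation of deltas on the overlap.
    """
    if persistent.empty:
        raise ValueError("empty persistent set")
    p_ids = set(persistent["tile_id"])
    t_ids = set(tissue_dmrs["tile_id"])
    k = len(p_ids & t_ids)
    a, b = k, len(p_ids) - k
    c = len(t_ids) - k
    d = universe - a - b - c
    if d < 0:
        raise ValueError("universe smaller than the union of sets")
    res = stats.fisher_exact([[a, b], [c, d]])
    pearson = None
    both = persistent.merge(tissue_dmrs[["tile_id", "delta"]], on="tile_id")
    if len(both) >= 3 and both["delta_sperm"].std() > 0 and both["delta"].std() > 0:
        pearson = stats.pearson_r(both["delta_sperm"], both["delta"])
    return CrossTissueResult(
        tissue=tissue,
        persistent_n=len(p_ids),
        overlap_n=k,
        fraction=k / len(p_ids),
        odds_ratio=res.odds_ratio if res.odds_ratio is not None else float("nan"),
        fisher_p=res.p,
        pearson=pearson,
    )


def write_report(report: PersistenceReport, path: str | Path) -> None:
    from . import __version__

    Path(path).write_text(f"# epipersist v{__version__} persistence report\n{report.to_text()}\n")


def write_shared_tsv(shared: pd.DataFrame, path: str | Path) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# epipersist v{__version__} shared DMRs\n")
        shared.to_csv(fh, sep="\t", index=False, float_format="%.6g")
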
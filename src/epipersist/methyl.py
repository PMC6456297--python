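"""RRBS tile aggregation and differential-methylation calling on 100-bp tiles.

Per-CpG methylated/total counts are summed within fixed 100-bp tiles; a
tile enters the analysis universe only when every sample covers it with at
least ``min_coverage`` reads.  Differential methylation per tile is a
likelihood-ratio test of a binomial regression of methylated/total on the
group indicator against the intercept-only model (the logistic-regression
approach standard for bisulfite tile data), with Benjamini–Hochberg
q-values across all tested tiles.  Because within-group maximum-likelihood
fits are the pooled group proportions, the deviance reduces to the G
statistic of the pooled 2x2 table; the per-sample structure enters through
the optional overdispersion (scale) correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import stats
from .intervals import FeatureSet, GenomeTiling, overlaps_any_bulk

logger = logging.getLogger(__name__)


@dataclass
class MethTileTable:
    """Per-tile per-sample (methylated, total) counts on one tiling.

    Rows are retained tiles (``tile_ids``), columns are ``samples``;
    ``meth`` and ``total`` are aligned integer matrices.
    """

    tiling: GenomeTiling
    tile_ids: np.ndarray
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape or self.meth.shape[0] != self.tile_ids.size:
            raise ValueError("meth/total matrices must align with tile ids")
        if np.any(self.meth > self.total):
            raise ValueError("methylated counts exceed totals")

    def sample_index(self, names: list[str]) -> np.ndarray:
        try:
            return np.asarray([self.samples.index(n) for n in names])
        except ValueError as exc:
            raise KeyError(f"unknown sample in {names}") from exc


def read_bismark_cov(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Read a Bismark-coverage-style TSV into per-CpG records.

    Columns: chrom, 1-based start, end, percent methylation, methylated
    count, unmethylated count.  Positions are converted to 0-based; the
    output frame has columns (chrom, pos, meth, total, sample).  Records
    for opposite-strand CpG pairs are merged by position when a seventh
    strand column is present (minus-strand positions shifted back by 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", header=None)
    frame = frame.iloc[:, :7]
    names = ["chrom", "start", "end", "percent", "meth", "unmeth", "strand"][: frame.shape[1]]
    frame.columns = names
    if "strand" not in frame.columns:
        frame["strand"] = np.nan
    has_strand = frame["strand"].notna().any()
    pos = frame["start"].astype(int) - 1
    if has_strand:
        pos = pos.where(frame["strand"] != "-", pos - 1)
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "pos": pos,
            "meth": frame["meth"].astype(int),
            "total": (frame["meth"] + frame["unmeth"]).astype(int),
        }
    )
    if has_strand:
        out = out.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]].sum()
    out["sample"] = sample or path.stem
    return out


def write_bismark_cov(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-CpG records (chrom, pos, meth, total) as Bismark coverage."""
    pct = np.where(records["total"] > 0, 100.0 * records["meth"] / records["total"], 0.0)
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"] + 1,
            "end": records["pos"] + 1,
            "percent": np.round(pct, 6),
            "meth": records["meth"],
            "unmeth": records["total"] - records["meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def aggregate_cpgs(
    records: pd.DataFrame,
    tiling: GenomeTiling,
    samples: list[str] | None = None,
    min_coverage: int = 10,
) -> MethTileTable:
    """Sum per-CpG counts into tiles and apply the coverage rule.

    ``records`` holds rows (chrom, pos, meth, total, sample) for every
    sample of the analysis.  A tile is retained iff EVERY sample totals at
    least ``min_coverage`` reads in it; the retained-tile universe is the
    denominator of all overlap statistics downstream.
    """
    if samples is None:
        samples = sorted(records["sample"].unique())
    bad = ~records["sample"].isin(samples)
    if bad.any():
        raise ValueError(f"records contain samples outside {samples}")
    # vectorised tile assignment; validates positions against the layout
    chrom_to_idx = {c: i for i, c in enumerate(tiling.layout.names)}
    try:
        cidx = records["chrom"].map(chrom_to_idx).to_numpy(dtype=float)
    except Exception as exc:  # pragma: no cover
        raise ValueError("unmappable chromosome in records") from exc
    if np.isnan(cidx).any():
        first = records.loc[np.isnan(cidx), ["chrom", "pos"]].iloc[0]
        raise ValueError(f"CpG at {first.chrom}:{first.pos} outside the layout")
    cidx = cidx.astype(int)
    pos = records["pos"].to_numpy()
    lengths = np.asarray(tiling.layout.lengths)
    if np.any(pos < 0) or np.any(pos >= lengths[cidx]):
        i = int(np.argmax((pos < 0) | (pos >= lengths[cidx])))
        raise ValueError(
            f"CpG at {records['chrom'].iloc[i]}:{pos[i]} outside the chromosome"
        )
    offsets = np.asarray(tiling._offsets)
    tile = offsets[cidx] + pos // tiling.width
    work = pd.DataFrame(
        {
            "tile_id": tile,
            "sample": records["sample"].to_numpy(),
            "meth": records["meth"].to_numpy(),
            "total": records["total"].to_numpy(),
        }
    )
    grouped = work.groupby(["tile_id", "sample"], sort=True)[["meth", "total"]].sum()
    meth = grouped["meth"].unstack("sample").reindex(columns=samples)
    total = grouped["total"].unstack("sample").reindex(columns=samples)
    meth = meth.fillna(0).astype(np.int64)
    total = total.fillna(0).astype(np.int64)
    keep = (total.to_numpy() >= min_coverage).all(axis=1)
    tile_ids = meth.index.to_numpy()[keep]
    table = MethTileTable(tiling, tile_ids, list(samples), meth.to_numpy()[keep], total.to_numpy()[keep])
    logger.info("aggregate_cpgs: %d/%d tiles pass coverage >= %d in all %d samples",
                tile_ids.size, keep.size, min_coverage, len(samples))
    return table


def global_methylation(table: MethTileTable, samples: list[str] | None = None) -> float:
    """Pooled percent methylation over all retained tiles and samples."""
    idx = table.sample_index(samples) if samples else np.arange(len(table.samples))
    total = table.total[:, idx].sum()
    if total == 0:
        raise ValueError("zero total coverage")
    return 100.0 * table.meth[:, idx].sum() / total


def _group_counts(table: MethTileTable, labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    idx = table.sample_index(labels)
    return table.meth[:, idx], table.total[:, idx]


def diff_methylation(
    table: MethTileTable,
    group_a: list[str],
    group_b: list[str],
    overdispersion: str = "shrink",
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-tile differential methylation between two sample groups.

    Likelihood-ratio (G) test of the group term in a binomial regression,
    1 df.  ``overdispersion`` selects the quasi-binomial correction:

    - ``"none"``: plain binomial LRT (anti-conservative when replicates
      vary beyond binomial sampling);
    - ``"scale"``: G divided by one global scale factor (median per-tile
      Pearson X²/df across all tiles, floored at 1);
    - ``"shrink"`` (default): G divided by a per-tile scale factor
      moderated toward the global one (prior weight ``d0`` = 4
      pseudo-degrees of freedom), so tiles whose replicates disagree are
      penalised individually while well-behaved tiles keep full power —
      the empirical-Bayes practice for few-replicate count data.

    delta is the pooled percent difference (A − B); ``is_dmr`` flags
    q < ``q_cut``.  Tiles where either group totals zero are skipped with a
    logged warning (cannot arise after the coverage rule).
    """
    if overdispersion not in ("none", "scale", "shrink"):
        raise ValueError("overdispersion must be 'none', 'scale' or 'shrink'")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    meth_a, tot_a = _group_counts(table, group_a)
    meth_b, tot_b = _group_counts(table, group_b)
    ma, ta = meth_a.sum(axis=1).astype(float), tot_a.sum(axis=1).astype(float)
    mb, tb = meth_b.sum(axis=1).astype(float), tot_b.sum(axis=1).astype(float)
    ok = (ta > 0) & (tb > 0)
    if not ok.all():
        logger.warning("diff_methylation: skipping %d tiles with zero group total", (~ok).sum())

    def xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        from scipy.special import xlogy as _x

        return _x(x, y)

    # G statistic of group vs intercept-only binomial fit (pooled 2x2)
    m, t = ma + mb, ta + tb
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_full = (
            xlogy(ma, ma / ta) + xlogy(ta - ma, 1 - ma / ta)
            + xlogy(mb, mb / tb) + xlogy(tb - mb, 1 - mb / tb)
        )
        ll_null = xlogy(m, m / t) + xlogy(t - m, 1 - m / t)
    g = np.where(ok, 2.0 * (ll_full - ll_null), np.nan)
    g = np.maximum(g, 0.0)

    if overdispersion == "scale":
        phi = _pearson_scale(table, group_a, group_b)
        g = g / phi
    elif overdispersion == "shrink":
        phi_t, phi = _moderated_scales(table, group_a, group_b)
        g = g / phi_t
    else:
        phi = 1.0
    p = np.where(ok, chi2.sf(g, df=1), np.nan)
    # identical proportions give G=0 -> p=1 exactly
    q = np.full_like(p, np.nan)
    q[ok] = stats.benjamini_hochberg(p[ok])
    delta = np.where(ok, 100.0 * (ma / np.maximum(ta, 1) - mb / np.maximum(tb, 1)), np.nan)
    frame = table.tiling.to_frame(table.tile_ids)
    frame["delta"] = delta
    frame["p"] = p
    frame["q"] = q
    frame["direction"] = np.where(delta >= 0, "hyper", "hypo")
    frame["is_dmr"] = q < q_cut
    frame.attrs["overdispersion"] = overdispersion
    frame.attrs["scale_factor"] = float(phi)
    frame.attrs["qvalue_method"] = "benjamini-hochberg"
    return frame[ok].reset_index(drop=True)


def _pearson_x2(table: MethTileTable, group_a: list[str], group_b: list[str]) -> np.ndarray:
    """Per-tile Pearson X² of per-sample counts around the pooled group fits."""
    x2 = np.zeros(table.tile_ids.size)
    for labels in (group_a, group_b):
        meth, tot = _group_counts(table, labels)
        p_hat = meth.sum(axis=1, keepdims=True) / np.maximum(tot.sum(axis=1, keepdims=True), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (meth - tot * p_hat) ** 2 / (tot * p_hat * (1 - p_hat))
        x2 += np.nan_to_num(contrib).sum(axis=1)
    return x2


def _moderated_scales(
    table: MethTileTable, group_a: list[str], group_b: list[str], d0: float = 4.0
) -> tuple[np.ndarray, float]:
    """Per-tile quasi-binomial scales shrunk toward the global median.

    phi_t = max(1, (d0*phi0 + df*X²_t/df) / (d0 + df)) with df = S − 2
    residual degrees of freedom and phi0 the global median (floored at 1).
    With fewer than 3 samples there is no residual information and the
    global (unit) scale is returned for every tile.
    """
    n_samples = len(group_a) + len(group_b)
    df = n_samples - 2
    if df < 1:
        return np.ones(table.tile_ids.size), 1.0
    x2 = _pearson_x2(table, group_a, group_b)
    phi0 = max(float(np.median(x2 / df)), 1.0)
    phi_t = np.maximum((d0 * phi0 + x2) / (d0 + df), 1.0)
    return phi_t, phi0


def _pearson_scale(table: MethTileTable, group_a: list[str], group_b: list[str]) -> float:
    """Global quasi-binomial scale: median per-tile Pearson X²/df, floored at 1.

    Residuals are taken per sample around the pooled group proportion; the
    median across tiles is robust to the minority of truly differential
    tiles.  Requires > 2 samples overall; otherwise returns 1.
    """
    n_samples = len(group_a) + len(group_b)
    df = n_samples - 2
    if df < 1:
        return 1.0
    x2 = _pearson_x2(table, group_a, group_b)
    return max(float(np.median(x2 / df)), 1.0)


def dmr_set(result: pd.DataFrame, q_cut: float = 0.05) -> pd.DataFrame:
    """Significant tiles (q < q_cut) from a diff_methylation result."""
    return result[result["q"] < q_cut].reset_index(drop=True)


def mask_variant_tiles(dmrs: pd.DataFrame, variants: FeatureSet) -> pd.DataFrame:
    """Drop DMR tiles overlapping >= 1 strain-variant position.

    Variants are 1-bp intervals (e.g., C>T / G>A differences between mouse
    strains that confound bisulfite calls); overlap uses half-open
    semantics, so a variant at a tile's end coordinate does not mask it.
    """
    if dmrs.empty:
        return dmrs.copy()
    hit = overlaps_any_bulk(dmrs, variants)
    logger.info("mask_variant_tiles: removed %d/%d tiles", int(hit.sum()), len(dmrs))
    return dmrs[~hit].reset_index(drop=True)


def thin_clustered(
    dmrs: pd.DataFrame, max_gap: int = 1000, seed: int | np.random.Generator = 0,
    min_cluster_size: int = 2,
) -> pd.DataFrame:
    """Keep one representative per cluster of nearby significant tiles.

    Tiles are chained into clusters by single linkage on start-to-start
    distance < ``max_gap`` within a chromosome; from every cluster of at
    least ``min_cluster_size`` tiles exactly one member is retained,
    chosen uniformly at random with the given seed, so a single genomic
    region is not weighted repeatedly in feature analyses.  Singletons are
    always retained.  Deterministic for a fixed seed.
    """
    if dmrs.empty:
        return dmrs.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = dmrs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    new_cluster = np.ones(len(frame), dtype=bool)
    same_chrom = frame["chrom"].to_numpy()[1:] == frame["chrom"].to_numpy()[:-1]
    close = np.diff(frame["start"].to_numpy()) < max_gap
    new_cluster[1:] = ~(same_chrom & close)
    cluster = np.cumsum(new_cluster)
    keep = np.zeros(len(frame), dtype=bool)
    for _, idx in pd.Series(np.arange(len(frame))).groupby(cluster):
        members = idx.to_numpy()
        if members.size < min_cluster_size:
            keep[members] = True
        else:
            keep[rng.choice(members)] = True
    return frame[keep].reset_index(drop=True)


def methylation_by_category(
    deltas: pd.DataFrame,
    calls: np.ndarray,
    chip_tiling: GenomeTiling,
) -> tuple[pd.DataFrame, dict[str, stats.TestResult]]:
    """Methylation change distribution by ChIP changed-tile category.

    ``deltas`` carries per 100-bp tile (chrom, start, end, delta); each is
    mapped by containment into the 2-kb ChIP tile grid (the fine width
    divides the coarse width, so no tile spans a boundary).  Returns a
    per-category summary (n, median, IQR of delta) and Mann–Whitney tests
    of gain-vs-unchanged and loss-vs-unchanged.
    """
    chrom_to_idx = {c: i for i, c in enumerate(chip_tiling.layout.names)}
    cidx = deltas["chrom"].map(chrom_to_idx).to_numpy()
    offsets = np.asarray(chip_tiling._offsets)
    chip_tile = offsets[cidx] + deltas["start"].to_numpy() // chip_tiling.width
    category = np.asarray(calls, dtype=object)[chip_tile]
    rows = []
    groups: dict[str, np.ndarray] = {}
    for cat in ("gain", "loss", "unchanged", "excluded"):
        vals = deltas["delta"].to_numpy()[category == cat]
        groups[cat] = vals
        q1, med, q3 = (np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3)
        rows.append({"category": cat, "n": int(vals.size), "median_delta": med, "iqr": q3 - q1})
    tests: dict[str, stats.TestResult] = {}
    for cat in ("gain", "loss"):
        if groups[cat].size and groups["unchanged"].size:
            tests[f"{cat}_vs_unchanged"] = stats.mann_whitney_u(groups[cat], groups["unchanged"])
    return pd.DataFrame(rows), tests


def write_dmr_tsv(dmrs: pd.DataFrame, path: str | Path) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(
            f"# epipersist v{__version__} DMRs; q-values: Benjamini-Hochberg; "
            f"overdispersion: {dmrs.attrs.get('overdispersion', '?')}\n"
        )
        dmrs.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_dmr_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
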
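"""Association of DMR tile sets with genomic features.

Three complementary views: distance-to-nearest-feature distributions of a
query set against a background set (Mann–Whitney), the fraction of each
set overlapping features (Fisher), and windowed proximity enrichment
(a tile is 'near' when its nearest-feature distance is within a window;
window 0 reduces exactly to the overlap test).  The background defaults to
the full covered-tile universe of the methylation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .intervals import NO_NEIGHBOR, FeatureSet, nearest_distances


@dataclass
class DistanceComparison:
    feature: str
    query_distances: np.ndarray
    background_distances: np.ndarray
    query_median: float
    background_median: float
    p: float
    n_no_neighbor: int


@dataclass
class ProximityEnrichment:
    feature: str
    window: int
    query_near: int
    query_total: int
    background_near: int
    background_total: int
    odds_ratio: float
    p: float

    @property
    def query_fraction(self) -> float:
        return self.query_near / self.query_total if self.query_total else float("nan")

    @property
    def background_fraction(self) -> float:
        return self.background_near / self.background_total if self.background_total else float("nan")


def distance_comparison(
    query: pd.DataFrame, background: pd.DataFrame, features: FeatureSet
) -> DistanceComparison:
    """Nearest-feature distances of query vs background tiles.

    Tiles on chromosomes without any feature carry the no-neighbor
    sentinel; they are excluded from the Mann–Whitney test and their count
    reported.  Medians are of the finite distances.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    dq = nearest_distances(query, features)
    db = nearest_distances(background, features)
    n_missing = int((dq == NO_NEIGHBOR).sum() + (db == NO_NEIGHBOR).sum())
    dq_f = dq[dq != NO_NEIGHBOR]
    db_f = db[db != NO_NEIGHBOR]
    test = stats.mann_whitney_u(dq_f, db_f)
    return DistanceComparison(
        feature=features.label,
        query_distances=dq,
        background_distances=db,
        query_median=float(np.median(dq_f)) if dq_f.size else float("nan"),
        background_median=float(np.median(db_f)) if db_f.size else float("nan"),
        p=test.p,
        n_no_neighbor=n_missing,
    )


def proximity_enrichment(
    query: pd.DataFrame,
    background: pd.DataFrame,
    features: FeatureSet,
    window: int = 1000,
) -> ProximityEnrichment:
    """Fisher enrichment of query tiles lying within ``window`` bp of a feature.

    A tile is 'near' iff its nearest-feature distance is <= window
    (distance 0 on overlap), so window=0 is exactly the overlap-fraction
    test.  The 2x2 table crosses set membership with nearness.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    dq = nearest_distances(query, features)
    db = nearest_distances(background, features)
    q_near = int(((dq != NO_NEIGHBOR) & (dq <= window)).sum())
    b_near = int(((db != NO_NEIGHBOR) & (db <= window)).sum())
    table = [[q_near, len(query) - q_near], [b_near, len(background) - b_near]]
    res = stats.fisher_exact(table)
    return ProximityEnrichment(
        feature=features.label,
        window=window,
        query_near=q_near,
        query_total=len(query),
        background_near=b_near,
        background_total=len(background),
        odds_ratio=res.odds_ratio if res.odds_ratio is not None else float("nan"),
        p=res.p,
    )


def overlap_fraction_test(
    query: pd.DataFrame, background: pd.DataFrame, features: FeatureSet
) -> ProximityEnrichment:
    """Fraction of each set overlapping >= 1 feature, with Fisher test."""
    return proximity_enrichment(query, background, features, window=0)


def top_changed_regions(comparison, fraction: float = 0.25) -> FeatureSet:
    """The top fraction of tiles ranked by |log2FC|, as a FeatureSet.

    Models 'the regions with greatest change' in the histone mark;
    sign-agnostic ranking, ties broken by tile id (deterministic).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = comparison.log2fc.size
    n_top = int(np.ceil(fraction * n))
    order = np.lexsort((np.arange(n), -np.abs(comparison.log2fc)))
    top = np.sort(order[:n_top])
    frame = comparison.tiling.to_frame(top)
    return FeatureSet("top-changed", frame[["chrom", "start", "end"]])


def enrichment_table(results: list[ProximityEnrichment]) -> pd.DataFrame:
    rows = [
        {
            "feature": r.feature,
            "window": r.window,
            "query_near": r.query_near,
            "query_total": r.query_total,
            "background_near": r.background_near,
            "background_total": r.background_total,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
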
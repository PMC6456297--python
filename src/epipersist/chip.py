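"""H3K27me3 tile-signal analysis on 2-kb genomic tiles.

Signal per tile is computed from ChIP and input read counts by
reads-per-million (RPM) scaling, input subtraction with clamping at zero,
and re-scaling by the inverse of the ChIP RPM factor so signal stays on the
count scale of the ChIP library (this avoids damping between-region
variation).  Changed tiles are those exceeding a log2 fold-change cutoff at
a q-value cutoff in BOTH biological replicates, excluding tiles that also
differ within genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .intervals import GenomeTiling

GAIN, LOSS, UNCHANGED, EXCLUDED = "gain", "loss", "unchanged", "excluded"


@dataclass
class TileCountTrack:
    """Raw read counts per tile for one library (ChIP or input).

    ``library_size`` is the total mapped reads of the library; it need not
    equal the sum of tile counts (reads may fall outside retained tiles).
    """

    tiling: GenomeTiling
    counts: np.ndarray
    library_size: int
    label: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.tiling.n_tiles,):
            raise ValueError("one count per tile required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.library_size < 1:
            raise ValueError("library size must be >= 1")


@dataclass
class TileSignalTrack:
    """Normalised, input-subtracted signal per tile (count scale, >= 0)."""

    tiling: GenomeTiling
    signal: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class TileComparison:
    """Per-tile case-vs-control comparison: log2FC, p, BH q, mean signal."""

    tiling: GenomeTiling
    log2fc: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mean_signal: np.ndarray


def tile_signal(chip: TileCountTrack, input_track: TileCountTrack) -> TileSignalTrack:
    """Input-subtracted ChIP signal per tile.

    s_t = max(0, chip_t·1e6/L_chip − input_t·1e6/L_input) · (L_chip/1e6):
    both libraries are scaled to reads per million, input is subtracted with
    negative values set to zero, and the result is re-scaled by the inverse
    of the ChIP RPM factor.  With an all-zero input track the scaling and
    inverse re-scaling cancel and the signal equals the raw chip counts.
    """
    if chip.tiling is not input_track.tiling and chip.tiling != input_track.tiling:
        raise ValueError("chip and input tracks use different tilings")
    lc, li = chip.library_size, input_track.library_size
    # algebraically (chip/lc - input/li)*1e6 * (lc/1e6); folded so the RPM
    # scale and its inverse cancel exactly when the input is zero
    signal = np.maximum(chip.counts - input_track.counts * (lc / li), 0.0).astype(float)
    return TileSignalTrack(
        chip.tiling,
        signal,
        provenance={
            "chip": chip.label,
            "input": input_track.label,
            "library_size_chip": lc,
            "library_size_input": li,
        },
    )


def count_ratio_test(case_count: int, control_count: int, size_factor: float = 1.0) -> float:
    """Exact two-sided conditional binomial test for two count libraries.

    Conditional on the total n = case + control, the case count is
    Binomial(n, pi0) under the null of equal per-library rates, where
    pi0 = f/(1+f) and f = ``size_factor`` = L_case/L_control.  Both counts
    zero gives p = 1 by convention.
    """
    n = case_count + control_count
    if n == 0:
        return 1.0
    pi0 = size_factor / (1.0 + size_factor)
    return float(sps.binomtest(int(case_count), int(n), pi0, alternative="two-sided").pvalue)


def _count_ratio_pvalues(case: np.ndarray, control: np.ndarray, size_factor: float) -> np.ndarray:
    p = np.ones(case.size)
    for i in range(case.size):
        p[i] = count_ratio_test(int(case[i]), int(control[i]), size_factor)
    return p


def tile_log2fc(
    case: TileSignalTrack,
    control: TileSignalTrack,
    pseudocount: float = 1.0,
    case_counts: TileCountTrack | None = None,
    control_counts: TileCountTrack | None = None,
) -> TileComparison:
    """Per-tile log2 fold change of case over control signal.

    log2FC_t = log2((case_t + c)/(control_t + c)).  The per-tile p-value
    is the conditional binomial :func:`count_ratio_test`, preferably on
    the raw ChIP count tracks (the binomial model is exact for counts;
    input-subtracted signal carries extra input noise) with the
    library-size ratio as size factor; when counts are not supplied the
    rounded signals are used.  q-values are Benjamini–Hochberg across all
    tiles.
    """
    if case.tiling != control.tiling:
        raise ValueError("case and control tracks use different tilings")
    c = float(pseudocount)
    if c < 0:
        raise ValueError("pseudocount must be >= 0")
    if c == 0 and (np.any(case.signal == 0) or np.any(control.signal == 0)):
        raise ValueError("zero signal with pseudocount 0; use a positive pseudocount")
    log2fc = np.log2((case.signal + c) / (control.signal + c))
    if case_counts is not None and control_counts is not None:
        size_factor = case_counts.library_size / control_counts.library_size
        p = _count_ratio_pvalues(case_counts.counts, control_counts.counts, size_factor)
    else:
        lc = case.provenance.get("library_size_chip", 1)
        lt = control.provenance.get("library_size_chip", 1)
        p = _count_ratio_pvalues(np.rint(case.signal), np.rint(control.signal), lc / lt)
    q = stats.benjamini_hochberg(p)
    mean_signal = (case.signal + control.signal) / 2.0
    return TileComparison(case.tiling, log2fc, p, q, mean_signal)


def call_changed_tiles(
    rep1: TileComparison,
    rep2: TileComparison,
    ctrl_vs_ctrl: TileComparison | None = None,
    cko_vs_cko: TileComparison | None = None,
    fc_cut: float = 0.5,
    q_cut: float = 0.1,
) -> np.ndarray:
    """Replicate-consistent changed-tile calls.

    gain: log2FC > fc_cut and q < q_cut in both replicates; loss symmetric
    with < −fc_cut; a tile called by the same rule in either within-genotype
    comparison (control vs control, case vs case) is 'excluded'; everything
    else is 'unchanged'.  Returns a string array per tile.
    """
    comps = [rep1, rep2] + [c for c in (ctrl_vs_ctrl, cko_vs_cko) if c is not None]
    for c in comps[1:]:
        if c.tiling != rep1.tiling:
            raise ValueError("all comparisons must share one tiling")
    gain = (
        (rep1.log2fc > fc_cut) & (rep1.q < q_cut) & (rep2.log2fc > fc_cut) & (rep2.q < q_cut)
    )
    loss = (
        (rep1.log2fc < -fc_cut) & (rep1.q < q_cut) & (rep2.log2fc < -fc_cut) & (rep2.q < q_cut)
    )
    excluded = np.zeros(rep1.log2fc.size, dtype=bool)
    for within in (ctrl_vs_ctrl, cko_vs_cko):
        if within is not None:
            excluded |= (np.abs(within.log2fc) > fc_cut) & (within.q < q_cut)
    calls = np.full(rep1.log2fc.size, UNCHANGED, dtype=object)
    calls[gain] = GAIN
    calls[loss] = LOSS
    calls[excluded] = EXCLUDED
    return calls


def top_tile_metagene(
    signal: TileSignalTrack,
    comparison: TileComparison,
    top_fraction: float = 0.05,
    flank: int = 5,
) -> pd.DataFrame:
    """Metagene around the highest-signal tiles.

    Anchors are the top ceil(fraction·T) tiles ranked by the given signal
    track (the control condition), ties broken by tile id.  For each offset
    in −flank..+flank the mean and standard error of log2FC and the median
    signal over anchors are reported; offsets that cross a chromosome
    boundary are dropped for that anchor (tiles never wrap around).
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top fraction must lie in (0, 1)")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    tiling = signal.tiling
    n = tiling.n_tiles
    n_top = int(np.ceil(top_fraction * n))
    # stable selection: sort by (-signal, tile_id)
    order = np.lexsort((np.arange(n), -signal.signal))
    anchors = np.sort(order[:n_top])
    anchor_chrom = tiling.chrom_of(anchors)
    rows = []
    for offset in range(-flank, flank + 1):
        pos = anchors + offset
        valid = (pos >= 0) & (pos < n)
        valid[valid] &= tiling.chrom_of(pos[valid]) == anchor_chrom[valid]
        fc = comparison.log2fc[pos[valid]]
        sig = signal.signal[pos[valid]]
        se = float(fc.std(ddof=1) / np.sqrt(fc.size)) if fc.size > 1 else np.nan
        rows.append(
            {
                "offset": offset,
                "n": int(fc.size),
                "mean_log2fc": float(fc.mean()) if fc.size else np.nan,
                "se_log2fc": se,
                "median_signal": float(np.median(sig)) if sig.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def genomewide_shift(
    tracks: list[TileSignalTrack], condition: list[str]
) -> tuple[pd.DataFrame, stats.TestResult]:
    """Per-track median/IQR of tile signal plus a pooled between-condition test.

    ``condition`` assigns each track to one of exactly two conditions; the
    Mann–Whitney U test compares all tile signals pooled across tracks of
    one condition against the other.
    """
    if len(tracks) != len(condition) or not tracks:
        raise ValueError("one condition label per track required")
    for t in tracks:
        if t.signal.size == 0:
            raise ValueError("empty signal track")
    rows = []
    for t, cond in zip(tracks, condition):
        q1, med, q3 = np.percentile(t.signal, [25, 50, 75])
        rows.append(
            {
                "track": t.provenance.get("chip", "?"),
                "condition": cond,
                "median": float(med),
                "iqr": float(q3 - q1),
            }
        )
    levels = list(dict.fromkeys(condition))
    if len(levels) != 2:
        raise ValueError("exactly two conditions required")
    pooled = {
        lev: np.concatenate([t.signal for t, c in zip(tracks, condition) if c == lev])
        for lev in levels
    }
    test = stats.mann_whitney_u(pooled[levels[0]], pooled[levels[1]])
    return pd.DataFrame(rows), test


# ---------------------------------------------------------------------------
# I/O: bedGraph counts + library-size sidecar, comparison TSV, calls BED


def write_count_bedgraph(track: TileCountTrack, path: str | Path) -> None:
    from . import __version__

    frame = track.tiling.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# epipersist v{__version__} tile counts: {track.label}\n")
        for (_, chrom, start, end), cnt in zip(frame.itertuples(index=False), track.counts):
            fh.write(f"{chrom}\t{start}\t{end}\t{cnt}\n")


def read_count_bedgraph(path: str | Path, tiling: GenomeTiling, library_size: int, label: str) -> TileCountTrack:
    counts = np.zeros(tiling.n_tiles, dtype=np.int64)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        counts[tiling.tile_id(chrom, int(start))] = int(float(value))
    return TileCountTrack(tiling, counts, library_size, label)


def write_comparison_tsv(comp: TileComparison, path: str | Path) -> None:
    from . import __version__

    frame = comp.tiling.to_frame()
    frame["log2fc"] = comp.log2fc
    frame["p"] = comp.p
    frame["q"] = comp.q
    frame["mean_signal"] = comp.mean_signal
    with open(path, "w") as fh:
        fh.write(f"# epipersist v{__version__} tile comparison\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_calls_bed(calls: np.ndarray, tiling: GenomeTiling, path: str | Path) -> None:
    """Changed-tile calls as BED4 (category in the name field)."""
    from . import __version__

    frame = tiling.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# epipersist v{__version__} changed-tile calls\n")
        for (_, chrom, start, end), cat in zip(frame.itertuples(index=False), calls):
            fh.write(f"{chrom}\t{start}\t{end}\t{cat}\n")
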
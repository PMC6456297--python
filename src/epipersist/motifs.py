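"""PWM scanning of tile sequences and motif enrichment of DMR sets.

A tile contains a motif hit when the best log-odds window score on either
strand reaches a fraction (default 0.8) of the motif's maximum achievable
score; the log-odds background is uniform by default, configurable to the
0-order composition of the scanned set.  Enrichment of hits in a query
tile set against the covered-tile control set is a two-sided Fisher test
per motif with Bonferroni correction over the number of motifs tested —
mirroring how binding-site enrichment in persistent DMRs is assessed
against all covered tiles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from . import stats

_BASES = "ACGT"
_BASE_INDEX = np.full(256, 4, dtype=np.int8)  # unknown/N -> 4
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T."""

    name: str
    matrix: np.ndarray  # (length, 4), columns A C G T

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: np.ndarray | None = None, floor: float = 1e-4) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        return np.log2(np.maximum(self.matrix, floor) / bg)

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


def _encode(seqs: Sequence[str], length: int) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _BASE_INDEX[arr].reshape(len(seqs), length)


def _best_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Best forward-strand window score per sequence; N windows score -inf."""
    n, slen = codes.shape
    L = lom.shape[0]
    if slen < L:
        return np.full(n, -np.inf)
    # pad log-odds with a -inf column for N (index 4)
    lom_pad = np.hstack([lom, np.full((L, 1), -1e9)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L, axis=1)  # (n, W, L)
    scores = lom_pad[np.arange(L)[None, None, :], windows].sum(axis=2)
    best = scores.max(axis=1)
    return np.where(best <= -1e8, -np.inf, best)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_fraction: float = 0.8,
    background: np.ndarray | None = None,
) -> bool:
    """Hit flag: does the sequence contain a window reaching the threshold?

    Scores every window on both strands as sum of log2(p_pos(base)/bg);
    hit iff the best score >= score_fraction x the PWM's maximum achievable
    score.  Sequences shorter than the motif never hit; windows containing
    N are discarded.
    """
    return bool(
        scan_many([sequence], pwm, score_fraction=score_fraction, background=background)[0]
    )


def scan_many(
    sequences: Sequence[str],
    pwm: PWM,
    score_fraction: float = 0.8,
    background: np.ndarray | None = None,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorised :func:`scan_pwm` over equal- or variable-length sequences."""
    if not 0 < score_fraction <= 1:
        raise ValueError("score fraction must lie in (0, 1]")
    lom = pwm.log_odds(background)
    threshold = score_fraction * pwm.max_score(background)
    out = np.zeros(len(sequences), dtype=bool)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_len.setdefault(len(s), []).append(i)
    for slen, idx in by_len.items():
        if slen < len(pwm):
            continue
        for lo in range(0, len(idx), chunk):
            part = idx[lo : lo + chunk]
            fwd = _encode([sequences[i] for i in part], slen)
            rev = _encode([reverse_complement(sequences[i]) for i in part], slen)
            best = np.maximum(_best_scores(fwd, lom), _best_scores(rev, lom))
            out[np.asarray(part)] = best >= threshold
    return out


def motif_enrichment(
    query: Sequence[str],
    control: Sequence[str],
    pwms: Iterable[PWM],
    score_fraction: float = 0.8,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of hits in query vs control tiles.

    Returns one row per motif (hit counts, percentages, odds ratio, raw
    and Bonferroni-adjusted p), sorted by adjusted p then name.
    """
    pwms = list(pwms)
    if not pwms:
        raise ValueError("empty PWM set")
    if not len(query) or not len(control):
        raise ValueError("query and control sets must be non-empty")
    rows = []
    for pwm in pwms:
        hq = int(scan_many(query, pwm, score_fraction, background).sum())
        hc = int(scan_many(control, pwm, score_fraction, background).sum())
        res = stats.fisher_exact([[hq, len(query) - hq], [hc, len(control) - hc]])
        rows.append(
            {
                "motif": pwm.name,
                "query_hits": hq,
                "query_total": len(query),
                "control_hits": hc,
                "control_total": len(control),
                "pct_query": 100.0 * hq / len(query),
                "pct_control": 100.0 * hc / len(control),
                "odds_ratio": res.odds_ratio,
                "p": res.p,
            }
        )
    frame = pd.DataFrame(rows)
    frame["adjusted_p"] = np.minimum(1.0, frame["p"] * len(pwms))
    return frame.sort_values(["adjusted_p", "p", "motif"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# MEME minimal format I/O (via Biopython) and FASTA helpers


def read_meme(path: str | Path) -> list[PWM]:
    """Read PWMs from a MEME minimal-format motif file."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        out = []
        for m in records:
            mat = np.column_stack([m.pwm[b] for b in _BASES])
            out.append(PWM(m.name, mat))
    return out


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal format."""
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for pwm in pwms:
        buf.write(f"MOTIF {pwm.name}\n")
        # large nsites keeps count-based re-normalisation by readers exact
        buf.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 1000000 E= 0\n")
        for row in pwm.matrix:
            buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def read_tile_fasta(path: str | Path) -> dict[int, str]:
    """Read tile sequences from FASTA; record ids are integer tile ids."""
    from Bio import SeqIO

    return {int(rec.id): str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tile_fasta(seqs: dict[int, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(seqs):
            fh.write(f">{tid}\n{seqs[tid]}\n")
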
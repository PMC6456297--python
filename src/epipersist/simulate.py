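"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the biology under study on a desk-scale genome
(default: two 2-Mb chromosomes): a repressive-mark (H3K27me3) landscape
whose highest-signal tiles are depleted in the mutant while the rest of
the genome gains signal ("flattening"), bisulfite count tables in which a
planted set of 100-bp tiles is shifted toward hypermethylation in the
mutant germ line — a fraction of which carry the same shift in offspring
somatic samples ("persistence") — genomic feature tracks with enhancers
planted near persistent tiles, strain-variant positions, and tile
sequences with one transcription-factor motif embedded preferentially in
persistent-truth tiles.

Every generator is a pure function of the configuration (seed included):
repeated runs are bit-identical.  Planted truth is returned alongside the
data and written next to every simulated dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import FeatureSet, GenomeLayout, GenomeTiling, make_tiling
from .chip import TileCountTrack
from .motifs import PWM

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class ChipSimConfig:
    """Histone-mark (ChIP) landscape parameters.

    Intensities are per 2-kb tile.  The control landscape is log-normal
    with a planted fraction of high-signal tiles (multiplied intensity);
    the mutant multiplies high tiles by ``depletion`` (< 1 flattens) and
    adds ``background_gain_frac`` x median intensity everywhere else.
    """

    tile_width: int = 2000
    log_sigma: float = 0.6
    high_fraction: float = 0.05
    high_multiplier: float = 8.0
    domain_length: int = 1  # tiles per high-signal domain
    depletion: float = 0.6  # d in (0, 1]
    background_gain_frac: float = 0.3  # g as a fraction of median intensity
    replicates: int = 2
    library_depth: int = 1_000_000
    chip_in_tile_fraction: float = 0.45
    input_in_tile_fraction: float = 0.2
    flank_radius: int = 3  # tiles flagged as "flank" truth around domains


@dataclass
class RrbsSimConfig:
    """Bisulfite (RRBS) cohort parameters for two tissues x two groups."""

    tile_width: int = 100
    cpg_per_bp: float = 0.05  # Bernoulli placement => ~5 CpGs per covered tile
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0  # negative-binomial size
    baseline_alpha: float = 6.5  # Beta(6.5, 3.5): mean methylation 0.65
    baseline_beta: float = 3.5
    overdispersion: float = 0.02  # beta-binomial rho between samples
    n_dmr: int = 150
    hyper_fraction: float = 14 / 15  # hyper:hypo planted ratio 14:1
    delta: float = 30.0  # percentage points added in the mutant
    soma_concordance: float = 0.8  # rho: fraction of sperm DMRs shifted in soma
    soma_specific_dmrs: int = 100
    samples_per_group: int = 3
    dmr_in_changed_fraction: float = 0.5  # planted DMRs inside changed ChIP tiles
    min_dmr_separation: int = 2000  # bp between planted DMR tiles
    min_coverage: int = 10


@dataclass
class FeatureSimConfig:
    """Feature-track parameters; enhancers are planted near persistent tiles."""

    n_tss: int = 300
    n_cpg_islands: int = 200
    cpg_island_length: int = 500
    n_enhancers: int = 200
    enhancer_length: int = 400
    enhancer_near_fraction: float = 0.8
    enhancer_max_distance: int = 500
    n_repeats: int = 500
    repeat_length: int = 300
    n_gene_bodies: int = 150
    gene_body_length: int = 10_000
    n_variants: int = 200
    variants_in_dmr_fraction: float = 0.0


@dataclass
class MotifSimConfig:
    """Tile-sequence parameters; one planted motif plus never-planted decoys."""

    gc: float = 0.42
    planted_query_fraction: float = 0.4
    planted_control_fraction: float = 0.02
    mutation_rate: float = 0.05
    n_decoys: int = 4
    motif_length: int = 8
    consensus_prob: float = 0.88
    score_fraction: float = 0.8


@dataclass
class SimConfig:
    seed: int = 0
    chromosome_lengths: dict = field(default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    chip: ChipSimConfig = field(default_factory=ChipSimConfig)
    rrbs: RrbsSimConfig = field(default_factory=RrbsSimConfig)
    features: FeatureSimConfig = field(default_factory=FeatureSimConfig)
    motifs: MotifSimConfig = field(default_factory=MotifSimConfig)

    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_dict(self.chromosome_lengths)

    # -- validation -------------------------------------------------------
    def validate(self) -> list[str]:
        """Range-check every field; returns ALL violations, empty when valid."""
        errors: list[str] = []

        def check(cond: bool, msg: str) -> None:
            if not cond:
                errors.append(msg)

        check(isinstance(self.seed, int) and self.seed >= 0, "seed: non-negative integer required")
        check(bool(self.chromosome_lengths), "chromosome_lengths: at least one chromosome")
        for name, length in self.chromosome_lengths.items():
            check(int(length) >= 1, f"chromosome_lengths[{name}]: length >= 1 required")
        c = self.chip
        check(c.tile_width >= 1, "chip.tile_width: >= 1 required")
        check(0 < c.depletion <= 1, "chip.depletion: in (0, 1] required")
        check(c.background_gain_frac >= 0, "chip.background_gain_frac: >= 0 required")
        check(0 < c.high_fraction < 1, "chip.high_fraction: in (0, 1) required")
        check(c.high_multiplier >= 1, "chip.high_multiplier: >= 1 required")
        check(c.replicates >= 1, "chip.replicates: >= 1 required")
        check(c.library_depth >= 1, "chip.library_depth: >= 1 required")
        check(0 < c.chip_in_tile_fraction <= 1, "chip.chip_in_tile_fraction: in (0, 1] required")
        check(0 < c.input_in_tile_fraction <= 1, "chip.input_in_tile_fraction: in (0, 1] required")
        r = self.rrbs
        check(r.tile_width >= 1, "rrbs.tile_width: >= 1 required")
        check(self.chip.tile_width % r.tile_width == 0,
              "rrbs.tile_width: must divide chip.tile_width")
        check(0 < r.cpg_per_bp < 1, "rrbs.cpg_per_bp: in (0, 1) required")
        check(r.coverage_mean > 0, "rrbs.coverage_mean: > 0 required")
        check(r.coverage_dispersion > 0, "rrbs.coverage_dispersion: > 0 required")
        check(0 <= r.overdispersion < 1, "rrbs.overdispersion: in [0, 1) required")
        check(r.n_dmr >= 0, "rrbs.n_dmr: >= 0 required")
        check(0 <= r.hyper_fraction <= 1, "rrbs.hyper_fraction: in [0, 1] required")
        check(-100 <= r.delta <= 100, "rrbs.delta: percentage points in [-100, 100]")
        check(0 <= r.soma_concordance <= 1, "rrbs.soma_concordance: in [0, 1] required")
        check(r.samples_per_group >= 1, "rrbs.samples_per_group: >= 1 required")
        check(0 <= r.dmr_in_changed_fraction <= 1, "rrbs.dmr_in_changed_fraction: in [0, 1]")
        f = self.features
        for fname in ("n_tss", "n_cpg_islands", "n_enhancers", "n_repeats", "n_gene_bodies", "n_variants"):
            check(getattr(f, fname) >= 0, f"features.{fname}: >= 0 required")
        check(0 <= f.enhancer_near_fraction <= 1, "features.enhancer_near_fraction: in [0, 1]")
        check(0 <= f.variants_in_dmr_fraction <= 1, "features.variants_in_dmr_fraction: in [0, 1]")
        m = self.motifs
        check(0 < m.gc < 1, "motifs.gc: in (0, 1) required")
        check(0 <= m.planted_query_fraction <= 1, "motifs.planted_query_fraction: in [0, 1]")
        check(0 <= m.planted_control_fraction <= 1, "motifs.planted_control_fraction: in [0, 1]")
        check(0 <= m.mutation_rate < 1, "motifs.mutation_rate: in [0, 1) required")
        check(m.motif_length >= 4, "motifs.motif_length: >= 4 required")
        check(0 < m.score_fraction <= 1, "motifs.score_fraction: in (0, 1] required")
        return errors

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sections = {"chip": ChipSimConfig, "rrbs": RrbsSimConfig,
                    "features": FeatureSimConfig, "motifs": MotifSimConfig}
        for key, klass in sections.items():
            if key in data and isinstance(data[key], dict):
                sub_known = {f.name for f in dataclasses.fields(klass)}
                sub_unknown = set(data[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown config keys in {key}: {sorted(sub_unknown)}")
                data[key] = klass(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Planted truth


@dataclass
class SimTruth:
    """Planted ground truth, written alongside every simulated dataset."""

    depleted_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    flank_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    gained_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    sperm_dmr_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    sperm_dmr_sign: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    soma_concordant_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    soma_specific_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    enhancer_adjacent_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    motif_query_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    motif_control_tiles: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    planted_motif: str = ""

    @property
    def persistent_truth(self) -> np.ndarray:
        """Planted concordant-hyper tiles: shifted in both tissues, positive."""
        hyper = self.sperm_dmr_tiles[self.sperm_dmr_sign > 0]
        return np.intersect1d(hyper, self.soma_concordant_tiles)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("depleted_tiles", "flank_tiles", "gained_tiles", "soma_concordant_tiles",
                     "soma_specific_tiles", "enhancer_adjacent_tiles",
                     "motif_query_tiles", "motif_control_tiles"):
            np.savetxt(outdir / f"{name}.tsv", getattr(self, name), fmt="%d")
        pd.DataFrame({"tile_id": self.sperm_dmr_tiles, "sign": self.sperm_dmr_sign}).to_csv(
            outdir / "sperm_dmr_tiles.tsv", sep="\t", index=False
        )
        (outdir / "planted_motif.txt").write_text(self.planted_motif + "\n")


def _rng_for(config: SimConfig, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the config seed."""
    stage_key = {"chip": 1, "rrbs": 2, "features": 3, "sequences": 4, "thinning": 5}[stage]
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage_key]))


# ---------------------------------------------------------------------------
# ChIP landscape


def simulate_chip(config: SimConfig, truth: SimTruth | None = None):
    """Replicate ChIP/input count tracks with a planted flattening.

    Control tile intensity is log-normal; a ``high_fraction`` of tiles
    (in domains of ``domain_length`` consecutive tiles) is multiplied by
    ``high_multiplier``.  The mutant multiplies high-domain tiles by the
    depletion factor d and adds g = background_gain_frac x median
    intensity everywhere else.  Counts are Poisson per replicate; the
    input track has flat intensity.  Returns ({label: TileCountTrack},
    tiling, truth).
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = config.chip
    rng = _rng_for(config, "chip")
    tiling = make_tiling(config.layout(), cfg.tile_width)
    n = tiling.n_tiles
    truth = truth if truth is not None else SimTruth()

    base = rng.lognormal(mean=0.0, sigma=cfg.log_sigma, size=n)
    n_high = max(1, int(round(cfg.high_fraction * n / cfg.domain_length)))
    starts = rng.choice(n - cfg.domain_length + 1, size=n_high, replace=False)
    members = (starts[:, None] + np.arange(cfg.domain_length)[None, :]).ravel()
    anchor = np.repeat(starts, cfg.domain_length)
    # domains never straddle a chromosome boundary
    members = members[tiling.chrom_of(members) == tiling.chrom_of(anchor)]
    high = np.unique(members)
    lam = base.copy()
    lam[high] *= cfg.high_multiplier
    scale = cfg.chip_in_tile_fraction * cfg.library_depth / lam.sum()
    lam_ctrl = lam * scale
    g = cfg.background_gain_frac * np.median(lam_ctrl)
    lam_cko = lam_ctrl + g
    lam_cko[high] = lam_ctrl[high] * cfg.depletion
    lam_input = np.full(n, cfg.input_in_tile_fraction * cfg.library_depth / n)

    tracks: dict[str, TileCountTrack] = {}
    for cond, intensity in (("ctrl", lam_ctrl), ("cko", lam_cko)):
        for rep in range(1, cfg.replicates + 1):
            tracks[f"chip_{cond}_rep{rep}"] = TileCountTrack(
                tiling, rng.poisson(intensity), cfg.library_depth, f"chip_{cond}_rep{rep}"
            )
            tracks[f"input_{cond}_rep{rep}"] = TileCountTrack(
                tiling, rng.poisson(lam_input), cfg.library_depth, f"input_{cond}_rep{rep}"
            )

    offs = np.arange(-cfg.flank_radius, cfg.flank_radius + 1)
    cand = (high[:, None] + offs[None, :]).ravel()
    origin = np.repeat(high, offs.size)
    ok = (cand >= 0) & (cand < n)
    cand, origin = cand[ok], origin[ok]
    same_chrom = tiling.chrom_of(cand) == tiling.chrom_of(origin)
    flank = np.setdiff1d(np.unique(cand[same_chrom]), high)
    truth.depleted_tiles = high
    truth.flank_tiles = flank
    truth.gained_tiles = np.setdiff1d(np.arange(n), high) if g > 0 else np.array([], dtype=int)
    return tracks, tiling, truth


# ---------------------------------------------------------------------------
# RRBS cohorts


def _place_cpgs(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """CpG positions as (chrom_index, pos) arrays, Bernoulli per bp."""
    layout = config.layout()
    chrom_idx, positions = [], []
    for i, length in enumerate(layout.lengths):
        n_sites = rng.binomial(length, config.rrbs.cpg_per_bp)
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        chrom_idx.append(np.full(n_sites, i))
        positions.append(pos)
    return np.concatenate(chrom_idx), np.concatenate(positions)


def _pick_spaced(candidates: np.ndarray, n: int, min_gap_tiles: int, rng: np.random.Generator) -> np.ndarray:
    """Sample up to n tile ids from candidates with pairwise gap >= min_gap_tiles."""
    chosen: list[int] = []
    pool = rng.permutation(candidates)
    taken = np.zeros(0, dtype=int)
    for t in pool:
        if len(chosen) >= n:
            break
        if taken.size == 0 or np.abs(taken - t).min() >= min_gap_tiles:
            chosen.append(int(t))
            taken = np.asarray(chosen)
    return np.sort(np.asarray(chosen, dtype=int))


def simulate_rrbs(config: SimConfig, truth: SimTruth | None = None):
    """Per-sample CpG count tables for two tissues x two groups.

    Tile baseline methylation pi_t ~ Beta(a, b); planted DMR tiles are
    shifted by ±delta percentage points (clipped to [0.02, 0.98]) in
    mutant samples — preferentially placed inside ChIP-changed truth tiles
    when that truth exists — and a Bernoulli(soma_concordance) subset of
    them carries the same shift in mutant soma samples, alongside
    soma-specific planted DMRs.  Per sample and tile the working
    proportion is Beta-distributed around pi (overdispersion rho); per CpG
    the total is negative-binomial and the methylated count binomial.

    Returns ({tissue: records DataFrame}, group labels dict, tiling, truth).
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = config.rrbs
    rng = _rng_for(config, "rrbs")
    tiling = make_tiling(config.layout(), cfg.tile_width)
    truth = truth if truth is not None else SimTruth()

    cidx, pos = _place_cpgs(config, rng)
    offsets = np.asarray(tiling._offsets)
    cpg_tile = offsets[cidx] + pos // cfg.tile_width
    tiles_with_cpg = np.unique(cpg_tile)

    # --- plant DMR tiles ------------------------------------------------
    changed_2kb = np.union1d(truth.depleted_tiles, truth.flank_tiles)
    ratio = config.chip.tile_width // cfg.tile_width
    if changed_2kb.size:
        fine_in_changed = (changed_2kb[:, None] * ratio + np.arange(ratio)[None, :]).ravel()
        in_changed = np.intersect1d(tiles_with_cpg, fine_in_changed)
    else:
        in_changed = np.array([], dtype=int)
    gap_tiles = max(1, cfg.min_dmr_separation // cfg.tile_width)
    n_in = int(round(cfg.n_dmr * cfg.dmr_in_changed_fraction)) if in_changed.size else 0
    planted_in = _pick_spaced(in_changed, n_in, gap_tiles, rng)
    remaining = np.setdiff1d(tiles_with_cpg, planted_in)
    planted_out = _pick_spaced(remaining, cfg.n_dmr - planted_in.size, gap_tiles, rng)
    planted = np.sort(np.concatenate([planted_in, planted_out]))
    # enforce spacing across the two pools
    planted = _pick_spaced(planted, planted.size, gap_tiles, rng)
    sign = np.where(rng.random(planted.size) < cfg.hyper_fraction, 1, -1)
    concordant = planted[(rng.random(planted.size) < cfg.soma_concordance)]
    soma_specific = _pick_spaced(
        np.setdiff1d(tiles_with_cpg, planted), cfg.soma_specific_dmrs, gap_tiles, rng
    )
    truth.sperm_dmr_tiles = planted
    truth.sperm_dmr_sign = sign
    truth.soma_concordant_tiles = concordant
    truth.soma_specific_tiles = soma_specific

    # --- tile-level methylation baselines -------------------------------
    tile_index = {t: i for i, t in enumerate(tiles_with_cpg)}
    pi_base = rng.beta(cfg.baseline_alpha, cfg.baseline_beta, size=tiles_with_cpg.size)
    shift = np.zeros(tiles_with_cpg.size)
    sperm_shift = shift.copy()
    pl_idx = np.asarray([tile_index[t] for t in planted], dtype=int)
    if pl_idx.size:
        sperm_shift[pl_idx] = sign * cfg.delta / 100.0
    soma_shift = shift.copy()
    conc_idx = np.asarray([tile_index[t] for t in concordant]) if concordant.size else np.array([], dtype=int)
    conc_sign = sign[np.isin(planted, concordant)]
    if conc_idx.size:
        soma_shift[conc_idx] = conc_sign * cfg.delta / 100.0
    spec_idx = np.asarray([tile_index[t] for t in soma_specific]) if soma_specific.size else np.array([], dtype=int)
    if spec_idx.size:
        soma_shift[spec_idx] = cfg.delta / 100.0

    layout = config.layout()
    chrom_names = np.asarray(layout.names, dtype=object)
    cpg_tile_idx = np.asarray([tile_index[t] for t in cpg_tile])

    def _tissue(shift_vec: np.ndarray, tissue: str) -> tuple[pd.DataFrame, dict]:
        frames = []
        groups = {"ctrl": [], "cko": []}
        for cond in ("ctrl", "cko"):
            pi_tile = np.clip(pi_base + (shift_vec if cond == "cko" else 0.0), 0.02, 0.98)
            for s in range(1, cfg.samples_per_group + 1):
                sample = f"{tissue}_{cond}_{s}"
                groups[cond].append(sample)
                if cfg.overdispersion > 0:
                    rho = cfg.overdispersion
                    a = pi_tile * (1 - rho) / rho
                    b = (1 - pi_tile) * (1 - rho) / rho
                    pi_sample = rng.beta(a, b)
                else:
                    pi_sample = pi_tile
                p_nb = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
                total = rng.negative_binomial(cfg.coverage_dispersion, p_nb, size=pos.size)
                meth = rng.binomial(total, pi_sample[cpg_tile_idx])
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom_names[cidx],
                            "pos": pos,
                            "meth": meth,
                            "total": total,
                            "sample": sample,
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True), groups

    sperm, sperm_groups = _tissue(sperm_shift, "sperm")
    soma, soma_groups = _tissue(soma_shift, "soma")
    records = {"sperm": sperm, "soma": soma}
    groups = {"sperm": sperm_groups, "soma": soma_groups}
    return records, groups, tiling, truth


# ---------------------------------------------------------------------------
# Feature tracks


def _uniform_intervals(
    layout: GenomeLayout, n: int, length: int, rng: np.random.Generator
) -> pd.DataFrame:
    lengths = np.asarray(layout.lengths)
    probs = lengths / lengths.sum()
    cidx = rng.choice(len(lengths), size=n, p=probs)
    starts = (rng.random(n) * (lengths[cidx] - length)).astype(int)
    return pd.DataFrame(
        {
            "chrom": np.asarray(layout.names, dtype=object)[cidx],
            "start": starts,
            "end": starts + length,
        }
    )


def simulate_features(config: SimConfig, truth: SimTruth, tiling_fine: GenomeTiling):
    """Feature BED tracks: TSS, CpG islands, enhancers, repeats, genes, variants.

    All tracks are uniform over the genome except enhancers, of which
    ``enhancer_near_fraction`` are placed within ``enhancer_max_distance``
    bp of randomly chosen persistent-truth tiles, and optionally a
    fraction of variants placed inside planted DMR tiles to exercise
    masking.  Returns {label: FeatureSet}.
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = config.features
    rng = _rng_for(config, "features")
    layout = config.layout()
    out: dict[str, FeatureSet] = {}
    out["tss"] = FeatureSet("tss", _uniform_intervals(layout, cfg.n_tss, 1, rng))
    out["cpg_islands"] = FeatureSet(
        "cpg_islands", _uniform_intervals(layout, cfg.n_cpg_islands, cfg.cpg_island_length, rng)
    )
    out["repeats"] = FeatureSet(
        "repeats", _uniform_intervals(layout, cfg.n_repeats, cfg.repeat_length, rng)
    )
    out["gene_bodies"] = FeatureSet(
        "gene_bodies", _uniform_intervals(layout, cfg.n_gene_bodies, cfg.gene_body_length, rng)
    )

    persistent = truth.persistent_truth
    n_near = int(round(cfg.enhancer_near_fraction * cfg.n_enhancers)) if persistent.size else 0
    near_rows = []
    adjacent = []
    if n_near:
        anchors = rng.choice(persistent, size=n_near, replace=True)
        for t in anchors:
            iv = tiling_fine.tile_interval(int(t))
            offset = int(rng.integers(-cfg.enhancer_max_distance, cfg.enhancer_max_distance + 1))
            start = max(0, iv.start + offset)
            end = min(layout.length(iv.chrom), start + cfg.enhancer_length)
            near_rows.append((iv.chrom, start, end))
            adjacent.append(int(t))
    uniform = _uniform_intervals(layout, cfg.n_enhancers - n_near, cfg.enhancer_length, rng)
    enh = pd.concat(
        [pd.DataFrame(near_rows, columns=["chrom", "start", "end"]), uniform], ignore_index=True
    )
    out["enhancers"] = FeatureSet("enhancers", enh)
    truth.enhancer_adjacent_tiles = np.unique(np.asarray(adjacent, dtype=int))

    n_target = int(round(cfg.variants_in_dmr_fraction * cfg.n_variants))
    var_rows = []
    if n_target and truth.sperm_dmr_tiles.size:
        targets = rng.choice(truth.sperm_dmr_tiles, size=n_target, replace=False)
        for t in targets:
            iv = tiling_fine.tile_interval(int(t))
            p = int(rng.integers(iv.start, iv.end))
            var_rows.append((iv.chrom, p, p + 1))
    uniform_v = _uniform_intervals(layout, cfg.n_variants - n_target, 1, rng)
    var = pd.concat(
        [pd.DataFrame(var_rows, columns=["chrom", "start", "end"]), uniform_v], ignore_index=True
    )
    out["variants"] = FeatureSet("variants", var)
    return out


# ---------------------------------------------------------------------------
# Tile sequences and motifs


def _make_pwm(name: str, consensus: str, consensus_prob: float) -> PWM:
    mat = np.full((len(consensus), 4), (1 - consensus_prob) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = consensus_prob
    return PWM(name, mat)


def default_pwms(config: SimConfig, rng: np.random.Generator) -> tuple[PWM, list[PWM]]:
    """One planted PWM plus decoys, consensus drawn from the seeded rng."""
    cfg = config.motifs
    consensi = []
    while len(consensi) < cfg.n_decoys + 1:
        cons = "".join(rng.choice(list("ACGT"), size=cfg.motif_length))
        if cons not in consensi:
            consensi.append(cons)
    planted = _make_pwm("planted_TF", consensi[0], cfg.consensus_prob)
    decoys = [
        _make_pwm(f"decoy_{i}", cons, cfg.consensus_prob)
        for i, cons in enumerate(consensi[1:], 1)
    ]
    return planted, decoys


def simulate_sequences(config: SimConfig, tile_ids: np.ndarray, truth: SimTruth, tiling_fine: GenomeTiling):
    """Random tile sequences with the planted motif embedded.

    i.i.d. background at the configured GC; the planted PWM's consensus
    (each base mutated with the configured rate) is embedded at a random
    offset in ``planted_query_fraction`` of persistent-truth tiles and
    ``planted_control_fraction`` of the remaining tiles; decoys are never
    embedded.  Returns ({tile_id: sequence}, [planted] + decoys, truth).
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = config.motifs
    rng = _rng_for(config, "sequences")
    planted_pwm, decoys = default_pwms(config, rng)
    consensus = planted_pwm.consensus
    probs = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    tile_ids = np.asarray(sorted(tile_ids), dtype=int)
    widths = np.asarray(
        [len(tiling_fine.tile_interval(int(t))) for t in tile_ids]
    )
    persistent = set(truth.persistent_truth.tolist())
    seqs: dict[int, str] = {}
    query_planted, control_planted = [], []
    for t, width in zip(tile_ids, widths):
        letters = rng.choice(4, size=width, p=probs)
        is_query = int(t) in persistent
        frac = cfg.planted_query_fraction if is_query else cfg.planted_control_fraction
        if width >= len(consensus) and rng.random() < frac:
            motif = np.asarray(["ACGT".index(b) for b in consensus])
            mutate = rng.random(motif.size) < cfg.mutation_rate
            motif[mutate] = rng.integers(0, 4, size=int(mutate.sum()))
            off = int(rng.integers(0, width - motif.size + 1))
            letters[off : off + motif.size] = motif
            (query_planted if is_query else control_planted).append(int(t))
        seqs[int(t)] = "".join(_BASES[letters])
    truth.motif_query_tiles = np.asarray(query_planted, dtype=int)
    truth.motif_control_tiles = np.asarray(control_planted, dtype=int)
    truth.planted_motif = consensus
    return seqs, [planted_pwm] + decoys, truth
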
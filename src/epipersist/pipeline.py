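"""End-to-end orchestration: simulate → chip → dmr → persist → features → motifs.

Each stage writes its outputs under the run directory and registers them
in a manifest (config snapshot, version, seeds, SHA-256 digests of every
written file, and method-deviation warnings).  No timestamps are written,
so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chip, features, methyl, motifs, persistence
from .intervals import write_bed
from .simulate import SimConfig, SimTruth, simulate_chip, simulate_features, simulate_rrbs, simulate_sequences

logger = logging.getLogger(__name__)

WARNINGS = [
    "q-values are Benjamini-Hochberg throughout (not SLIM)",
    "coverage rule: >= 10 reads per tile in EVERY sample",
    "thinning: one representative per cluster of >= 2 significant tiles (< 1 kb apart)",
]


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int = 0
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=lambda: list(WARNINGS))

    def register(self, stage: str, paths: list[Path]) -> None:
        digests = {}
        for p in sorted(paths):
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages[stage] = digests

    def write(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class RunResult:
    """In-memory handles to every stage's products (besides files on disk)."""

    config: SimConfig
    truth: SimTruth
    manifest: RunManifest
    calls: np.ndarray
    metagene: pd.DataFrame
    shift_summary: pd.DataFrame
    sperm_result: pd.DataFrame  # per-tile test results, all universe tiles
    soma_result: pd.DataFrame
    sperm_dmrs: pd.DataFrame  # q<0.05, variant-masked (persistence input)
    soma_dmrs: pd.DataFrame
    sperm_dmrs_thinned: pd.DataFrame  # one tile per clustered region
    soma_dmrs_thinned: pd.DataFrame
    sperm_universe: np.ndarray
    soma_universe: np.ndarray
    universe: np.ndarray
    report: persistence.PersistenceReport
    global_methylation: dict
    feature_results: pd.DataFrame
    motif_results: pd.DataFrame
    mean_comparison: chip.TileComparison
    category_summary: pd.DataFrame


def validate_config(path: str | Path) -> list[str]:
    """Type- and range-check a config file; returns every violation."""
    try:
        config = SimConfig.from_yaml(path)
    except (ValueError, TypeError) as exc:
        return [str(exc)]
    return config.validate()


def run_all(config: SimConfig | str | Path, outdir: str | Path, write_inputs: bool = True) -> RunResult:
    """Run every stage in dependency order; any failure names its stage.

    ``outdir`` receives per-stage outputs (bedGraph/TSV/BED/FASTA) and
    ``manifest.json``.  With ``write_inputs`` the simulated raw inputs are
    written too, so each stage can be re-run from files.
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)

    # ---- stage: simulate ------------------------------------------------
    stage = "simulate"
    try:
        truth = SimTruth()
        tracks, tiling2k, truth = simulate_chip(config, truth)
        records, groups, tiling100, truth = simulate_rrbs(config, truth)
        feats = simulate_features(config, truth, tiling100)
        sim_paths = []
        sim_dir = outdir / "inputs"
        if write_inputs:
            sim_dir.mkdir(exist_ok=True)
            for label, track in tracks.items():
                p = sim_dir / f"{label}.bedgraph"
                chip.write_count_bedgraph(track, p)
                sim_paths.append(p)
            lib = sim_dir / "library_sizes.tsv"
            with open(lib, "w") as fh:
                fh.write("track\tlibrary_size\n")
                for label, track in tracks.items():
                    fh.write(f"{label}\t{track.library_size}\n")
            sim_paths.append(lib)
            for tissue, frame in records.items():
                for sample, sub in frame.groupby("sample", sort=True):
                    p = sim_dir / f"{sample}.cov"
                    methyl.write_bismark_cov(sub, p)
                    sim_paths.append(p)
            for label, fs in feats.items():
                p = sim_dir / f"{label}.bed"
                write_bed(fs, p)
                sim_paths.append(p)
            config.to_yaml(sim_dir / "config.yaml")
            sim_paths.append(sim_dir / "config.yaml")
        manifest.register(stage, sim_paths)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: chip ----------------------------------------------------
    stage = "chip"
    try:
        sig = {
            f"{cond}_rep{r}": chip.tile_signal(
                tracks[f"chip_{cond}_rep{r}"], tracks[f"input_{cond}_rep{r}"]
            )
            for cond in ("ctrl", "cko")
            for r in range(1, config.chip.replicates + 1)
        }
        def _cmp(a: str, b: str) -> chip.TileComparison:
            return chip.tile_log2fc(
                sig[a], sig[b],
                case_counts=tracks[f"chip_{a}"], control_counts=tracks[f"chip_{b}"],
            )

        rep1 = _cmp("cko_rep1", "ctrl_rep1")
        rep2 = _cmp("cko_rep2", "ctrl_rep2")
        within_ctrl = _cmp("ctrl_rep1", "ctrl_rep2")
        within_cko = _cmp("cko_rep1", "cko_rep2")
        calls = chip.call_changed_tiles(rep1, rep2, within_ctrl, within_cko)
        ctrl_mean = chip.TileSignalTrack(
            tiling2k,
            (sig["ctrl_rep1"].signal + sig["ctrl_rep2"].signal) / 2,
            {"chip": "ctrl_mean"},
        )
        mean_comp = chip.TileComparison(
            tiling2k,
            (rep1.log2fc + rep2.log2fc) / 2,
            np.minimum(rep1.p, rep2.p),
            np.minimum(rep1.q, rep2.q),
            (rep1.mean_signal + rep2.mean_signal) / 2,
        )
        metagene = chip.top_tile_metagene(ctrl_mean, mean_comp, top_fraction=0.05, flank=5)
        shift, shift_test = chip.genomewide_shift(
            [sig["ctrl_rep1"], sig["ctrl_rep2"], sig["cko_rep1"], sig["cko_rep2"]],
            ["ctrl", "ctrl", "cko", "cko"],
        )
        shift = shift.assign(mwu_p=shift_test.p)
        chip_dir = outdir / "chip"
        chip_dir.mkdir(exist_ok=True)
        chip.write_comparison_tsv(rep1, chip_dir / "comparison_rep1.tsv")
        chip.write_comparison_tsv(rep2, chip_dir / "comparison_rep2.tsv")
        chip.write_calls_bed(calls, tiling2k, chip_dir / "changed_tiles.bed")
        metagene.to_csv(chip_dir / "metagene.tsv", sep="\t", index=False, float_format="%.6g")
        shift.to_csv(chip_dir / "genomewide_shift.tsv", sep="\t", index=False, float_format="%.6g")
        manifest.register(stage, list(chip_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: dmr -----------------------------------------------------
    stage = "dmr"
    try:
        dmr_dir = outdir / "dmr"
        dmr_dir.mkdir(exist_ok=True)
        tables, results, dmr_sets, thinned_sets, universes, gm = {}, {}, {}, {}, {}, {}
        for tissue in ("sperm", "soma"):
            g = groups[tissue]
            table = methyl.aggregate_cpgs(
                records[tissue], tiling100, g["ctrl"] + g["cko"],
                min_coverage=config.rrbs.min_coverage,
            )
            tables[tissue] = table
            universes[tissue] = table.tile_ids
            gm[tissue] = {
                "ctrl": methyl.global_methylation(table, g["ctrl"]),
                "cko": methyl.global_methylation(table, g["cko"]),
            }
            result = methyl.diff_methylation(table, g["cko"], g["ctrl"])
            results[tissue] = result
            # persistence uses masked DMRs; thinning only affects the sets
            # used for feature characterization (one tile per clustered region)
            masked = methyl.mask_variant_tiles(methyl.dmr_set(result), feats["variants"])
            dmr_sets[tissue] = masked
            thin_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
            thinned_sets[tissue] = methyl.thin_clustered(masked, seed=thin_rng)
            methyl.write_dmr_tsv(result, dmr_dir / f"{tissue}_all_tiles.tsv")
            methyl.write_dmr_tsv(dmr_sets[tissue], dmr_dir / f"{tissue}_dmrs.tsv")
            methyl.write_dmr_tsv(thinned_sets[tissue], dmr_dir / f"{tissue}_dmrs_thinned.tsv")
        category_summary, _ = methyl.methylation_by_category(results["sperm"], calls, tiling2k)
        category_summary.to_csv(dmr_dir / "methylation_by_category.tsv", sep="\t", index=False, float_format="%.6g")
        manifest.register(stage, list(dmr_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: persist -------------------------------------------------
    stage = "persist"
    try:
        universe = np.intersect1d(universes["sperm"], universes["soma"])
        sperm_u = dmr_sets["sperm"][np.isin(dmr_sets["sperm"]["tile_id"], universe)]
        soma_u = dmr_sets["soma"][np.isin(dmr_sets["soma"]["tile_id"], universe)]
        shared = persistence.intersect_dmrs(sperm_u, soma_u)
        report = persistence.classify_persistence(
            shared, universe=universe.size, sperm_n=len(sperm_u), soma_n=len(soma_u)
        )
        persist_dir = outdir / "persist"
        persist_dir.mkdir(exist_ok=True)
        persistence.write_shared_tsv(shared, persist_dir / "shared_dmrs.tsv")
        persistence.write_report(report, persist_dir / "report.txt")
        pbed = report.persistent[["chrom", "start", "end"]].assign(name="persistent")
        from .intervals import FeatureSet

        write_bed(FeatureSet("persistent", pbed), persist_dir / "persistent.bed")
        manifest.register(stage, list(persist_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: features ------------------------------------------------
    stage = "features"
    try:
        feat_dir = outdir / "features"
        feat_dir.mkdir(exist_ok=True)
        thin_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
        persistent_thinned = methyl.thin_clustered(report.persistent, seed=thin_rng)
        query = persistent_thinned[["chrom", "start", "end"]].reset_index(drop=True)
        background = tiling100.to_frame(universe)[["chrom", "start", "end"]]
        rows = []
        if len(query) >= 1:
            top_changed = features.top_changed_regions(mean_comp, fraction=0.25)
            for fs in (feats["enhancers"], feats["cpg_islands"], feats["tss"], top_changed):
                dc = features.distance_comparison(query, background, fs)
                rows.append(
                    {
                        "feature": fs.label,
                        "kind": "distance",
                        "query_median": dc.query_median,
                        "background_median": dc.background_median,
                        "statistic": np.nan,
                        "p": dc.p,
                    }
                )
            for fs, window in ((feats["repeats"], 0), (feats["gene_bodies"], 1000)):
                pe = features.proximity_enrichment(query, background, fs, window=window)
                rows.append(
                    {
                        "feature": fs.label,
                        "kind": f"proximity_{window}bp",
                        "query_median": pe.query_fraction,
                        "background_median": pe.background_fraction,
                        "statistic": pe.odds_ratio,
                        "p": pe.p,
                    }
                )
        feature_results = pd.DataFrame(rows)
        feature_results.to_csv(feat_dir / "feature_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        manifest.register(stage, list(feat_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---- stage: motifs --------------------------------------------------
    stage = "motifs"
    try:
        motif_dir = outdir / "motifs"
        motif_dir.mkdir(exist_ok=True)
        seqs, pwms, truth = simulate_sequences(config, universe, truth, tiling100)
        motifs.write_meme(pwms, motif_dir / "motifs.meme")
        query_ids = [int(t) for t in persistent_thinned["tile_id"] if int(t) in seqs]
        query_seqs = [seqs[t] for t in query_ids]
        control_seqs = [seqs[int(t)] for t in universe if int(t) in seqs]
        if query_seqs:
            motif_results = motifs.motif_enrichment(
                query_seqs, control_seqs, pwms, score_fraction=config.motifs.score_fraction
            )
        else:
            motif_results = pd.DataFrame()
        motif_results.to_csv(motif_dir / "motif_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        motifs.write_tile_fasta(seqs, motif_dir / "tiles.fa")
        manifest.register(stage, list(motif_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    truth.write(outdir / "truth")
    manifest.register("truth", list((outdir / "truth").iterdir()))
    manifest.write(outdir / "manifest.json")
    return RunResult(
        config=config,
        truth=truth,
        manifest=manifest,
        calls=calls,
        metagene=metagene,
        shift_summary=shift,
        sperm_result=results["sperm"],
        soma_result=results["soma"],
        sperm_dmrs=dmr_sets["sperm"],
        soma_dmrs=dmr_sets["soma"],
        sperm_dmrs_thinned=thinned_sets["sperm"],
        soma_dmrs_thinned=thinned_sets["soma"],
        sperm_universe=universes["sperm"],
        soma_universe=universes["soma"],
        universe=universe,
        report=report,
        global_methylation=gm,
        feature_results=feature_results,
        motif_results=motif_results,
        mean_comparison=mean_comp,
        category_summary=category_summary,
    )
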
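"""End-to-end orchestration of the crossover-mapping pipeline.

A single :class:`PipelineConfig` drives simulation (or loading of real
inputs), pedigree QC, phasing, crossover detection, map construction,
sex-bias testing, hotspot calling and correlate modelling.  Every stage
writes its tables under the run directory and contributes to a summary
JSON; all randomness descends from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import codetect, correlates, genmap, hotspots, io as gio, pedigree as ped_mod
from . import phasing, sexbias, simcross
from .containers import GenomeLayout


class ConfigError(ValueError):
    """Raised when a configuration fails validation (CLI exit code 1)."""


@dataclass
class PipelineConfig:
    """All paths, thresholds and window sizes in one place.

    Defaults are desk scale: 2 chromosomes of 5 Mb with 2,000 markers
    each, 196 progeny (4 per full-sib family), 1% genotype error and 5%
    missingness, a 1.2x male multiplier on every other chromosome.
    """

    outdir: str = "gametemap_run"
    seed: int = 1
    # input paths (ignored when simulate=True)
    simulate: bool = True
    vcf: str | None = None
    pedigree: str | None = None
    fasta: str | None = None
    gff3: str | None = None
    repeat_bed: str | None = None
    # simulation
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_markers_per_chrom: int = 2000
    total_progeny: int = 196
    error_rate: float = 0.01
    missing_rate: float = 0.05
    co_per_gamete: float = 1.2
    male_multiplier: float = 1.2
    interference_mode: str = "gamma"
    obligate_co: bool = False
    hotspot_multiplier: float = 0.0      # > 0 injects one hotspot per chromosome
    hotspot_frac: float = 0.01
    landscape_segments: int = 10         # piecewise segments (0 = flat landscape)
    landscape_variation: float = 0.6
    simulate_features: bool = True
    # thresholds (each appears exactly once)
    min_parentage_score: float = 0.95
    min_family: int = 50
    epsilon: float = 0.01
    min_abs_ld: float = 0.3
    min_lod: float = 8.0
    twopoint_band: int = 30
    smoothing_window: int = 20
    min_block_bp: int = 500_000
    pseudo_marker_bp: int = 10_000
    sexbias_window_bp: int = 960_000
    hotspot_window_bp: int = 30_000
    fdr_threshold: float = 0.25
    fwer_alpha: float = 0.05
    feature_window_bp: int = 960_000

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            if self.vcf is None or self.pedigree is None:
                raise ConfigError("non-simulated input requires vcf and pedigree paths")
        if not (0 <= self.error_rate < 1 and 0 <= self.missing_rate < 1):
            raise ConfigError("error_rate/missing_rate must lie in [0, 1)")
        if self.min_block_bp <= 0 or self.hotspot_window_bp <= 0:
            raise ConfigError("window/block sizes must be positive")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _family_sizes(total: int) -> np.ndarray:
    return simcross.default_family_sizes(total=total)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the summary dict
    (also written to ``outdir/summary.json``)."""
    cfg.validate()
    out = gio.ensure_dir(cfg.outdir)
    log: list[str] = [f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]

    # --- stage: simulate or load -------------------------------------------
    truth = None
    feature_paths = None
    if cfg.simulate:
        layout = GenomeLayout.test_scale(cfg.n_chroms, cfg.chrom_length_bp)
        hotspot_list = []
        if cfg.hotspot_multiplier > 0:
            for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
                width = int(length * cfg.hotspot_frac)
                start = int(length * 0.45)
                hotspot_list.append(
                    simcross.Hotspot(chrom, start, start + width, cfg.hotspot_multiplier)
                )
        if hotspot_list or cfg.landscape_segments == 0 or cfg.landscape_variation == 0:
            landscape = simcross.RecombLandscape.uniform(
                layout,
                co_per_gamete=cfg.co_per_gamete,
                male_multiplier=cfg.male_multiplier,
                hotspots=hotspot_list or None,
                obligate_co=cfg.obligate_co,
                interference_mode=cfg.interference_mode,
            )
        else:
            landscape = simcross.RecombLandscape.piecewise(
                layout,
                co_per_gamete=cfg.co_per_gamete,
                n_segments=cfg.landscape_segments,
                variation=cfg.landscape_variation,
                seed=cfg.seed,
                male_multiplier=cfg.male_multiplier,
                obligate_co=cfg.obligate_co,
                interference_mode=cfg.interference_mode,
            )
        parents = simcross.simulate_parent_haplotypes(
            layout, cfg.n_markers_per_chrom, seed=cfg.seed
        )
        geno, ped, truth = simcross.simulate_factorial_cross(
            parents, landscape, _family_sizes(cfg.total_progeny),
            error_rate=cfg.error_rate, missing_rate=cfg.missing_rate,
            seed=cfg.seed, outdir=f"{out}/sim",
        )
        if cfg.simulate_features:
            tracks = simcross.simulate_feature_tracks(
                layout, landscape, seed=cfg.seed, outdir=f"{out}/sim"
            )
            feature_paths = tracks["paths"]
        log.append("stage simulate: ok")
    else:
        geno = gio.read_vcf(cfg.vcf)
        ped = gio.read_pedigree(cfg.pedigree)
        chrom_names = list(pd.unique(geno.markers["chrom"]))
        lengths = [int(geno.markers.loc[geno.markers["chrom"] == c, "pos"].max()) for c in chrom_names]
        layout = GenomeLayout(chrom_names, lengths)
        if cfg.fasta and cfg.gff3 and cfg.repeat_bed:
            feature_paths = {"fasta": cfg.fasta, "gff3": cfg.gff3, "bed": cfg.repeat_bed}
        log.append("stage load: ok")

    # --- stage: pedigree QC -------------------------------------------------
    qc = ped_mod.verify_pedigree(
        geno, ped, min_score=cfg.min_parentage_score, seed=cfg.seed
    )
    qc.to_csv(f"{out}/parentage.tsv", sep="\t", index=False)
    corrected: dict[str, np.ndarray] = {}
    n_corrections = 0
    for parent in ped.parents:
        dos, report = ped_mod.correct_parental_genotypes(
            geno, ped, parent, epsilon=cfg.epsilon, min_family=cfg.min_family
        )
        corrected[parent] = dos
        n_corrections += len(report)
    log.append(f"stage qc: {int(qc['matches_pedigree'].sum())}/{len(qc)} trios verified, "
               f"{n_corrections} parental corrections")

    # --- stage: phase + detect ---------------------------------------------
    co_parts, block_parts = [], []
    phase_acc_conf: list[float] = []
    haps_by_parent = {}
    tracks_by_parent = {}
    for parent in ped.parents:
        haps, contrib, conflicts = phasing.phase_parent(
            geno, ped, parent, corrected[parent],
            min_abs_ld=cfg.min_abs_ld, min_lod=cfg.min_lod, band=cfg.twopoint_band,
        )
        haps_by_parent[parent] = haps
        sex = ped.sex_of(parent)
        co, blocks, smoothed = codetect.detect_crossovers(
            contrib, haps, sex, window=cfg.smoothing_window, min_block_bp=cfg.min_block_bp
        )
        co_parts.append(co)
        block_parts.append(blocks)
        tracks_by_parent[parent] = {
            chrom: (contrib.markers["pos"].to_numpy()[sl], smoothed[chrom])
            for chrom, sl in contrib.chrom_slices.items()
        }
    co_df = pd.concat(co_parts, ignore_index=True)
    blocks_df = pd.concat(block_parts, ignore_index=True)
    codetect.co_regions_to_bed(co_df).to_csv(f"{out}/co_regions.tsv", sep="\t", index=False)
    blocks_df.to_csv(f"{out}/blocks.tsv", sep="\t", index=False)
    log.append(f"stage detect: {len(co_df)} CO regions")

    # --- stage: maps --------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parent_maps = {
            p: genmap.build_parent_map(tracks_by_parent[p], p) for p in ped.parents
        }
        consensus = genmap.build_consensus_map(blocks_df, layout, cfg.pseudo_marker_bp)
    consensus.to_frame().to_csv(f"{out}/consensus_map.tsv", sep="\t", index=False)
    map_summary = pd.DataFrame(
        [(p, m.length_cm, m.span_bp, m.kb_per_cm) for p, m in parent_maps.items()],
        columns=["parent", "length_cM", "span_bp", "kb_per_cM"],
    )
    map_summary.to_csv(f"{out}/parent_maps.tsv", sep="\t", index=False)
    log.append(f"stage map: consensus {consensus.length_cm:.1f} cM")

    # --- stage: sex bias ----------------------------------------------------
    per_lg, per_parent_lg = sexbias.per_lg_sex_counts(co_df, ped)
    chisq = sexbias.lg_chisq_test(per_lg)
    chisq.to_csv(f"{out}/lg_chisq.tsv", sep="\t", index=False)
    glmm = sexbias.fit_poisson_glmm(per_parent_lg)
    signals = sexbias.binned_sex_signals(co_df, layout, bin_bp=cfg.hotspot_window_bp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wavelet_table, selected_bins = sexbias.wavelet_scale_analysis(
            signals, bin_bp=cfg.hotspot_window_bp
        )
    wavelet_table.to_csv(f"{out}/wavelet_power.tsv", sep="\t", index=False)
    win = sexbias.window_co_counts(co_df, layout, ped, window_bp=cfg.sexbias_window_bp)
    win = sexbias.sex_bias_tests(win, fdr_threshold=cfg.fdr_threshold)
    win.to_csv(f"{out}/sexbias_windows.tsv", sep="\t", index=False)
    log.append(f"stage sexbias: {int(win['sex_biased'].sum())} biased windows")

    # --- stage: hotspots ----------------------------------------------------
    marker_pos = {
        c: geno.markers.loc[geno.markers["chrom"] == c, "pos"].to_numpy()
        for c in layout.chrom_names
    }
    hs = hotspots.hotspot_analysis(
        co_df, layout, ped, marker_pos, window_bp=cfg.hotspot_window_bp, alpha=cfg.fwer_alpha
    )
    hs["combined"].calls.to_csv(f"{out}/hotspots.tsv", sep="\t", index=False)

    # narrowly demarcated CO regions exported for motif tools
    if feature_paths is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records, n_narrow = codetect.extract_co_sequences(co_df, feature_paths["fasta"])
        gio.write_fasta(records, f"{out}/co_regions_narrow.fasta")
        log.append(f"stage detect: {n_narrow} CO regions demarcated to <= 10 kb exported")

    # --- stage: correlates --------------------------------------------------
    correlate_summary = {}
    if feature_paths is not None:
        feats = correlates.window_features(
            feature_paths["fasta"], feature_paths["gff3"], feature_paths["bed"],
            layout, window_bp=cfg.feature_window_bp,
        )
        fwin = sexbias.window_co_counts(co_df, layout, ped, window_bp=cfg.feature_window_bp)
        rows = []
        for p in ped.parents:
            d = feats.copy()
            d["count"] = fwin[p].to_numpy()
            d["sex_male"] = 1.0 if ped.sex_of(p) == "male" else 0.0
            d["retained"] = fwin["retained"].to_numpy()
            rows.append(d)
        model_data = pd.concat(rows, ignore_index=True)
        model_data = model_data[model_data["retained"]]
        fit1 = correlates.fit_co_models(model_data, "model1", seed=cfg.seed)
        fit2 = correlates.fit_co_models(model_data, "model2", seed=cfg.seed)
        feats.to_csv(f"{out}/window_features.tsv", sep="\t", index=False)
        correlate_summary = {
            "model1_cv_r2": round(fit1.cv_r2, 4),
            "model2_cv_r2": round(fit2.cv_r2, 4),
            "model1_gene_beta": round(float(fit1.coefficients.get("gene_count", np.nan)), 4),
            "model1_gc_beta": round(float(fit1.coefficients.get("gc", np.nan)), 4),
        }
        log.append("stage correlates: ok")

    # --- summary ------------------------------------------------------------
    total_f = int((co_df["sex"] == "female").sum())
    total_m = int((co_df["sex"] == "male").sum())
    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_offspring": len(ped.table),
        "n_co_total": len(co_df),
        "n_co_female": total_f,
        "n_co_male": total_m,
        "consensus_map_cm": round(consensus.length_cm, 2),
        "consensus_kb_per_cm": round(consensus.kb_per_cm, 2),
        "parent_map_cm_mean": round(float(map_summary["length_cM"].mean()), 2),
        "glmm_exp_sex": round(glmm.exp_sex, 4),
        "glmm_method": glmm.method,
        "wavelet_selected_bins": selected_bins,
        "n_sex_biased_windows": int(win["sex_biased"].sum()),
        "n_hotspot_windows": int(hs["combined"].calls["is_hotspot"].sum()),
        "n_hotspot_windows_female": int(hs["female"].calls["is_hotspot"].sum()),
        "n_hotspot_windows_male": int(hs["male"].calls["is_hotspot"].sum()),
        "hotspot_lambda": round(hs["combined"].lam, 4) if np.isfinite(hs["combined"].lam) else None,
        **correlate_summary,
    }
    if truth is not None:
        from .evaluation import co_precision_recall

        pr = co_precision_recall(co_df, truth)
        summary["co_precision"] = round(pr["precision"], 4)
        summary["co_recall"] = round(pr["recall"], 4)
        summary["n_co_true"] = truth.co_count()
    with open(f"{out}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(f"{out}/run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary
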
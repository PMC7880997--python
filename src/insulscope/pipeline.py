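"""End-to-end synthetic-scenario pipeline.

Runs the stage graph simulate -> normalize -> insulation/boundaries ->
differential classification -> compartments -> windowed ChIP -> association
on a configured two-genotype scenario and emits a machine-readable report
(boundary counts per class, peak dependency counts, compartment-switch
fraction, enrichment folds) plus text outputs (BED / bedGraph / TSV / JSON).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, compartments, insulation, io, occupancy, synthdata
from .genome import GenomeSpec
from .hic import filter_low_coverage, ice_normalize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Scenario + thresholds. Defaults follow the analysis conventions:

    2 kb resolution, insulation windows 20/40/80/160 kb, 2 kb merge gap,
    |delta| > 0.1 weak-boundary flag, ChIP FDR < 0.01 & |FC| > 2, DE gene
    thresholds padj < 0.05 & |FC| > 1.5.
    """

    # genome / simulation scenario
    chrom_length: int = 1_500_000
    resolution: int = 2000
    depth: float = 7.5e6
    n_boundaries: int = 40
    n_strict: int = 10
    n_partial: int = 5
    f_range: tuple[float, float] = (0.2, 0.4)
    gamma: float = 0.5
    compartment_strength: float = 0.2
    compartment_block: int = 200_000
    alpha: float = 1.0
    # insulation / boundary thresholds
    windows_bp: tuple[int, ...] = insulation.DEFAULT_WINDOWS_BP
    merge_gap: int = 2000
    weak_thresh: float = 0.1
    boundary_p_cut: float = 0.05
    # ChIP scenario / thresholds
    chip_n_windows: int = 20_000
    chip_background: float = 20.0
    chip_dispersion: float = 0.05
    chip_fdr: float = 0.01
    chip_min_fc: float = 2.0
    chip_min_fold_filter: float = 3.0
    # gene table / DE thresholds
    n_genes: int = 1000
    de_fraction: float = 0.05
    de_padj: float = 0.05
    de_min_fc: float = 1.5
    seed: int = 1
    outdir: str | None = None

    def genome(self) -> GenomeSpec:
        return GenomeSpec({"chrSim": self.chrom_length}, self.resolution)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on the configured synthetic scenario.

    Returns the run report; when ``config.outdir`` is set, stage outputs and
    the report are also written there. Deterministic for a fixed config.
    """
    cfg = config
    genome = cfg.genome()
    chrom = "chrSim"
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(8)]

    stage = "simulate"
    try:
        truth = synthdata.make_two_genotype_truth(
            genome, chrom, cfg.n_boundaries, cfg.n_strict, cfg.n_partial,
            f_range=cfg.f_range, compartment_block=cfg.compartment_block,
            c=cfg.compartment_strength, alpha=cfg.alpha, gamma=cfg.gamma,
            seed=seeds[0],
        )
        raw_wt = synthdata.simulate_contacts(truth.wt, cfg.depth, seeds[1], cfg.resolution)
        raw_mut = synthdata.simulate_contacts(truth.mut, cfg.depth, seeds[2], cfg.resolution)
        logger.info("stage=simulate bins=%d depth=%.0f", truth.wt.n_bins, cfg.depth)

        stage = "normalize"
        norm = {}
        for name, raw in (("wt", raw_wt), ("mut", raw_mut)):
            mask = filter_low_coverage(raw)
            norm[name], _ = ice_normalize(raw, mask)
        logger.info("stage=normalize valid_wt=%d valid_mut=%d",
                    norm["wt"].mask.sum(), norm["mut"].mask.sum())

        stage = "boundaries"
        sets, tracks = {}, {}
        for name in ("wt", "mut"):
            sets[name], tracks[name] = insulation.call_and_merge(
                norm[name], cfg.windows_bp, cfg.boundary_p_cut, merge_gap=cfg.merge_gap
            )
        avg_wt = insulation.average_score_track(tracks["wt"])
        avg_mut = insulation.average_score_track(tracks["mut"])
        delta = insulation.differential_insulation(avg_mut, avg_wt)
        classified = insulation.harmonize_genotypes(
            sets["wt"], sets["mut"], delta, cfg.merge_gap, cfg.weak_thresh, cfg.resolution
        )
        class_counts = classified["class"].value_counts().to_dict()
        logger.info("stage=boundaries classes=%s", class_counts)

        stage = "compartments"
        genes = synthdata.simulate_gene_table(
            genome, chrom, cfg.n_genes, cfg.de_fraction,
            near_boundary_bias=True,
            boundary_positions=(truth.affected_bins() + 0.5) * cfg.resolution
            if truth.affected else None,
            seed=seeds[3],
            compartment_sigma=truth.wt.sigma,
        )
        comp = {}
        for name in ("wt", "mut"):
            tssd = compartments.tss_density(genes, chrom, genome.n_bins(chrom), cfg.resolution)
            comp[name] = compartments.compartment_eigenvector(norm[name], tssd)
        assignments = compartments.assign_ab_and_switches(comp["wt"], comp["mut"], genes)
        de_mask = genes["de"]
        switch_frac_de = compartments.switch_fraction(assignments, de_mask)

        stage = "chip"
        chip = run_chip_scenario(cfg, seeds[4])

        stage = "associate"
        peak_pos = (np.sort(np.concatenate(
            [truth.affected_bins(), truth.shared_bins()[: max(1, cfg.n_boundaries // 3)]]
        )) + 0.5) * cfg.resolution
        called_pos = (classified["bin"].to_numpy() + 0.5) * cfg.resolution
        profile = association.distance_profile(peak_pos, called_pos, cfg.resolution, 20_000)
        rand = association.random_control(
            peak_pos.size, genome, chrom, norm["wt"].mask, seeds[5]
        )
        control = association.distance_profile(rand, called_pos, cfg.resolution, 20_000)
        fold = association.fold_enrichment_at_center(profile, control)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    report = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "seeds": seeds,
        "boundaries": {
            "n_wt": int(len(sets["wt"])),
            "n_mut": int(len(sets["mut"])),
            "classes": {k: int(v) for k, v in class_counts.items()},
            "n_weaker_in_mutant": int(classified["weaker_in_mutant"].sum()),
        },
        "compartments": {
            "switch_fraction_de_genes": switch_frac_de,
            "switch_fraction_all": compartments.switch_fraction(assignments),
        },
        "chip": chip["summary"],
        "association": {
            "central_percent": float(
                profile.percent[(profile.offsets == -cfg.resolution)
                                | (profile.offsets == 0)].mean()
            ),
            "fold_enrichment_center": fold,
        },
    }

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_bin_table(out / "bins.tsv", genome, chrom)
        io.write_sparse(out / "wt.raw.triplet.tsv", raw_wt)
        io.write_sparse(out / "mut.raw.triplet.tsv", raw_mut)
        bed = classified.assign(
            chrom=chrom,
            start=classified["bin"] * cfg.resolution,
            end=(classified["bin"] + 1) * cfg.resolution,
        )
        io.write_bed(out / "boundaries.bed", bed, ["score", "class", "delta"])
        io.write_bedgraph(out / "insulation.wt.bedgraph", chrom, avg_wt, cfg.resolution)
        io.write_bedgraph(out / "insulation.mut.bedgraph", chrom, avg_mut, cfg.resolution)
        io.write_bedgraph(out / "eigenvector.wt.bedgraph", chrom,
                          comp["wt"].eigenvector, cfg.resolution)
        io.write_gene_table(out / "genes.tsv", genes)
        chip["fragments"].to_csv(out / "peak_dependency.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def run_chip_scenario(cfg: RunConfig, seed: int) -> dict:
    """Three-condition ChIP scenario: WT, factor-null mutant, tag knockout.

    Peaks are planted on the window grid in three classes — strictly
    dependent (enriched in WT only), partially dependent (enriched in both,
    weaker in mutant) and independent (equal) — then recovered by the
    three-way differential comparisons and classified.
    """
    rng = np.random.default_rng(seed)
    grid = occupancy.WindowGrid.over_length(cfg.chip_n_windows * 10 + 20)
    n = grid.n_windows
    n_peaks = {"strict": 10, "partial": 10, "independent": 30}
    peak_width_windows = 5
    starts = rng.choice(
        np.arange(20, n - 20 - peak_width_windows, peak_width_windows * 4),
        size=sum(n_peaks.values()), replace=False,
    )
    labels = (["strict"] * n_peaks["strict"] + ["partial"] * n_peaks["partial"]
              + ["independent"] * n_peaks["independent"])
    fold_wt = np.ones(n)
    fold_mut = np.ones(n)
    truth_rows = []
    # fold choices make each class resolvable under the thresholds: a peak
    # must clear the 3-fold abundance filter (mean over the two compared
    # conditions), and "reduced" needs a >2-fold WT/mutant drop. WT peaks sit
    # at 16x background; partial peaks retain a 6x residual in the mutant
    # (16/6 > 2, (6+1)/2 > 3), mirroring loss from high-occupancy sites and
    # reduction at lower-occupancy ones.
    for s, lab in zip(starts, labels):
        sl = slice(s, s + peak_width_windows)
        fold_wt[sl] = 16.0
        fold_mut[sl] = {"strict": 1.0, "partial": 6.0, "independent": 16.0}[lab]
        truth_rows.append({"start": int(grid.starts()[s]), "label": lab})
    conditions = [
        synthdata.ChipCondition("wt", 2, cfg.chip_background),
        synthdata.ChipCondition("mut", 2, cfg.chip_background),
        synthdata.ChipCondition("ko", 2, cfg.chip_background),
    ]
    table = synthdata.simulate_chip_window_counts(
        np.array([], dtype=int), n, conditions, cfg.chip_dispersion,
        seed=int(rng.integers(2**31)),
        fold_profiles={"wt": fold_wt, "mut": fold_mut, "ko": np.ones(n)},
    )
    cond_of = {c: c.rsplit("_", 1)[0] for c in table.columns}
    peak_sets = {}
    n_retained = {}
    for key, contrast in (
        ("wt_vs_ko", ("ko", "wt")),
        ("mut_vs_ko", ("ko", "mut")),
        ("mut_vs_wt", ("wt", "mut")),
    ):
        # each comparison filters and normalizes on its own samples only
        cols = [c for c in table.columns if cond_of[c] in contrast]
        pair = table[cols]
        retained = occupancy.filter_windows(pair, cfg.chip_min_fold_filter)
        n_retained[key] = int(retained.sum())
        sub = pair[retained]
        sub_starts = grid.starts()[retained]
        # composition/depth normalization on the background-dominated full
        # grid: in one-sided comparisons every retained window is
        # differential, and TMM on those alone normalizes the signal away
        factors = occupancy.tmm_factors(pair)
        res = occupancy.test_windows(sub, cond_of, contrast, factors)
        peak_sets[key] = occupancy.combine_regions(
            res, sub_starts, grid.width, cfg.chip_fdr, cfg.chip_min_fc
        )
    reduced = peak_sets["mut_vs_wt"]
    reduced = reduced[reduced["occupancy"] < 0].reset_index(drop=True)
    frags = occupancy.classify_peak_dependency(
        peak_sets["wt_vs_ko"], peak_sets["mut_vs_ko"], reduced
    )
    dep_counts = frags["class"].value_counts().to_dict() if not frags.empty else {}
    return {
        "summary": {
            "n_retained_windows": n_retained,
            "n_peaks_wt_vs_ko": int(len(peak_sets["wt_vs_ko"])),
            "n_peaks_mut_vs_ko": int(len(peak_sets["mut_vs_ko"])),
            "n_reduced_mut_vs_wt": int(len(reduced)),
            "dependency_classes": {k: int(v) for k, v in dep_counts.items()},
        },
        "fragments": frags,
        "truth": pd.DataFrame(truth_rows),
        "peak_sets": peak_sets,
    }
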
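"""Parameter-recovery experiments on the synthetic generator.

Each function runs a self-contained simulation study against planted ground
truth and returns summary rates: boundary recovery precision/recall,
insulation-score monotonicity in boundary strength, differential boundary
classification, compartment eigenvector recovery, and the calibration of the
windowed ChIP test (type-I rate, region-level FDR, TMM factor recovery).
They are what the validation suite and the reproduction script run.
"""

from __future__ import annotations

import numpy as np

from . import compartments, insulation, occupancy, synthdata
from .genome import GenomeSpec
from .hic import filter_low_coverage, ice_normalize

MATCH_TOL_BINS = 1


def _default_genome(n_bins: int = 500, resolution: int = 2000) -> GenomeSpec:
    return GenomeSpec({"chrSim": n_bins * resolution}, resolution)


def _matched(a: np.ndarray, b: np.ndarray, tol: int) -> int:
    """Count members of ``a`` with a member of ``b`` within ``tol`` bins."""
    return int(sum(np.abs(np.asarray(b) - x).min() <= tol if len(b) else False for x in a))


def boundary_recovery(
    n_seeds: int = 20,
    n_bins: int = 500,
    depth: float = 5e6,
    n_boundaries: int = 10,
    f_range: tuple[float, float] = (0.2, 0.4),
    min_spacing: int = 15,
    seed: int = 0,
    tol_bins: int = MATCH_TOL_BINS,
) -> dict:
    """Precision/recall of the full multi-window boundary caller.

    Simulates ``n_seeds`` single-genotype maps with planted boundaries and
    matches merged calls to truth at +/- ``tol_bins``. Returns pooled
    precision and recall plus per-seed minima.
    """
    genome = _default_genome(n_bins)
    tp = n_called = n_true = 0
    per_p, per_r = [], []
    for k in range(n_seeds):
        lay = synthdata.make_layout(
            genome, "chrSim", n_boundaries, f_range, c=0.0,
            seed=seed * 1000 + k, min_spacing=min_spacing,
        )
        raw = synthdata.simulate_contacts(lay, depth, seed * 1000 + 500 + k)
        norm, _ = ice_normalize(raw, filter_low_coverage(raw))
        merged, _ = insulation.call_and_merge(norm)
        called = merged["bin"].to_numpy()
        hit = _matched(called, lay.boundaries, tol_bins)
        rec = _matched(lay.boundaries, called, tol_bins)
        tp += hit
        n_called += called.size
        n_true += lay.boundaries.size
        per_p.append(hit / max(1, called.size))
        per_r.append(rec / lay.boundaries.size)
    return {
        "precision": tp / max(1, n_called),
        "recall": tp / n_true,
        "min_seed_precision": min(per_p),
        "min_seed_recall": min(per_r),
    }


def score_monotonicity(
    f_values: tuple[float, ...] = (0.8, 0.6, 0.4, 0.2),
    n_bins: int = 500,
    depth: float = 5e6,
    seed: int = 7,
) -> dict:
    """Averaged insulation score at a single planted boundary across f.

    The same seed and depth are used for every f so the score differences
    reflect boundary strength alone; lower f must give a lower score.
    """
    scores = []
    for f in f_values:
        lay = synthdata.DomainLayout(
            n_bins, np.array([n_bins // 2]), np.array([f]), np.ones(n_bins, dtype=int)
        )
        raw = synthdata.simulate_contacts(lay, depth, seed)
        norm, _ = ice_normalize(raw, filter_low_coverage(raw))
        tracks = {w: insulation.insulation_track(norm, w) for w in (10, 20, 40, 80)}
        scores.append(float(insulation.average_score_track(tracks)[n_bins // 2]))
    return {
        "f_values": list(f_values),
        "scores": scores,
        "strictly_decreasing": bool(np.all(np.diff(scores) < 0)),
    }


def differential_classification(
    n_seeds: int = 20,
    n_bins: int = 500,
    depth: float = 5e6,
    n_boundaries: int = 20,
    n_strict: int = 5,
    n_partial: int = 3,
    f_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    tol_bins: int = 2,
) -> dict:
    """Recovery of strict/shared boundary classes across two genotypes.

    A strict-affected boundary counts as recovered when the harmonized set
    near it (within ``tol_bins``) is WT-only or carries an insulation delta
    > +0.1; a shared boundary when it is labeled present in both genotypes.
    """
    genome = _default_genome(n_bins)
    strict_ok = strict_tot = shared_ok = shared_tot = 0
    for k in range(n_seeds):
        truth = synthdata.make_two_genotype_truth(
            genome, "chrSim", n_boundaries, n_strict, n_partial,
            f_range=f_range, c=0.0, seed=seed * 1000 + k,
        )
        raw_wt = synthdata.simulate_contacts(truth.wt, depth, seed * 1000 + 300 + k)
        raw_mut = synthdata.simulate_contacts(truth.mut, depth, seed * 1000 + 600 + k)
        nw, _ = ice_normalize(raw_wt, filter_low_coverage(raw_wt))
        nm, _ = ice_normalize(raw_mut, filter_low_coverage(raw_mut))
        sw, tw = insulation.call_and_merge(nw)
        sm, tm = insulation.call_and_merge(nm)
        delta = insulation.differential_insulation(
            insulation.average_score_track(tm), insulation.average_score_track(tw)
        )
        cls = insulation.harmonize_genotypes(sw, sm, delta)
        bins = cls["bin"].to_numpy()
        for b in truth.affected_bins(synthdata.STRICT):
            strict_tot += 1
            near = cls[np.abs(bins - b) <= tol_bins]
            if len(near) and (
                (near["class"] == insulation.CLASS_WT_ONLY).any()
                or (near["delta"] > 0.1).any()
            ):
                strict_ok += 1
        for b in truth.shared_bins():
            shared_tot += 1
            near = cls[np.abs(bins - b) <= tol_bins]
            if len(near) and (near["class"] == insulation.CLASS_BOTH).any():
                shared_ok += 1
    return {
        "strict_detected": strict_ok / max(1, strict_tot),
        "shared_both": shared_ok / max(1, shared_tot),
        "n_strict": strict_tot,
        "n_shared": shared_tot,
    }


def compartment_recovery(
    n_seeds: int = 20,
    n_bins: int = 500,
    depth: float = 5e6,
    c: float = 0.3,
    block: int = 100_000,
    seed: int = 0,
) -> dict:
    """Eigenvector recovery of a planted checkerboard without boundaries.

    Expressed-TSS density is drawn denser in active blocks so the sign
    correction has the signal it relies on in real data. Returns the mean
    and minimum Pearson r against the planted signs and A/B label accuracy.
    """
    genome = _default_genome(n_bins)
    rs, accs = [], []
    for k in range(n_seeds):
        lay = synthdata.make_layout(
            genome, "chrSim", 0, c=c, compartment_block=block, seed=seed * 1000 + k
        )
        raw = synthdata.simulate_contacts(lay, depth, seed * 1000 + 200 + k)
        norm, _ = ice_normalize(raw, filter_low_coverage(raw))
        rng = np.random.default_rng(seed * 1000 + 400 + k)
        tss = np.where(lay.sigma > 0, rng.poisson(3.0, n_bins), rng.poisson(1.0, n_bins))
        track = compartments.compartment_eigenvector(norm, tss.astype(float))
        v = track.valid
        rs.append(float(np.corrcoef(track.eigenvector[v], lay.sigma[v])[0, 1]))
        accs.append(float(np.mean((track.eigenvector[v] > 0) == (lay.sigma[v] > 0))))
    return {
        "mean_r": float(np.mean(rs)),
        "min_r": float(np.min(rs)),
        "mean_accuracy": float(np.mean(accs)),
        "min_accuracy": float(np.min(accs)),
    }


def chip_type_one_rate(
    n_windows: int = 10_000,
    background: float = 50.0,
    dispersion: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null NB windows (2+2 replicates) with p below ``alpha``."""
    conds = [
        synthdata.ChipCondition("a", 2, background, 1.0),
        synthdata.ChipCondition("b", 2, background, 1.0),
    ]
    table = synthdata.simulate_chip_window_counts(
        np.array([], dtype=int), n_windows, conds, dispersion, seed=seed
    )
    cond_of = {col: col.rsplit("_", 1)[0] for col in table.columns}
    res = occupancy.test_windows(table, cond_of, ("a", "b"))
    return float((res["p"] < alpha).mean())


def chip_region_fdr(
    n_seeds: int = 20,
    n_windows: int = 20_000,
    background: float = 20.0,
    dispersion: float = 0.05,
    fdr: float = 0.01,
    seed: int = 0,
) -> dict:
    """Empirical region-level FDR in mixed null/alternative simulations.

    Plants 20 differential peaks (8-fold in one condition) and 30
    equally-enriched null peaks per run — the nulls survive the abundance
    filter, so the FDR is measured against retained null windows, not only
    unenriched background.
    """
    grid = occupancy.WindowGrid.over_length(n_windows * 10 + 20)
    n = grid.n_windows
    total_fp = total_regions = total_true_found = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + k)
        slots = rng.permutation(np.arange(20, n - 40, 40))
        diff_starts, null_starts = slots[:20], slots[20:50]
        fold_a, fold_b = np.ones(n), np.ones(n)
        true_diff = np.zeros(n, dtype=bool)
        for s in diff_starts:
            fold_b[s: s + 5] = 8.0
            true_diff[s: s + 5] = True
        for s in null_starts:
            fold_a[s: s + 5] = 8.0
            fold_b[s: s + 5] = 8.0
        conds = [
            synthdata.ChipCondition("a", 2, background),
            synthdata.ChipCondition("b", 2, background),
        ]
        table = synthdata.simulate_chip_window_counts(
            np.array([], dtype=int), n, conds, dispersion, seed=seed * 1000 + 500 + k,
            fold_profiles={"a": fold_a, "b": fold_b},
        )
        cond_of = {col: col.rsplit("_", 1)[0] for col in table.columns}
        keep = occupancy.filter_windows(table, 3.0)
        sub = table[keep]
        starts = grid.starts()[keep]
        factors = occupancy.tmm_factors(table)
        res = occupancy.test_windows(sub, cond_of, ("a", "b"), factors)
        regions = occupancy.combine_regions(res, starts, grid.width, fdr, 2.0)
        tw = np.flatnonzero(true_diff) * grid.spacing
        found = set()
        for _, region in regions.iterrows():
            total_regions += 1
            is_true = np.any((tw < region["end"]) & (tw + grid.width > region["start"]))
            if not is_true:
                total_fp += 1
            else:
                found.update(
                    s for s in diff_starts
                    if s * grid.spacing < region["end"]
                    and s * grid.spacing + 5 * grid.spacing + grid.width > region["start"]
                )
        total_true_found += len(found)
    return {
        "empirical_fdr": total_fp / max(1, total_regions),
        "n_regions": total_regions,
        "power": total_true_found / (20 * n_seeds),
    }


def tmm_library_ratio(
    ratio: float = 2.0,
    n_windows: int = 5000,
    background: float = 50.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> float:
    """Recovered factor ratio for two libraries differing only in depth."""
    conds = [
        synthdata.ChipCondition("a", 1, background, 1.0),
        synthdata.ChipCondition("b", 1, background, 1.0, lib_factors=(ratio,)),
    ]
    table = synthdata.simulate_chip_window_counts(
        np.array([], dtype=int), n_windows, conds, dispersion, seed=seed
    )
    factors = occupancy.tmm_factors(table)
    return float(factors["b_rep1"] / factors["a_rep1"])
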
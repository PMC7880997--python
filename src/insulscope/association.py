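"""Anchor-feature association statistics.

Distance-profile enrichment (the percentage of anchors with at least one
feature per signed 2-kb offset bin), random and expression-matched control
anchor sets, central fold-enrichment summaries, Fisher/Wilcoxon category
tests, proximity counting against external domain lists, and reporter
fluorescence-ratio summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec


@dataclass
class DistanceProfile:
    """Percentage of anchors with >= 1 feature per signed offset bin."""

    offsets: np.ndarray  # left edge of each offset bin (bp, signed)
    percent: np.ndarray
    n_anchors: int
    bin_width: int

    @property
    def centers(self) -> np.ndarray:
        return self.offsets + self.bin_width / 2


def distance_profile(
    anchors: np.ndarray,
    features: np.ndarray,
    bin_width: int = 2000,
    span: int = 20_000,
    strands: np.ndarray | None = None,
) -> DistanceProfile:
    """Per-offset-bin percentage of anchors having >= 1 nearby feature.

    Offset bins are half-open ``[anchor + o, anchor + o + bin_width)`` for
    left edges ``o`` in ``-span .. span - bin_width``. With ``strands``
    given (direction-aware mode), offsets at minus-strand anchors are
    sign-flipped so positive offsets read "downstream of the anchor".
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ValueError("empty anchor set")
    features = np.sort(np.asarray(features, dtype=float))
    offsets = np.arange(-span, span, bin_width)
    hit = np.zeros((anchors.size, offsets.size), dtype=bool)
    for k, a in enumerate(anchors):
        flip = strands is not None and strands[k] == "-"
        for m, o in enumerate(offsets):
            lo, hi = a + o, a + o + bin_width
            if flip:
                # mirror the offset bin across the anchor
                lo, hi = a - (o + bin_width), a - o
            left = np.searchsorted(features, lo, side="left")
            right = np.searchsorted(features, hi, side="left")
            hit[k, m] = right > left
    return DistanceProfile(offsets, 100.0 * hit.mean(axis=0), anchors.size, bin_width)


def random_control(
    n: int, genome: GenomeSpec, chrom: str, valid_mask: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """``n`` uniform random anchor positions over the valid genome."""
    rng = np.random.default_rng(seed)
    res = genome.resolution
    n_bins = genome.n_bins(chrom)
    mask = np.ones(n_bins, dtype=bool) if valid_mask is None else np.asarray(valid_mask, bool)
    valid_bins = np.flatnonzero(mask)
    if valid_bins.size == 0:
        raise ValueError("no valid positions to draw from")
    bins = rng.choice(valid_bins, size=n)
    return bins * res + rng.integers(0, res, size=n)


def averaged_random_control_profile(
    n_anchors: int,
    features: np.ndarray,
    genome: GenomeSpec,
    chrom: str,
    valid_mask: np.ndarray | None = None,
    n_draws: int = 10,
    bin_width: int = 2000,
    span: int = 20_000,
    seed: int = 0,
) -> DistanceProfile:
    """Random-control profile averaged over ``n_draws`` independent draws.

    A single draw (as plotted in enrichment figures) is the default
    elsewhere; the averaged version trades the figure-faithful single
    realization for a variance estimate of the control level.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_draws):
        anchors = random_control(
            n_anchors, genome, chrom, valid_mask, seed=int(rng.integers(2**31))
        )
        profiles.append(distance_profile(anchors, features, bin_width, span))
    percent = np.mean([p.percent for p in profiles], axis=0)
    return DistanceProfile(profiles[0].offsets, percent, n_anchors, bin_width)


def matched_control_sample(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    match_on: str = "expression",
    n_bins: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a control set matching the cases' covariate distribution.

    The covariate is cut into ``n_bins`` equal-frequency bins on the pooled
    values; for every bin the control draws (without replacement) exactly as
    many pool members as there are cases. A bin with cases but an
    insufficient pool raises, naming the bin.
    """
    rng = np.random.default_rng(seed)
    all_vals = np.concatenate([cases[match_on].to_numpy(), pool[match_on].to_numpy()])
    edges = np.quantile(all_vals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    case_bin = np.searchsorted(edges, cases[match_on].to_numpy(), side="right") - 1
    pool_bin = np.searchsorted(edges, pool[match_on].to_numpy(), side="right") - 1
    chosen = []
    for b in range(n_bins):
        need = int((case_bin == b).sum())
        if need == 0:
            continue
        avail = np.flatnonzero(pool_bin == b)
        if avail.size < need:
            raise ValueError(
                f"matching bin {b} needs {need} controls but pool has {avail.size}"
            )
        chosen.append(rng.choice(avail, size=need, replace=False))
    idx = np.concatenate(chosen) if chosen else np.array([], dtype=int)
    return pool.iloc[idx].reset_index(drop=True)


def fold_enrichment_at_center(
    profile: DistanceProfile, control: DistanceProfile, half_width: int = 1000
) -> float:
    """Ratio of case to control percentage within +/- half_width of offset 0.

    Both profiles must share the offset grid; the central percentage is the
    fraction of anchors with >= 1 feature in any offset bin overlapping
    ``[-half_width, +half_width)``, approximated by the mean over those
    bins. Zero control enrichment yields +inf.
    """
    if not np.array_equal(profile.offsets, control.offsets):
        raise ValueError("profiles computed on different offset grids")
    sel = (profile.offsets + profile.bin_width > -half_width) & (profile.offsets < half_width)
    case = float(profile.percent[sel].mean())
    ctrl = float(control.percent[sel].mean())
    if ctrl == 0:
        return float("inf")
    return case / ctrl


def fisher_test(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table -> (odds ratio, p)."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with continuity correction -> (W, p).

    Uses the normal approximation with continuity correction for larger
    groups (as R's wilcox.test does by default above n = 25 per group),
    otherwise the exact distribution.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(x.size, y.size) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True,
                             method=method)
    return float(res.statistic), float(res.pvalue)


def proximity_count(
    boundaries: np.ndarray,
    intervals: pd.DataFrame,
    max_size: int = 4000,
    within: int = 2000,
) -> tuple[int, float]:
    """Count small external domains close to any boundary.

    Intervals longer than ``max_size`` bp are dropped; a remaining interval
    counts when its center lies within ``within`` bp of a boundary position.
    Returns (count, fraction of boundaries with >= 1 such small domain).
    """
    boundaries = np.sort(np.asarray(boundaries, dtype=float))
    sizes = intervals["end"].to_numpy() - intervals["start"].to_numpy()
    small = intervals[sizes <= max_size]
    if small.empty or boundaries.size == 0:
        return 0, 0.0
    centers = (small["start"].to_numpy() + small["end"].to_numpy()) / 2
    idx = np.clip(np.searchsorted(boundaries, centers), 1, boundaries.size - 1)
    nearest = np.minimum(
        np.abs(centers - boundaries[idx - 1]), np.abs(centers - boundaries[np.minimum(idx, boundaries.size - 1)])
    )
    hit = nearest <= within
    involved = {
        int(np.argmin(np.abs(boundaries - c))) for c in centers[hit]
    }
    return int(hit.sum()), len(involved) / boundaries.size


def reporter_ratio_summary(replicates: list[pd.DataFrame]) -> tuple[list[float], float]:
    """Per-replicate median log2 fluorescence ratio and their mean.

    Each replicate frame holds per-cell ``mcherry`` and ``egfp`` intensities;
    cells with a non-positive intensity are dropped (logged). Returns the
    per-replicate medians of log2(mCherry/EGFP) and their cross-replicate
    mean.
    """
    import logging

    medians = []
    dropped = 0
    for rep in replicates:
        ok = (rep["mcherry"] > 0) & (rep["egfp"] > 0)
        dropped += int((~ok).sum())
        if not ok.any():
            raise ValueError("replicate has no cells with positive intensities")
        ratios = np.log2(rep.loc[ok, "mcherry"].to_numpy() / rep.loc[ok, "egfp"].to_numpy())
        medians.append(float(np.median(ratios)))
    if dropped:
        logging.getLogger(__name__).info("reporter_ratio_summary: dropped %d cells", dropped)
    return medians, float(np.mean(medians))
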
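"""Insulation scoring and contact-domain boundary calling.

For a window of ``w`` bins, ``binSignal_i`` is the mean normalized contact
frequency of the w x w rectangle between the ``w`` bins up to and including
``i`` and the ``w`` bins after ``i`` (the cross-boundary "diamond"). The
physical insulation score at bin ``i`` is

    score_i = log2( binSignal_i / sum_{i - w/2 < j < i + w/2} binSignal_j )

with strict bounds on ``j`` (for even ``w`` the denominator has ``w - 1``
terms, e.g. 9 terms at w = 10). The denominator is a *sum*, so the score
carries a constant ``-log2(n_terms)`` offset relative to a local-mean
normalization; the offset cancels in every between-genotype or
between-position difference, and lower scores mean stronger boundaries.

Boundary calling is TopDom-compatible but not bit-identical: local minima of
binSignal are pruned by a one-sided rank-sum test that cross-boundary
contacts are lower than flanking within-domain contacts. The test is run on
observed-over-expected values (raw contact values would compare cells at
systematically different distances under the decay background), with an
additional effect-size gate on the cross/within mean ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hic import NORMALIZED, ContactMatrix, observed_over_expected

DEFAULT_WINDOWS_BP = (20_000, 40_000, 80_000, 160_000)

CLASS_BOTH = "both"
CLASS_WT_ONLY = "wt_only"
CLASS_MUT_ONLY = "mutant_only"


@dataclass
class InsulationTrack:
    """Per-bin binSignal and insulation score for one window size (in bins)."""

    w: int
    bin_signal: np.ndarray
    score: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.score)


def bin_signal(matrix: ContactMatrix, w: int) -> np.ndarray:
    """Mean contact frequency of the w x w cross rectangle at each bin.

    The rectangle spans rows ``i-w+1 .. i`` and columns ``i+1 .. i+w``
    (clipped — hence truncated — at chromosome ends); the mean is taken over
    valid (finite) cells only and is NaN where no valid cell exists.
    """
    n = matrix.n_bins
    if w < 1:
        raise ValueError("w must be >= 1")
    if w >= n:
        raise ValueError(f"window w={w} bins is not smaller than the chromosome ({n} bins)")
    m = matrix.matrix
    out = np.full(n, np.nan)
    for i in range(n - 1):
        rect = m[max(0, i - w + 1): i + 1, i + 1: min(n, i + w + 1)]
        finite = np.isfinite(rect)
        if finite.any():
            out[i] = rect[finite].mean()
    return out


def insulation_score(signal: np.ndarray, w: int) -> np.ndarray:
    """Insulation score from a binSignal track (see module docstring).

    Invalid wherever any denominator term is invalid (including truncation at
    chromosome ends) or the denominator is not positive.
    """
    n = signal.size
    half = (w - 1) // 2 if w % 2 else w // 2 - 1  # strict bounds: |j - i| <= half
    score = np.full(n, np.nan)
    for i in range(n):
        lo, hi = i - half, i + half
        if lo < 0 or hi >= n:
            continue
        window = signal[lo: hi + 1]
        if not np.all(np.isfinite(window)):
            continue
        denom = window.sum()
        if denom > 0 and np.isfinite(signal[i]) and signal[i] > 0:
            score[i] = np.log2(signal[i] / denom)
    return score


def insulation_track(matrix: ContactMatrix, w: int) -> InsulationTrack:
    sig = bin_signal(matrix, w)
    return InsulationTrack(w, sig, insulation_score(sig, w))


def _local_minima(signal: np.ndarray) -> list[int]:
    """Indices of local minima of a track; plateaus yield their leftmost bin."""
    n = signal.size
    minima = []
    i = 1
    while i < n - 1:
        if not np.isfinite(signal[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and signal[j + 1] == signal[i]:
            j += 1
        left, right = signal[i - 1], signal[min(j + 1, n - 1)]
        if np.isfinite(left) and np.isfinite(right) and signal[i] < left and (
            j + 1 >= n or signal[i] < right
        ):
            minima.append(i)
        i = j + 1
    return minima


def call_boundaries(
    matrix: ContactMatrix,
    w: int,
    p_cut: float = 0.05,
    max_ratio: float = 0.8,
    oe: ContactMatrix | None = None,
) -> np.ndarray:
    """Candidate boundary bins for one window size.

    Candidates are local minima of binSignal. Bins inside wide masked
    stretches have no valid rectangle cells, hence NaN binSignal, and are
    never candidates; isolated masked bins remain callable from their valid
    neighborhood. A candidate is retained when (1) a one-sided rank-sum test
    finds its cross-rectangle observed/expected values lower than the
    flanking within-domain values at ``p < p_cut`` and (2) the cross/within
    mean ratio is <= ``max_ratio``.
    """
    matrix.require_state(NORMALIZED)
    sig = bin_signal(matrix, w)
    if oe is None:
        oe = observed_over_expected(matrix)
    om = oe.matrix
    n = matrix.n_bins
    kept = []
    for i in _local_minima(sig):
        lo, hi = max(0, i - w + 1), min(n, i + w + 1)
        cross = om[lo: i + 1, i + 1: hi]
        cross = cross[np.isfinite(cross)]
        up = om[lo: i + 1, lo: i + 1][np.triu_indices(i + 1 - lo, k=1)]
        down = om[i + 1: hi, i + 1: hi][np.triu_indices(hi - i - 1, k=1)]
        within = np.concatenate([up, down])
        within = within[np.isfinite(within)]
        if cross.size < 3 or within.size < 3:
            continue
        mean_within = within.mean()
        if mean_within <= 0 or cross.mean() / mean_within > max_ratio:
            continue
        p = stats.mannwhitneyu(cross, within, alternative="less").pvalue
        if p < p_cut:
            kept.append(i)
    return np.asarray(kept, dtype=int)


def merge_across_windows(
    calls: dict[int, np.ndarray],
    tracks: dict[int, InsulationTrack],
    required: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Union of per-window boundary calls, scored by the across-window mean.

    Every boundary bin found at any window size is retained; its score is the
    arithmetic mean of the per-window insulation scores at that bin (NaN
    windows ignored). ``required`` (default: the window sizes present in
    ``tracks``) lists window sizes that must have been computed.
    """
    required = required or tuple(sorted(tracks))
    missing = [w for w in required if w not in calls or w not in tracks]
    if missing:
        raise ValueError(f"missing boundary calls/tracks for window sizes {missing}")
    support: dict[int, list[int]] = {}
    for w in required:
        for b in calls[w]:
            support.setdefault(int(b), []).append(w)
    bins = sorted(support)
    score_stack = np.array([tracks[w].score for w in required])
    scores = [float(np.nanmean(score_stack[:, b])) for b in bins]
    return pd.DataFrame(
        {"bin": bins, "score": scores, "windows": [tuple(support[b]) for b in bins]}
    )


def _chains(bins: np.ndarray, gap: float, resolution: int) -> list[np.ndarray]:
    """Group sorted boundary bins transitively by edge-to-edge distance.

    Boundaries are whole bins of ``resolution`` bp, so the distance between
    bins b1 < b2 is the gap between their intervals, ``(b2 - b1 - 1) *
    resolution``; consecutive boundaries within ``gap`` of each other chain
    into one group (a-b and b-c within gap chain all three even when a-c is
    not).
    """
    if bins.size == 0:
        return []
    edge_gap = (np.diff(bins) - 1) * resolution
    breaks = np.flatnonzero(edge_gap > gap) + 1
    return np.split(np.arange(bins.size), breaks)


def merge_consecutive_boundaries(
    boundaries: pd.DataFrame, gap: float = 2000, resolution: int = 2000
) -> pd.DataFrame:
    """Collapse chains of boundaries within ``gap`` bp to their strongest member.

    Distances are edge-to-edge between boundary bins (a boundary is a whole
    bin); grouping is transitive (a-b and b-c within gap chain all three).
    Each chain is replaced by the member with the lowest insulation score
    (leftmost on ties), so output boundaries are pairwise > gap apart.
    """
    if boundaries.empty:
        return boundaries.copy()
    df = boundaries.sort_values("bin", kind="stable").reset_index(drop=True)
    bins = df["bin"].to_numpy()
    keep_rows = []
    for chain in _chains(bins, gap, resolution):
        sub = df.iloc[chain]
        keep_rows.append(sub.index[np.argmin(sub["score"].to_numpy())])
    return df.loc[keep_rows].reset_index(drop=True)


def differential_insulation(score_mut: np.ndarray, score_wt: np.ndarray) -> np.ndarray:
    """Per-bin insulation-score difference, mutant minus WT.

    Positive delta = weaker insulation in the mutant (lower score = stronger
    boundary). NaN wherever either input is NaN.
    """
    score_mut = np.asarray(score_mut, dtype=float)
    score_wt = np.asarray(score_wt, dtype=float)
    if score_mut.shape != score_wt.shape:
        raise ValueError("score tracks must share the bin grid")
    return score_mut - score_wt


def harmonize_genotypes(
    set_wt: pd.DataFrame,
    set_mut: pd.DataFrame,
    delta: np.ndarray,
    gap: float = 2000,
    weak_thresh: float = 0.1,
    resolution: int = 2000,
) -> pd.DataFrame:
    """Merge WT and mutant boundary sets into one classified set.

    Boundaries from both genotypes are pooled and chain-merged within
    ``gap`` bp. A chain containing both genotypes is class ``both`` (score =
    mean of the two genotypes' best scores); otherwise ``wt_only`` /
    ``mutant_only``. The representative bin is the lowest-score member. The
    insulation-score delta (mutant - WT) is read at that bin;
    ``weaker_in_mutant`` flags delta > +weak_thresh, ``weaker_in_wt`` flags
    delta < -weak_thresh.
    """
    frames = []
    for name, df in (("wt", set_wt), ("mut", set_mut)):
        if not df.empty:
            frames.append(df.assign(genotype=name))
    if not frames:
        return pd.DataFrame(
            columns=["bin", "score", "class", "delta", "weaker_in_mutant", "weaker_in_wt"]
        )
    pooled = pd.concat(frames, ignore_index=True).sort_values("bin", kind="stable")
    pooled = pooled.reset_index(drop=True)
    bins = pooled["bin"].to_numpy()
    rows = []
    for chain in _chains(bins, gap, resolution):
        sub = pooled.iloc[chain]
        genos = set(sub["genotype"])
        rep = sub.iloc[int(np.argmin(sub["score"].to_numpy()))]
        if genos == {"wt", "mut"}:
            cls = CLASS_BOTH
            score = float(
                np.mean([sub[sub.genotype == g]["score"].min() for g in ("wt", "mut")])
            )
        elif genos == {"wt"}:
            cls, score = CLASS_WT_ONLY, float(rep["score"])
        else:
            cls, score = CLASS_MUT_ONLY, float(rep["score"])
        b = int(rep["bin"])
        d = float(delta[b]) if 0 <= b < len(delta) else np.nan
        rows.append(
            {
                "bin": b,
                "score": score,
                "class": cls,
                "delta": d,
                "weaker_in_mutant": bool(np.isfinite(d) and d > weak_thresh),
                "weaker_in_wt": bool(np.isfinite(d) and d < -weak_thresh),
            }
        )
    return pd.DataFrame(rows)


def call_and_merge(
    matrix: ContactMatrix,
    windows_bp: tuple[int, ...] = DEFAULT_WINDOWS_BP,
    p_cut: float = 0.05,
    max_ratio: float = 0.8,
    merge_gap: float = 2000,
    sharpen: bool = True,
) -> tuple[pd.DataFrame, dict[int, InsulationTrack]]:
    """Full per-genotype boundary calling: all window sizes, merged and pruned.

    Window sizes are given in bp and converted to bins; returns the merged
    boundary set and the per-window insulation tracks (for the average track
    and differential analysis).

    With ``sharpen`` (default), merged boundaries are kept only when they
    lie within one bin of a call at the smallest window size: the smallest
    window carries the positional resolution, while larger windows drift
    between closely spaced boundaries (their rectangle spans both), so
    isolated large-window positions can sit bins away from any boundary.
    Larger windows still corroborate calls and contribute to the averaged
    score.
    """
    ws = tuple(b // matrix.resolution for b in windows_bp)
    oe = observed_over_expected(matrix)
    tracks = {w: insulation_track(matrix, w) for w in ws}
    calls = {w: call_boundaries(matrix, w, p_cut, max_ratio, oe) for w in ws}
    merged = merge_across_windows(calls, tracks, required=ws)
    if sharpen and not merged.empty:
        anchors = np.asarray(calls[min(ws)])
        near = merged["bin"].map(
            lambda b: anchors.size > 0 and np.abs(anchors - b).min() <= 1
        ).to_numpy()
        merged = merged[near].reset_index(drop=True)
    return merge_consecutive_boundaries(merged, merge_gap, matrix.resolution), tracks


def average_score_track(tracks: dict[int, InsulationTrack]) -> np.ndarray:
    """Across-window mean insulation score per bin (NaN windows ignored)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        return np.nanmean(np.array([t.score for t in tracks.values()]), axis=0)
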
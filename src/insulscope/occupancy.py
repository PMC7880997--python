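"""Windowed differential ChIP occupancy, dependency classes, and PWM scanning.

Counts are tallied in sliding windows (20 bp wide, 10 bp apart by default),
background-filtered (3-fold over the between-sample median background),
TMM-normalized and tested per window with a pooled-dispersion
negative-binomial exact conditional test. Adjacent significant windows are
clustered into regions whose p-value is the Simes combination of member
windows; Benjamini-Hochberg across regions controls the FDR. A region's
*occupancy* is the log2 fold change of its most significant window
(best.log2FC) and its reported *position* that window's center (best.pos).

Dependency classification mirrors the three-way genotype comparison design:
a binding region detected in WT (vs knockout) is *strictly dependent* on a
factor when no region is detectable in the factor-null mutant (vs knockout),
*partially dependent* when a mutant region exists but the locus is called
reduced in mutant-vs-WT, and *independent* otherwise; overlapping partner
regions split a peak into fragments so each fragment carries one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

INDEPENDENT = "independent"
STRICT_DEP = "strictly-dependent"
PARTIAL_DEP = "partially-dependent"

# CTCF motif pair from the insulator-reporter construct: the wildtype binding
# site and its 2-bp mutant used to abolish CTCF binding.
REPORTER_MOTIF_WT = "ATGTCAGAGGGCGCT"
REPORTER_MOTIF_MUT = "ATGTCAGACAGCGCT"


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid: window k covers [k*spacing, k*spacing + width)."""

    width: int = 20
    spacing: int = 10
    n_windows: int = 0

    @classmethod
    def over_length(cls, length: int, width: int = 20, spacing: int = 10) -> "WindowGrid":
        n = max(0, (length - width) // spacing + 1)
        return cls(width, spacing, n)

    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.spacing

    def centers(self) -> np.ndarray:
        return self.starts() + self.width / 2


def count_windows(
    reads: pd.DataFrame, grid: WindowGrid, dedup: bool = True
) -> np.ndarray:
    """Per-window read counts; a read increments every window it overlaps.

    ``reads`` needs ``start``/``end`` columns (0-based half-open) and
    optionally ``strand``; with ``dedup`` identical (chrom, start, end,
    strand) intervals are counted once.
    """
    if reads.empty:
        return np.zeros(grid.n_windows, dtype=int)
    df = reads
    if dedup:
        keys = [c for c in ("chrom", "start", "end", "strand") if c in df.columns]
        df = df.drop_duplicates(subset=keys)
    acc = np.zeros(grid.n_windows + 1, dtype=int)
    w, s = grid.width, grid.spacing
    for rs, re in zip(df["start"].to_numpy(), df["end"].to_numpy()):
        if re <= rs:
            continue
        # windows overlapping [rs, re): k*s < re and rs < k*s + w
        k_min = max(0, (rs - w) // s + 1)
        k_max = min(grid.n_windows - 1, (re - 1) // s)
        if k_max >= k_min:
            acc[k_min] += 1
            acc[k_max + 1] -= 1
    return np.cumsum(acc[:-1])


def filter_windows(
    table: pd.DataFrame, fold: float = 3.0, background: float | None = None
) -> np.ndarray:
    """Boolean mask of windows at >= ``fold`` x background average abundance.

    The background is the median across samples of each sample's mean window
    count (an estimate, at window scale, of the genome-wide per-2-kb-bin
    average the filter is defined against). Zero background keeps every
    window with nonzero abundance, with a warning.
    """
    counts = table.to_numpy(dtype=float)
    if background is None:
        background = float(np.median(counts.mean(axis=0)))
    abundance = counts.mean(axis=1)
    if background == 0:
        import logging

        logging.getLogger(__name__).warning("filter_windows: zero background")
        return abundance > 0
    return abundance >= fold * background


def tmm_factors(
    table: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample effective scaling factors by trimmed mean of M-values.

    Factors capture the relative effective sequencing depth of each library
    (library size times composition), anchored so their product is 1.
    M-values are computed against the reference sample whose upper quartile
    is closest to the mean upper quartile; 30% of M and 5% of A values are
    trimmed symmetrically and the remainder averaged with precision weights.
    """
    counts = table.to_numpy(dtype=float)
    if counts.shape[0] < 1 or counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if np.any(counts.sum(axis=0) == 0):
        bad = table.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero retained counts: {bad}")
    uq = np.quantile(counts, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    log_factors = np.zeros(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        both = (counts[:, k] > 0) & (counts[:, ref] > 0)
        x, r = counts[both, k], counts[both, ref]
        if x.size == 0:
            raise ValueError(f"sample {table.columns[k]} shares no nonzero windows with reference")
        m = np.log2(x / r)
        a = 0.5 * np.log2(x * r)
        keep = np.ones(x.size, dtype=bool)
        for vals, trim in ((m, trim_m), (a, trim_a)):
            lo, hi = np.quantile(vals[keep], [trim / 2, 1 - trim / 2])
            keep &= (vals >= lo) & (vals <= hi)
        wts = 1.0 / (1.0 / x[keep] + 1.0 / r[keep])
        log_factors[k] = float(np.average(m[keep], weights=wts))
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric-mean anchor
    return pd.Series(factors, index=table.columns)


def estimate_dispersion(norm_counts: np.ndarray, groups: list[np.ndarray]) -> float:
    """Pooled method-of-moments NB dispersion across windows.

    For replicate groups, var = mu + phi*mu^2; phi is estimated from the
    pooled sums of (var - mean) against (mean^2 - var/r), clipped at a small
    positive floor.
    """
    num = den = 0.0
    for idx in groups:
        if idx.size < 2:
            continue
        y = norm_counts[:, idx]
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2 - v / idx.size))
    if den <= 0:
        return 1e-8
    return max(1e-8, num / den)


def _nb_params(mean: float, phi: float) -> tuple[float, float]:
    size = 1.0 / phi
    return size, size / (size + mean)


def test_windows(
    table: pd.DataFrame,
    condition_of: dict[str, str],
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-window two-sided p and log2FC for one condition contrast.

    Counts are divided by the per-sample scaling factors, the pooled NB
    dispersion is estimated from the data (unless supplied), and each window
    is tested with an exact conditional NB test on the per-condition sums
    (two-sided by summing outcome probabilities not exceeding the observed
    one). log2FC is ``log2((meanB + 0.5) / (meanA + 0.5))`` of normalized
    per-replicate means for contrast (A, B).
    """
    cond_a, cond_b = contrast
    cols_a = [c for c in table.columns if condition_of.get(c) == cond_a]
    cols_b = [c for c in table.columns if condition_of.get(c) == cond_b]
    if not cols_a or not cols_b:
        raise ValueError("each contrast condition needs >= 1 replicate column")
    counts = table.to_numpy(dtype=float)
    if factors is not None:
        counts = counts / factors.reindex(table.columns).to_numpy()[None, :]
    ia = np.array([table.columns.get_loc(c) for c in cols_a])
    ib = np.array([table.columns.get_loc(c) for c in cols_b])
    if dispersion is None:
        dispersion = estimate_dispersion(counts, [ia, ib])
    ra, rb = len(cols_a), len(cols_b)
    sa = counts[:, ia].sum(axis=1)
    sb = counts[:, ib].sum(axis=1)
    mean_a = sa / ra
    mean_b = sb / rb
    l2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    pvals = np.ones(counts.shape[0])
    for w in range(counts.shape[0]):
        pvals[w] = _exact_nb_test(sa[w], sb[w], ra, rb, dispersion)
    return pd.DataFrame({"p": pvals, "log2fc": l2fc}, index=table.index)


def _exact_nb_test(sa: float, sb: float, ra: int, rb: int, phi: float) -> float:
    """Exact conditional two-sided NB test on condition sums."""
    s = int(round(sa + sb))
    ka = int(round(sa))
    if s == 0:
        return 1.0
    mu = s / (ra + rb)  # common per-replicate mean under the null
    size_a, p_a = _nb_params(ra * mu, phi / ra)
    size_b, p_b = _nb_params(rb * mu, phi / rb)
    k = np.arange(s + 1)
    joint = nbinom.pmf(k, size_a, p_a) * nbinom.pmf(s - k, size_b, p_b)
    total = joint.sum()
    if total <= 0:
        return 1.0
    p_obs = joint[min(ka, s)]
    return float(min(1.0, joint[joint <= p_obs * (1 + 1e-12)].sum() / total))


def simes_p(pvals: np.ndarray) -> float:
    """Simes combination of a set of p-values."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    return float(min(1.0, np.min(p * m / np.arange(1, m + 1))))


def combine_regions(
    results: pd.DataFrame,
    window_starts: np.ndarray,
    window_width: int,
    fdr: float = 0.01,
    min_fc: float = 2.0,
    merge_gap: int = 100,
) -> pd.DataFrame:
    """Cluster adjacent windows into regions, combine p-values, apply BH.

    ``results`` holds per-window ``p`` and ``log2fc`` for the retained
    windows; windows whose intervals lie within ``merge_gap`` bp of each
    other join the same region. Region p = Simes over member windows; BH is
    applied across all regions; reported regions satisfy FDR < ``fdr`` and
    |fold change| > ``min_fc``. The region's occupancy is the log2FC of the
    window with the smallest p (ties: larger |log2FC|, then leftmost) and its
    position that window's center.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["start", "end", "p", "fdr", "occupancy", "best_pos", "n_windows"]
        )
    starts = np.asarray(window_starts, dtype=int)
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    res = results.iloc[order]
    gap_break = np.flatnonzero(starts[1:] - (starts[:-1] + window_width) > merge_gap) + 1
    groups = np.split(np.arange(starts.size), gap_break)
    rows = []
    for g in groups:
        p = res["p"].to_numpy()[g]
        fc = res["log2fc"].to_numpy()[g]
        best = np.lexsort((g, -np.abs(fc), p))[0]
        rows.append(
            {
                "start": int(starts[g[0]]),
                "end": int(starts[g[-1]] + window_width),
                "p": simes_p(p),
                "occupancy": float(fc[best]),
                "best_pos": float(starts[g[best]] + window_width / 2),
                "n_windows": int(g.size),
            }
        )
    regions = pd.DataFrame(rows)
    m = len(regions)
    order_p = np.argsort(regions["p"].to_numpy(), kind="stable")
    ranked = regions["p"].to_numpy()[order_p] * m / np.arange(1, m + 1)
    qvals = np.minimum.accumulate(ranked[::-1])[::-1]
    regions["fdr"] = 1.0
    regions.loc[regions.index[order_p], "fdr"] = np.minimum(qvals, 1.0)
    keep = (regions["fdr"] < fdr) & (np.abs(regions["occupancy"]) > np.log2(min_fc))
    return regions[keep].reset_index(drop=True)


def _overlaps(start: float, end: float, frame: pd.DataFrame) -> bool:
    return bool(((frame["start"] < end) & (frame["end"] > start)).any())


def classify_peak_dependency(
    peaks_wt_vs_ko: pd.DataFrame,
    peaks_mut_vs_ko: pd.DataFrame,
    reduced_mut_vs_wt: pd.DataFrame,
) -> pd.DataFrame:
    """Label WT binding regions by their dependency on the deleted factor.

    Each WT-vs-KO peak is split at the edges of overlapping mutant-vs-KO
    peaks (so fragments are uniformly covered or uncovered); a fragment with
    no mutant-vs-KO overlap is strictly dependent, one with overlap plus a
    reduced-in-mutant call is partially dependent, otherwise independent.
    """
    rows = []
    cut_sources = pd.concat([peaks_mut_vs_ko, reduced_mut_vs_wt], ignore_index=True) \
        if len(peaks_mut_vs_ko) or len(reduced_mut_vs_wt) else pd.DataFrame(columns=["start", "end"])
    for _, pk in peaks_wt_vs_ko.iterrows():
        s, e = float(pk["start"]), float(pk["end"])
        cuts = sorted(
            {s, e}
            | {
                float(x)
                for col in ("start", "end")
                for x in cut_sources[col]
                if s < float(x) < e
            }
        )
        for fs, fe in zip(cuts[:-1], cuts[1:]):
            in_mut = _overlaps(fs, fe, peaks_mut_vs_ko)
            in_reduced = _overlaps(fs, fe, reduced_mut_vs_wt)
            if not in_mut:
                cls = STRICT_DEP
            elif in_reduced:
                cls = PARTIAL_DEP
            else:
                cls = INDEPENDENT
            rows.append({"start": fs, "end": fe, "class": cls, "parent_start": s})
    return pd.DataFrame(rows)


def pwm_from_consensus(consensus: str, match_prob: float = 0.97) -> np.ndarray:
    """(4, L) probability matrix concentrated on a consensus sequence."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((4, len(consensus)), (1 - match_prob) / 3)
    for j, base in enumerate(consensus.upper()):
        pwm[idx[base], j] = match_prob
    return pwm


def read_jaspar_pfm(path) -> np.ndarray:
    """Read a JASPAR-format position frequency matrix into a (4, L) PWM."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    counts += 0.5  # pseudocount
    return counts / counts.sum(axis=0, keepdims=True)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def pwm_scan(seq: str, pwm: np.ndarray, threshold: float = 0.0) -> pd.DataFrame:
    """Scan both strands of ``seq`` with a probability PWM.

    Scores are log2 odds against a uniform background; N contributes 0
    (background). A minus-strand hit at position ``pos`` means the reverse
    complement of ``seq[pos:pos+L]`` matches the motif. Raises on letters
    outside {A, C, G, T, N}.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"sequence contains letters outside ACGTN: {set(seq) - set('ACGTN')}")
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    L = pwm.shape[1]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand in "+-":
        lod = logodds if strand == "+" else logodds[::-1, ::-1]  # revcomp of the motif
        for pos in range(len(seq) - L + 1):
            score = 0.0
            for j in range(L):
                base = seq[pos + j]
                if base != "N":
                    score += lod[idx[base], j]
            if score >= threshold:
                hits.append({"pos": pos, "strand": strand, "score": score})
    return pd.DataFrame(hits, columns=["pos", "strand", "score"])


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))
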
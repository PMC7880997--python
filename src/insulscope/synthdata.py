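"""Synthetic two-genotype Hi-C / ChIP / gene-table generator with ground truth.

The generative contact model is deliberately simple enough that every
downstream statistic has a predictable behaviour. For a single chromosome
binned into ``n`` bins, the expected contact count between bins ``i < j`` is

    E[i, j] = A * (j - i)^(-alpha) * (1 + c * sigma_i * sigma_j)
              * prod(f_b for boundaries b with i <= b < j)

i.e. a power-law distance decay, a rank-1 checkerboard compartment term with
per-bin signs ``sigma`` and strength ``c``, and multiplicative attenuation by
every planted boundary crossed. A boundary "at bin b" separates bins
``<= b`` from bins ``> b``; its insulation factor ``f`` in (0, 1] multiplies
all crossing contacts (``f = 1`` means no boundary). The diagonal is zero and
counts are Poisson with the expected total scaled to a target depth.

Mutant genotypes are derived by removing boundaries (strict loss, ``f -> 1``)
or weakening them (partial loss, ``f -> f**gamma``), mirroring the strict
versus partial CTCF dependency of contact-domain boundaries that the analysis
pipeline classifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .hic import RAW, ContactMatrix

STRICT = "strict"
PARTIAL = "partial"


@dataclass(frozen=True)
class DomainLayout:
    """Planted domain structure for one chromosome.

    ``boundaries`` are strictly increasing bin indices; ``f`` the matching
    insulation factors in (0, 1]; ``sigma`` per-bin compartment signs (+/-1);
    ``c`` compartment strength in [0, 1); ``alpha`` the decay exponent;
    ``amplitude`` the (relative) decay amplitude.
    """

    n_bins: int
    boundaries: np.ndarray
    f: np.ndarray
    sigma: np.ndarray
    c: float = 0.0
    alpha: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries", np.asarray(self.boundaries, dtype=int))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=int))
        if self.boundaries.size and np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries.size != self.f.size:
            raise ValueError("one insulation factor per boundary required")
        if np.any((self.f <= 0) | (self.f > 1)):
            raise ValueError("insulation factors must lie in (0, 1]")
        if self.sigma.size != self.n_bins:
            raise ValueError("sigma must be defined for every bin")
        if not 0 <= self.c < 1:
            raise ValueError("compartment strength c must be in [0, 1)")
        if self.alpha <= 0 or self.amplitude <= 0:
            raise ValueError("alpha and amplitude must be > 0")


@dataclass
class GroundTruth:
    """Planted truth used by parameter-recovery tests.

    ``affected`` maps a WT boundary id (index into ``wt.boundaries``) to its
    loss mode (``strict`` or ``partial``); strict boundaries are absent from
    the mutant layout.
    """

    genome: GenomeSpec
    chrom: str
    wt: DomainLayout
    mut: DomainLayout
    affected: dict[int, str] = field(default_factory=dict)
    gamma: float = 0.5
    peak_truth: pd.DataFrame | None = None
    gene_table: pd.DataFrame | None = None

    def affected_bins(self, mode: str | None = None) -> np.ndarray:
        ids = [i for i, m in self.affected.items() if mode is None or m == mode]
        return self.wt.boundaries[sorted(ids)]

    def shared_bins(self) -> np.ndarray:
        ids = [i for i in range(self.wt.boundaries.size) if i not in self.affected]
        return self.wt.boundaries[ids]


def make_layout(
    genome: GenomeSpec,
    chrom: str,
    n_boundaries: int,
    f_range: tuple[float, float] = (0.2, 0.5),
    compartment_block: int = 50_000,
    c: float = 0.0,
    alpha: float = 1.0,
    seed: int = 0,
    min_spacing: int = 5,
    edge_margin: int = 40,
) -> DomainLayout:
    """Place ``n_boundaries`` random boundaries with minimum spacing.

    Boundary bins are sampled uniformly with pairwise spacing >=
    ``min_spacing`` bins and at least ``edge_margin`` bins from either
    chromosome end (insulation windows truncate near the ends, so planted
    boundaries there would be unscorable; the default margin is half the
    largest default window size). Insulation factors are drawn uniformly
    from ``f_range`` and compartment signs alternate in blocks of
    ``compartment_block`` bp.
    """
    rng = np.random.default_rng(seed)
    n_bins = genome.n_bins(chrom)
    margin = max(min_spacing, edge_margin)
    lo, hi = margin, n_bins - 1 - margin
    # sampling k points with pairwise gaps >= g on [lo, hi]: sample without
    # replacement from a contracted range, sort, then re-expand
    slots = (hi - lo + 1) - (n_boundaries - 1) * (min_spacing - 1) if n_boundaries else 1
    if n_boundaries < 0:
        raise ValueError("n_boundaries must be >= 0")
    if n_boundaries and (slots < n_boundaries or hi < lo):
        raise ValueError(
            f"cannot place {n_boundaries} boundaries with spacing {min_spacing} in {n_bins} bins"
        )
    if n_boundaries:
        picks = np.sort(rng.choice(slots, size=n_boundaries, replace=False))
        boundaries = lo + picks + np.arange(n_boundaries) * (min_spacing - 1)
    else:
        boundaries = np.array([], dtype=int)
    f_lo, f_hi = f_range
    if not (0 < f_lo <= f_hi <= 1):
        raise ValueError("f_range must lie within (0, 1]")
    f = rng.uniform(f_lo, f_hi, size=n_boundaries)
    block_bins = max(1, compartment_block // genome.resolution)
    sigma = np.where((np.arange(n_bins) // block_bins) % 2 == 0, 1, -1)
    return DomainLayout(n_bins, boundaries, f, sigma, c=c, alpha=alpha)


def expected_matrix(layout: DomainLayout, depth: float | None = None) -> np.ndarray:
    """Closed-form expected contact matrix (diagonal 0, symmetric).

    If ``depth`` is given the matrix is rescaled so the upper-triangle total
    equals ``depth`` exactly.
    """
    n = layout.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(d > 0, d ** -layout.alpha, 0.0)
    comp = 1.0 + layout.c * np.outer(layout.sigma, layout.sigma)
    # cumulative log-attenuation: cum[k] = sum(log f_b for boundaries b < k)
    cum = np.zeros(n + 1)
    if layout.boundaries.size:
        logf = np.zeros(n)
        logf[layout.boundaries] = np.log(layout.f)
        cum[1:] = np.cumsum(logf)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    att = np.exp(cum[np.maximum(i, j)] - cum[np.minimum(i, j)])
    exp = layout.amplitude * decay * comp * att
    np.fill_diagonal(exp, 0.0)
    if depth is not None:
        total = np.triu(exp).sum()
        if total <= 0:
            raise ValueError("expected matrix has zero total")
        exp *= depth / total
    return exp


def simulate_contacts(layout: DomainLayout, depth: float, seed: int, resolution: int = 2000,
                      chrom: str = "chrSim") -> ContactMatrix:
    """Poisson-sample a raw contact matrix at the target depth.

    The expected upper-triangle total equals ``depth``; the realized total is
    Poisson-distributed around it.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    exp = expected_matrix(layout, depth=depth)
    n = layout.n_bins
    iu = np.triu_indices(n, k=1)
    counts = rng.poisson(exp[iu]).astype(float)
    m = np.zeros((n, n))
    m[iu] = counts
    m = m + m.T
    return ContactMatrix(chrom, resolution, m, state=RAW)


def derive_mutant_layout(
    wt: DomainLayout, affected: dict[int, str], gamma: float = 0.5
) -> DomainLayout:
    """Apply strict/partial boundary loss to a WT layout.

    Strict-affected boundaries are removed (attenuation factor 1); partially
    affected ones are weakened to ``f**gamma`` (gamma in (0, 1) moves f
    toward 1). All other boundaries are untouched.
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    keep, f_out = [], []
    n_b = wt.boundaries.size
    for bid, mode in affected.items():
        if not 0 <= bid < n_b:
            raise KeyError(f"affected boundary id {bid} not in WT layout (0..{n_b - 1})")
        if mode not in (STRICT, PARTIAL):
            raise ValueError(f"unknown mode {mode!r}")
    for bid in range(n_b):
        mode = affected.get(bid)
        if mode == STRICT:
            continue
        keep.append(wt.boundaries[bid])
        f_out.append(wt.f[bid] ** gamma if mode == PARTIAL else wt.f[bid])
    return DomainLayout(
        wt.n_bins, np.array(keep, dtype=int), np.array(f_out), wt.sigma,
        c=wt.c, alpha=wt.alpha, amplitude=wt.amplitude,
    )


def make_two_genotype_truth(
    genome: GenomeSpec,
    chrom: str,
    n_boundaries: int,
    n_strict: int,
    n_partial: int,
    f_range: tuple[float, float] = (0.2, 0.5),
    compartment_block: int = 50_000,
    c: float = 0.0,
    alpha: float = 1.0,
    gamma: float = 0.5,
    seed: int = 0,
    min_spacing: int = 10,
) -> GroundTruth:
    """Build a WT layout plus a mutant with planted strict/partial losses.

    The default boundary spacing floor of 10 bins (20 kb at the default
    resolution) reflects the smallest contact domains observed in fly Hi-C
    maps at this scale; closer planted pairs are below the positional
    resolution of a 20-kb insulation window.
    """
    if n_strict + n_partial > n_boundaries:
        raise ValueError("affected boundaries exceed planted boundaries")
    wt = make_layout(genome, chrom, n_boundaries, f_range, compartment_block, c, alpha, seed,
                     min_spacing=min_spacing)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    ids = rng.permutation(n_boundaries)
    affected = {int(i): STRICT for i in ids[:n_strict]}
    affected.update({int(i): PARTIAL for i in ids[n_strict:n_strict + n_partial]})
    mut = derive_mutant_layout(wt, affected, gamma)
    return GroundTruth(genome, chrom, wt, mut, affected, gamma)


@dataclass(frozen=True)
class ChipCondition:
    """One ChIP condition: replicate count, background window mean, peak fold,
    and optional per-replicate library-size factors."""

    name: str
    n_replicates: int = 2
    background_mean: float = 20.0
    fold: float = 8.0
    lib_factors: tuple[float, ...] | None = None


def simulate_chip_window_counts(
    peak_windows: np.ndarray,
    n_windows: int,
    conditions: list[ChipCondition],
    dispersion: float = 0.05,
    seed: int = 0,
    fold_profiles: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Negative-binomial window counts for 2-4 conditions.

    ``peak_windows`` are window indices whose expected count is
    ``background_mean * fold`` for each condition (fold may be 1);
    all other windows sit at background. Counts are gamma-Poisson with
    ``var = mu + dispersion * mu**2``. Columns are ``<condition>_rep<k>``;
    replicate streams are spawned deterministically from ``seed``.

    ``fold_profiles`` optionally supplies a full per-window fold vector per
    condition name (overriding ``peak_windows``/``fold``) for scenarios where
    different peaks have different condition-wise enrichment.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if not 2 <= len(conditions) <= 4:
        raise ValueError("between 2 and 4 conditions required")
    peak_windows = np.asarray(peak_windows, dtype=int)
    if peak_windows.size and (peak_windows.min() < 0 or peak_windows.max() >= n_windows):
        raise ValueError("peak windows outside the window grid")
    cols: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(sum(c.n_replicates for c in conditions)))
    shape = 1.0 / dispersion
    for cond in conditions:
        mu = np.full(n_windows, float(cond.background_mean))
        if fold_profiles is not None and cond.name in fold_profiles:
            profile = np.asarray(fold_profiles[cond.name], dtype=float)
            if profile.size != n_windows:
                raise ValueError(f"{cond.name}: fold profile length != n_windows")
            mu *= profile
        else:
            mu[peak_windows] *= cond.fold
        lib = cond.lib_factors or (1.0,) * cond.n_replicates
        if len(lib) != cond.n_replicates:
            raise ValueError(f"{cond.name}: one library factor per replicate required")
        for rep, factor in enumerate(lib, start=1):
            rng = np.random.default_rng(next(streams))
            lam = rng.gamma(shape, (mu * factor) / shape)
            cols[f"{cond.name}_rep{rep}"] = rng.poisson(lam)
    return pd.DataFrame(cols)


def make_peaks_at_boundaries(
    truth: GroundTruth, boundary_bins: np.ndarray, width: int = 400, seed: int = 0
) -> pd.DataFrame:
    """Peak intervals centered on the given boundary bins (BED-like frame)."""
    res = truth.genome.resolution
    centers = (np.asarray(boundary_bins) + 0.5) * res
    start = np.maximum(0, centers - width // 2).astype(int)
    return pd.DataFrame(
        {
            "chrom": truth.chrom,
            "start": start,
            "end": start + width,
            "name": [f"peak_{k}" for k in range(len(start))],
        }
    )


def simulate_gene_table(
    genome: GenomeSpec,
    chrom: str,
    n_genes: int,
    de_fraction: float = 0.03,
    near_boundary_bias: bool = False,
    boundary_positions: np.ndarray | None = None,
    seed: int = 0,
    bias_sd: float = 2000.0,
    compartment_sigma: np.ndarray | None = None,
    a_density_ratio: float = 2.0,
) -> pd.DataFrame:
    """Gene table with TSS, strand, log-scale expression, DE flag/log2FC/padj.

    The DE flag is consistent with the thresholds the differential-expression
    consumers assume (padj < 0.05 and |fold change| > 1.5). With
    ``near_boundary_bias`` the DE TSSs are scattered (sd ``bias_sd`` bp)
    around the supplied boundary positions instead of uniformly. When a
    per-bin ``compartment_sigma`` is supplied, non-DE TSSs are placed with
    ``a_density_ratio`` : 1 density in active (+1) versus inactive (-1)
    blocks, emulating the gene-density asymmetry that lets expressed-TSS
    density fix the compartment eigenvector's sign.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    length = genome.chromosomes[chrom]
    n_de = int(round(de_fraction * n_genes))
    de = np.zeros(n_genes, dtype=bool)
    de[:n_de] = True
    if compartment_sigma is not None:
        res = genome.resolution
        weights = np.where(np.asarray(compartment_sigma) > 0, a_density_ratio, 1.0)
        bins = rng.choice(weights.size, size=n_genes, p=weights / weights.sum())
        tss = bins * res + rng.integers(0, res, size=n_genes)
        tss = np.minimum(tss, length - 1)
    else:
        tss = rng.integers(0, length, size=n_genes)
    if near_boundary_bias and n_de:
        if boundary_positions is None or len(boundary_positions) == 0:
            raise ValueError("near_boundary_bias requires boundary positions")
        anchors = rng.choice(np.asarray(boundary_positions, dtype=float), size=n_de)
        biased = anchors + rng.normal(0, bias_sd, size=n_de)
        tss[:n_de] = np.clip(biased, 0, length - 1).astype(int)
    strand = rng.choice(["+", "-"], size=n_genes)
    expr = rng.normal(4.0, 2.0, size=n_genes)
    l2fc = rng.normal(0, 0.2, size=n_genes)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    l2fc[:n_de] = sign * rng.uniform(np.log2(1.5) + 0.2, 3.0, size=n_de)
    padj = rng.uniform(0.05, 1.0, size=n_genes)
    padj[:n_de] = rng.uniform(1e-8, 0.049, size=n_de)
    table = pd.DataFrame(
        {
            "gene_id": [f"gene_{k}" for k in range(n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "expression": expr,
            "de": de,
            "log2fc": l2fc,
            "padj": padj,
        }
    )
    return table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
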
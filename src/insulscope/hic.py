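"""Contact-matrix data model and primitives.

Implements the per-chromosome binned Hi-C workflow: binning contact pairs,
low-coverage bin filtering, ICE (iterative correction) balancing,
observed-over-expected transformation, exact-total downsampling, and the
distance-restricted replicate Pearson correlation.

A :class:`ContactMatrix` moves through the states ``raw -> normalized -> oe``;
operations check the state they require. Masked (invalid) bins carry NaN in
normalized and O/E matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .genome import GenomeSpec

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"
OE = "oe"


class IceConvergenceError(RuntimeError):
    """ICE balancing failed to reach the requested coverage CV."""

    def __init__(self, message: str, last_cv: float):
        super().__init__(message)
        self.last_cv = last_cv


@dataclass
class ContactMatrix:
    """Symmetric binned contact map for one chromosome.

    Attributes
    ----------
    chrom : str
        Chromosome identifier.
    resolution : int
        Bin width in bp.
    matrix : ndarray of shape (n, n)
        Symmetric grid of counts (raw) or reals (normalized / O/E).
    mask : boolean ndarray of shape (n,)
        True for valid bins. Invalid bins carry NaN once normalized.
    state : str
        One of ``raw``, ``normalized``, ``oe``.
    """

    chrom: str
    resolution: int
    matrix: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    state: str = RAW

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length must match matrix size")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def total(self) -> float:
        """Total contacts counted once per unordered bin pair (incl. diagonal)."""
        m = np.nan_to_num(self.matrix)
        return float(np.triu(m).sum())

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise ValueError(f"operation requires state in {states}, matrix is {self.state!r}")


def bin_pairs(
    pairs: Iterable[tuple[str, int, str, int]],
    genome: GenomeSpec,
    resolution: int | None = None,
) -> dict[str, ContactMatrix]:
    """Bin intra-chromosomal contact pairs into per-chromosome raw matrices.

    Each pair increments one cell and its mirror; inter-chromosomal pairs are
    dropped (per-chromosome matrices only). Malformed entries are skipped and
    counted in the log. Unknown chromosomes raise.
    """
    res = resolution or genome.resolution
    if res != genome.resolution:
        genome = GenomeSpec(genome.chromosomes, res)
    mats = {c: np.zeros((genome.n_bins(c),) * 2) for c in genome.names}
    skipped = 0
    for entry in pairs:
        try:
            c1, p1, c2, p2 = entry
            p1, p2 = int(p1), int(p2)
        except (TypeError, ValueError):
            skipped += 1
            continue
        if c1 not in mats or c2 not in mats:
            raise KeyError(f"chromosome {c1 if c1 not in mats else c2!r} not in genome")
        if c1 != c2:
            continue
        if not (0 <= p1 < genome.chromosomes[c1] and 0 <= p2 < genome.chromosomes[c2]):
            skipped += 1
            continue
        i, j = p1 // res, p2 // res
        mats[c1][i, j] += 1
        if i != j:
            mats[c1][j, i] += 1
    if skipped:
        logger.warning("bin_pairs: skipped %d malformed pairs", skipped)
    return {c: ContactMatrix(c, res, m) for c, m in mats.items()}


def pairs_from_tsv(path) -> Iterator[tuple[str, int, str, int]]:
    """Yield (chrom1, pos1, chrom2, pos2) from a 4-column TSV stream."""
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4 or line.startswith("#"):
                continue
            yield parts[0], int(parts[1]), parts[2], int(parts[3])


def filter_low_coverage(matrix: ContactMatrix, frac: float = 0.02) -> np.ndarray:
    """Valid-bin mask excluding zero-total bins and the lowest-coverage tail.

    All bins with zero total contacts are masked. Among the remaining bins,
    the ``floor(frac * n_nonzero)`` bins with the smallest totals are
    additionally masked; ties are broken deterministically by bin index.
    """
    matrix.require_state(RAW)
    totals = np.nan_to_num(matrix.matrix).sum(axis=1)
    mask = totals > 0
    n_nonzero = int(mask.sum())
    if n_nonzero == 0:
        logger.warning("filter_low_coverage: all bins have zero coverage")
        return mask
    k = int(np.floor(frac * n_nonzero))
    if k > 0:
        nonzero_idx = np.flatnonzero(mask)
        order = np.lexsort((nonzero_idx, totals[nonzero_idx]))
        mask[nonzero_idx[order[:k]]] = False
    return mask


def ice_normalize(
    matrix: ContactMatrix,
    mask: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> tuple[ContactMatrix, np.ndarray]:
    """Balance a raw matrix by symmetric iterative correction (ICE).

    Finds the diagonal bias ``b`` making per-bin coverage equal over valid
    bins (coefficient of variation <= ``tol``); the equal-coverage equations
    are solved in log space with a Newton-Krylov iteration, falling back to
    the classic fixed-point loop (divide by coverage relative to the
    valid-bin mean) if it does not converge. The output is rescaled so the
    valid-cell total equals the raw valid-cell total, fixing the free global
    scale of ``D M D``. Returns the normalized matrix (invalid rows/columns
    NaN) and ``b`` with ``out[i, j] = raw[i, j] / (b[i] * b[j])`` on valid
    bins (NaN at invalid bins).
    """
    matrix.require_state(RAW)
    if mask is None:
        mask = matrix.mask.copy()
    mask = np.asarray(mask, dtype=bool)
    n = matrix.n_bins
    work = np.nan_to_num(matrix.matrix).copy()
    work[~mask, :] = 0.0
    work[:, ~mask] = 0.0
    if mask.sum() == 0:
        raise ValueError("no valid bins to balance")
    sub = work[np.ix_(mask, mask)]
    if np.any(sub.sum(axis=1) == 0):
        raise ValueError("a valid bin has zero total coverage; filter it first")

    def coverage(inv_b_sub: np.ndarray) -> np.ndarray:
        return (sub @ inv_b_sub) * inv_b_sub

    inv_b_sub = np.ones(int(mask.sum()))
    cv = np.inf
    try:
        from scipy.optimize import newton_krylov

        def resid(x: np.ndarray) -> np.ndarray:
            cov = coverage(np.exp(x))
            return cov / cov.mean() - 1.0

        # solve well past the CV tolerance: the bias is cheap to refine and a
        # loosely balanced D·M·D differs cell-wise from the exact fixed point
        x = newton_krylov(
            resid, np.zeros(inv_b_sub.size), f_tol=max(tol * 1e-4, 1e-13), maxiter=100
        )
        inv_b_sub = np.exp(x)
        cov = coverage(inv_b_sub)
        cv = float(cov.std() / cov.mean())
    except Exception:
        cv = np.inf
    if cv > tol:  # fixed-point fallback
        inv_b_sub = np.ones(inv_b_sub.size)
        for _ in range(max_iter):
            cov = coverage(inv_b_sub)
            mean_cov = cov.mean()
            cv = float(cov.std() / mean_cov)
            if cv <= tol:
                break
            inv_b_sub /= cov / mean_cov
        else:
            raise IceConvergenceError(
                f"ICE did not reach CV <= {tol} in {max_iter} iterations (CV={cv:.3e})", cv
            )
    out_sub = sub * np.outer(inv_b_sub, inv_b_sub)
    raw_total, out_total = sub.sum(), out_sub.sum()
    scale = raw_total / out_total if out_total > 0 else 1.0
    out_sub *= scale
    inv_b_sub *= np.sqrt(scale)
    out = np.full((n, n), np.nan)
    out[np.ix_(mask, mask)] = out_sub
    bias_out = np.full(n, np.nan)
    bias_out[mask] = 1.0 / inv_b_sub
    return (
        ContactMatrix(matrix.chrom, matrix.resolution, out, mask, NORMALIZED),
        bias_out,
    )


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean normalized contact value at each genomic distance over valid pairs."""
    n = matrix.n_bins
    exp = np.full(n, np.nan)
    m = matrix.matrix
    for d in range(n):
        diag = np.diagonal(m, offset=d)
        vals = diag[np.isfinite(diag)]
        if vals.size:
            exp[d] = vals.mean()
    return exp


def observed_over_expected(matrix: ContactMatrix) -> ContactMatrix:
    """Divide a normalized matrix by its per-distance expected profile.

    At every distance with at least one valid pair, the mean of the output
    over valid pairs is exactly 1. Distances with no valid pairs, or expected
    value 0, are NaN.
    """
    matrix.require_state(NORMALIZED)
    n = matrix.n_bins
    exp = expected_by_distance(matrix)
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = exp[idx]
        out = np.where(denom != 0, matrix.matrix / denom, np.nan)
    return ContactMatrix(matrix.chrom, matrix.resolution, out, matrix.mask.copy(), OE)


def downsample_contacts(matrix: ContactMatrix, n: int, seed: int) -> ContactMatrix:
    """Draw exactly ``n`` contacts without replacement from a raw matrix.

    A multivariate-hypergeometric draw over the upper-triangle cells
    (diagonal included), mirrored back to a symmetric matrix. The output
    total is exactly ``n``.
    """
    matrix.require_state(RAW)
    total = matrix.total()
    if n > total:
        raise ValueError(f"cannot downsample to {n} > total {total:.0f}")
    rng = np.random.default_rng(seed)
    nb = matrix.n_bins
    iu = np.triu_indices(nb)
    counts = np.nan_to_num(matrix.matrix)[iu].astype(np.int64)
    drawn = rng.multivariate_hypergeometric(counts, int(n), method="marginals")
    out = np.zeros((nb, nb))
    out[iu] = drawn
    out = out + out.T - np.diag(np.diag(out))
    return ContactMatrix(matrix.chrom, matrix.resolution, out, matrix.mask.copy(), RAW)


def replicate_correlation(
    m1: ContactMatrix, m2: ContactMatrix, max_dist: float = 1_000_000
) -> float:
    """Pearson r between two normalized matrices at genomic distance < max_dist.

    Cells are the upper-triangle bin pairs (diagonal included) valid in both
    matrices, restricted to distance below ``max_dist`` bp.
    """
    m1.require_state(NORMALIZED)
    m2.require_state(NORMALIZED)
    if m1.n_bins != m2.n_bins or m1.resolution != m2.resolution:
        raise ValueError("matrices must share bin grid")
    mask = m1.mask & m2.mask
    n = m1.n_bins
    i, j = np.triu_indices(n)
    keep = (
        mask[i]
        & mask[j]
        & ((j - i) * m1.resolution < max_dist)
        & np.isfinite(m1.matrix[i, j])
        & np.isfinite(m2.matrix[i, j])
    )
    v1, v2 = m1.matrix[i[keep], j[keep]], m2.matrix[i[keep], j[keep]]
    if v1.size < 2:
        raise ValueError("fewer than 2 usable cells for correlation")
    return float(np.corrcoef(v1, v2)[0, 1])
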
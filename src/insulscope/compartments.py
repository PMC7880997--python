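"""A/B compartment calling from the observed-over-expected correlation matrix.

Per chromosome arm, the normalized contact matrix (invalid bins and any
configured excluded regions dropped) is transformed to observed-over-expected,
the Pearson correlation matrix of its columns is computed, and the leading
eigenvector is extracted. The eigenvector is mean-centered and its global
sign fixed so it correlates positively with the density of expressed-gene
TSSs per bin — positive values are compartment A (active), negative B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic import NORMALIZED, ContactMatrix, observed_over_expected

UNASSIGNED = "unassigned"


@dataclass
class CompartmentTrack:
    """Mean-centered, sign-corrected leading eigenvector with A/B labels."""

    chrom: str
    resolution: int
    eigenvector: np.ndarray  # NaN at excluded/invalid bins
    valid: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        lab = np.full(self.eigenvector.size, UNASSIGNED, dtype=object)
        lab[self.valid & (self.eigenvector > 0)] = "A"
        lab[self.valid & (self.eigenvector <= 0)] = "B"
        return lab


def tss_density(
    genes: pd.DataFrame, chrom: str, n_bins: int, resolution: int,
    expression_min: float = 0.0,
) -> np.ndarray:
    """Expressed-gene TSS count per bin (expression > ``expression_min``)."""
    sub = genes[(genes["chrom"] == chrom) & (genes["expression"] > expression_min)]
    bins = (sub["tss"].to_numpy() // resolution).astype(int)
    bins = bins[(bins >= 0) & (bins < n_bins)]
    return np.bincount(bins, minlength=n_bins).astype(float)


def exclusion_mask_from_bed(
    regions: pd.DataFrame, chrom: str, n_bins: int, resolution: int
) -> np.ndarray:
    """Per-bin exclusion mask from BED-style regions (e.g. pericentromeric
    spans); a bin is excluded when any part of it overlaps a region."""
    mask = np.zeros(n_bins, dtype=bool)
    for _, row in regions[regions["chrom"] == chrom].iterrows():
        lo = max(0, int(row["start"]) // resolution)
        hi = min(n_bins, -(-int(row["end"]) // resolution))
        mask[lo:hi] = True
    return mask


def compartment_eigenvector(
    matrix: ContactMatrix,
    tss_per_bin: np.ndarray,
    exclude: np.ndarray | None = None,
) -> CompartmentTrack:
    """Sign-corrected leading eigenvector of the O/E correlation matrix.

    ``exclude`` is an optional boolean mask of bins to drop in addition to
    the matrix's own invalid bins (e.g. pericentromeric spans supplied as a
    BED-derived mask). The output is mean-centered over valid bins and
    sign-flipped so its Pearson correlation with ``tss_per_bin`` is >= 0.
    """
    matrix.require_state(NORMALIZED)
    n = matrix.n_bins
    valid = matrix.mask.copy()
    if exclude is not None:
        valid &= ~np.asarray(exclude, dtype=bool)
    oe = observed_over_expected(matrix).matrix
    sub = oe[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, 1.0)  # distances w/o valid pairs: neutral
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix (constant rows)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = eigvecs[:, -1]
    ev = ev - ev.mean()
    tss_valid = np.asarray(tss_per_bin, dtype=float)[valid]
    if tss_valid.std() > 0 and ev.std() > 0:
        r = np.corrcoef(ev, tss_valid)[0, 1]
        if r < 0:
            ev = -ev
    full = np.full(n, np.nan)
    full[valid] = ev
    return CompartmentTrack(matrix.chrom, matrix.resolution, full, valid)


def assign_ab_and_switches(
    track_wt: CompartmentTrack,
    track_mut: CompartmentTrack,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene A/B labels in both genotypes and compartment-switch flags.

    A gene's compartment is the label of its TSS bin. Genes whose TSS bin is
    invalid in either genotype are 'unassigned' and excluded from the switch
    denominator (switch flag NA).
    """
    if track_wt.eigenvector.size != track_mut.eigenvector.size:
        raise ValueError("compartment tracks must share the bin grid")
    n, res = track_wt.eigenvector.size, track_wt.resolution
    lab_wt, lab_mut = track_wt.labels, track_mut.labels
    rows = []
    for _, g in genes.iterrows():
        b = int(g["tss"]) // res
        if not 0 <= b < n:
            raise ValueError(f"TSS {g['tss']} outside the binned chromosome")
        lw, lm = lab_wt[b], lab_mut[b]
        assigned = lw != UNASSIGNED and lm != UNASSIGNED
        rows.append(
            {
                "gene_id": g["gene_id"],
                "compartment_wt": lw,
                "compartment_mut": lm,
                "switch": (lw != lm) if assigned else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def switch_fraction(assignments: pd.DataFrame, subset: pd.Series | None = None) -> float:
    """Fraction of (optionally subset) assignable genes that switch compartment."""
    df = assignments if subset is None else assignments[subset.to_numpy()]
    flags = df["switch"].dropna()
    if flags.empty:
        return float("nan")
    return float(flags.astype(bool).mean())
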
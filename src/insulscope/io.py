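"""Text-format readers and writers.

Contact matrices travel as sparse triplet text (``bin1_id<TAB>bin2_id<TAB>
count``, upper triangle) with a sidecar bin table (``chrom start end
bin_id``); per-bin tracks as bedGraph; interval sets as BED (0-based,
half-open).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .hic import ContactMatrix


def write_bin_table(path, genome: GenomeSpec, chrom: str) -> None:
    res = genome.resolution
    n = genome.n_bins(chrom)
    length = genome.chromosomes[chrom]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * res,
            "end": np.minimum((np.arange(n) + 1) * res, length),
            "bin_id": np.arange(n),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_sparse(path, matrix: ContactMatrix) -> None:
    """Upper-triangle nonzero cells as bin1_id, bin2_id, count triplets."""
    m = np.nan_to_num(matrix.matrix)
    i, j = np.nonzero(np.triu(m))
    pd.DataFrame({"bin1_id": i, "bin2_id": j, "count": m[i, j]}).to_csv(
        path, sep="\t", index=False
    )


def read_sparse(path, n_bins: int, chrom: str, resolution: int) -> ContactMatrix:
    df = pd.read_csv(path, sep="\t")
    m = np.zeros((n_bins, n_bins))
    i = df["bin1_id"].to_numpy(int)
    j = df["bin2_id"].to_numpy(int)
    m[i, j] = df["count"].to_numpy(float)
    m[j, i] = df["count"].to_numpy(float)
    return ContactMatrix(chrom, resolution, m)


def write_dense_tsv(path, matrix: ContactMatrix) -> None:
    pd.DataFrame(matrix.matrix).to_csv(path, sep="\t", index=False, header=False)


def read_dense_tsv(path, chrom: str, resolution: int) -> ContactMatrix:
    m = pd.read_csv(path, sep="\t", header=None).to_numpy(float)
    return ContactMatrix(chrom, resolution, m)


def write_bedgraph(path, chrom: str, values: np.ndarray, resolution: int) -> None:
    """Per-bin track as bedGraph; NaN bins are skipped."""
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    starts = np.arange(values.size)[keep] * resolution
    pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + resolution, "value": values[keep]}
    ).to_csv(path, sep="\t", index=False, header=False)


def write_bed(path, frame: pd.DataFrame, columns: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (columns or [])
    frame[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (extra_columns or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [f"col{k}" for k in range(len(names), df.shape[1])]
    return df


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
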
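"""Assembly summary statistics.

N50 and a coverage-based haploid genome-size estimate: given the total
number of sequenced bases and the median sequencing depth of long
contigs, the true genome size is approximately
``total_read_bases / median_coverage`` — depth in excess of the
assembly-implied depth indicates assembly redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["AssemblyStats", "n50", "estimate_genome_size", "assembly_stats"]


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_len: int
    n50: int
    long_contig_median_cov: float | None = None
    est_genome_size: float | None = None


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that contigs of length >= L hold at least half the assembly.

    Ties at exactly 50% count as reaching half (">= half").
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("n50 of an empty contig set is undefined")
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    arr = np.sort(arr)[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, half, side="left"))
    return int(arr[idx])


def estimate_genome_size(
    total_read_bases: float,
    lengths: Sequence[int],
    coverages: Sequence[float],
    min_len: int = 10_000,
) -> tuple[float, float]:
    """Haploid genome-size estimate from long-contig median coverage.

    Parameters
    ----------
    total_read_bases : total sequenced bases (numerator of the estimate).
    lengths, coverages : per-contig length (bases) and median fold coverage.
    min_len : contigs at least this long enter the median (default 10 kb);
        short contigs are depth-noisy and repeat-enriched.

    Returns
    -------
    (estimated genome size in bases, median coverage used)
    """
    if total_read_bases <= 0:
        raise ValueError("total_read_bases must be positive")
    lengths = np.asarray(lengths, dtype=np.int64)
    coverages = np.asarray(coverages, dtype=float)
    if lengths.shape != coverages.shape:
        raise ValueError("lengths and coverages must align")
    mask = lengths >= min_len
    if not mask.any():
        raise ValueError(f"no contigs of length >= {min_len} with coverage")
    med = float(np.median(coverages[mask]))
    if med <= 0:
        raise ValueError("median coverage must be positive")
    return total_read_bases / med, med


def assembly_stats(
    lengths: Sequence[int],
    coverages: Sequence[float] | None = None,
    total_read_bases: float | None = None,
    min_len: int = 10_000,
) -> AssemblyStats:
    """Bundle contig count, total size, N50 and (optionally) the genome-size estimate."""
    arr = np.asarray(lengths, dtype=np.int64)
    est = cov = None
    if coverages is not None and total_read_bases is not None:
        est, cov = estimate_genome_size(total_read_bases, arr, coverages, min_len)
    return AssemblyStats(
        n_contigs=int(arr.size),
        total_len=int(arr.sum()),
        n50=n50(arr),
        long_contig_median_cov=cov,
        est_genome_size=est,
    )


def lengths_from_fasta(path) -> list[int]:
    from Bio import SeqIO

    return [len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def read_length_table(path) -> pd.DataFrame:
    """Read a TSV with columns ``contig``, ``length`` and optionally ``coverage``."""
    df = pd.read_csv(path, sep="\t")
    if "length" not in df.columns:
        raise ValueError(f"{path}: expected a 'length' column")
    return df
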
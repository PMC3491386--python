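"""Digital differential gene expression from per-gene library read counts.

Expression differences between two cDNA read libraries (here iron-limited
Fe(-) vs iron-replete Fe(+)) are assessed per gene from its read counts
``x_i`` in libraries of known total sizes ``N_i`` with the Stekel
log-likelihood ratio statistic

    R = sum_i x_i ln(x_i / xhat_i),   xhat_i = N_i * phat,
    phat = sum_i x_i / sum_i N_i,

with the convention 0 ln 0 = 0. R is zero when every library shows the
same proportion and grows with heterogeneity; 2R is asymptotically
chi-square with (m - 1) degrees of freedom under the null of a common
proportion.

Significance can be calibrated either by that chi-square approximation
or (default) by a parametric bootstrap that redraws each library's count
as Binomial(N_i, phat) — preferable for the small counts typical of EST
libraries, where the chi-square tail is anticonservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LibrarySpec",
    "AggregateReadSummary",
    "stekel_r",
    "stekel_r_table",
    "calibrate_significance",
    "run_de",
    "aggregate_compartment",
]


@dataclass(frozen=True)
class LibrarySpec:
    """A cDNA read library: a label and its total read count N."""

    name: str
    n_reads: int

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError(f"library {self.name!r}: N must be positive")


@dataclass(frozen=True)
class AggregateReadSummary:
    """Per-library read totals over one compartment and their Fe(-)/Fe(+) ratio."""

    compartment: str
    per_library_totals: dict[str, int]
    ratio_fe_minus_over_fe_plus: float  # NaN when the denominator is empty


def _validate_counts(x: np.ndarray, n: np.ndarray) -> None:
    if x.shape[-1] != n.shape[-1]:
        raise ValueError("counts must align with libraries")
    if x.shape[-1] < 2:
        raise ValueError("at least two libraries are required")
    if (x < 0).any():
        raise ValueError("read counts must be non-negative")
    if (x > n).any():
        raise ValueError("a gene cannot exceed its library size")


def stekel_r(counts: Sequence[float], libs: Sequence[LibrarySpec]) -> float:
    """Log-likelihood ratio statistic R for one gene across m libraries."""
    x = np.asarray(counts, dtype=float)
    n = np.asarray([lib.n_reads for lib in libs], dtype=float)
    _validate_counts(x, n)
    if x.sum() == 0:
        warnings.warn("all-zero counts: R = 0", stacklevel=2)
        return 0.0
    return float(_r_stat(x[None, :], n)[0])


def _r_stat(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized R over the last axis; x has shape (..., m)."""
    phat = x.sum(axis=-1, keepdims=True) / n.sum()
    expected = n * phat
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / expected), 0.0)
    # R is non-negative by Gibbs' inequality; clip float residue at zero
    return np.maximum(terms.sum(axis=-1), 0.0)


def stekel_r_table(counts: np.ndarray, libs: Sequence[LibrarySpec]) -> np.ndarray:
    """Per-gene R for a (genes x libraries) count matrix."""
    x = np.asarray(counts, dtype=float)
    n = np.asarray([lib.n_reads for lib in libs], dtype=float)
    _validate_counts(x, n)
    return _r_stat(x, n)


def calibrate_significance(
    r: float,
    counts: Sequence[float],
    libs: Sequence[LibrarySpec],
    method: Literal["chi2", "parametric_bootstrap"] = "parametric_bootstrap",
    n_boot: int = 999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """p-value for one gene's R statistic.

    ``chi2``: upper tail of chi-square with (m - 1) df at 2R.
    ``parametric_bootstrap``: counts are redrawn per library as
    Binomial(N_i, phat); p = (1 + #{R* >= R}) / (n_boot + 1).
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray([lib.n_reads for lib in libs], dtype=float)
    _validate_counts(x, n)
    if method == "chi2":
        return float(stats.chi2.sf(2.0 * r, df=len(libs) - 1))
    if method != "parametric_bootstrap":
        raise ValueError(f"unknown calibration method: {method!r}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phat = x.sum() / n.sum()
    x_star = rng.binomial(n.astype(np.int64), phat, size=(n_boot, len(libs)))
    r_star = _r_stat(x_star.astype(float), n)
    return float((1 + np.count_nonzero(r_star >= r)) / (n_boot + 1))


def run_de(
    table: pd.DataFrame,
    libs: Sequence[LibrarySpec],
    alpha: float = 0.05,
    method: Literal["chi2", "parametric_bootstrap"] = "parametric_bootstrap",
    n_boot: int = 999,
    seed: int | None = None,
    mt_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-gene differential expression over a count table.

    Parameters
    ----------
    table : DataFrame with ``gene_id``, one count column per library
        named after ``lib.name``, and optionally ``compartment``.
    libs : library specifications; the first library is taken as Fe(-)
        and the second as Fe(+) for the direction call.
    alpha : significance level for the ``significant`` flag on adjusted p.
    method, n_boot, seed : null calibration, see :func:`calibrate_significance`.
    mt_method : multiple-testing correction passed to statsmodels
        (default Benjamini-Hochberg).

    Returns
    -------
    DataFrame sorted by R descending with columns ``gene_id``, per-library
    proportions, ``r``, ``p_raw``, ``p_adj``, ``direction``
    (up_at_low_iron / down_at_low_iron / flat) and ``significant``.
    """
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    names = [lib.name for lib in libs]
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise ValueError(f"count columns missing from table: {missing}")
    x = table[names].to_numpy(dtype=float)
    n = np.asarray([lib.n_reads for lib in libs], dtype=float)
    _validate_counts(x, n)

    r = _r_stat(x, n)
    if method == "chi2":
        p_raw = stats.chi2.sf(2.0 * r, df=len(libs) - 1)
    elif method == "parametric_bootstrap":
        if n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        rng = np.random.default_rng(seed)
        phat = x.sum(axis=1) / n.sum()
        # (genes, n_boot, m) redraw; chunked to bound memory on large tables
        n_genes = x.shape[0]
        p_raw = np.empty(n_genes)
        chunk = max(1, int(5e6 // max(1, n_boot * len(libs))))
        for lo in range(0, n_genes, chunk):
            hi = min(lo + chunk, n_genes)
            draws = rng.binomial(
                n.astype(np.int64)[None, None, :],
                phat[lo:hi, None, None],
                size=(hi - lo, n_boot, len(libs)),
            )
            r_star = _r_stat(draws.astype(float), n)
            p_raw[lo:hi] = (1 + np.count_nonzero(r_star >= r[lo:hi, None], axis=1)) / (
                n_boot + 1
            )
    else:
        raise ValueError(f"unknown calibration method: {method!r}")

    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method=mt_method)[:4]
    props = x / n
    diff = props[:, 0] - props[:, 1]
    direction = np.where(diff > 0, "up_at_low_iron", np.where(diff < 0, "down_at_low_iron", "flat"))

    out = pd.DataFrame({"gene_id": table["gene_id"].to_numpy()})
    for j, name in enumerate(names):
        out[f"prop_{name}"] = props[:, j]
    out["r"] = r
    out["p_raw"] = p_raw
    out["p_adj"] = p_adj
    out["direction"] = direction
    out["significant"] = reject
    if "compartment" in table.columns:
        out.insert(1, "compartment", table["compartment"].to_numpy())
    return out.sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)


def aggregate_compartment(
    table: pd.DataFrame,
    libs: Sequence[LibrarySpec],
    compartment: str,
) -> AggregateReadSummary:
    """Total reads per library over one compartment and their Fe(-)/Fe(+) ratio.

    The ratio is first library over second (Fe(-)/Fe(+) in the standard
    orientation); it is NaN when the compartment is empty or the
    denominator is zero.
    """
    if "compartment" not in table.columns:
        raise ValueError("count table has no 'compartment' column")
    names = [lib.name for lib in libs]
    sub = table[table["compartment"] == compartment]
    totals = {name: int(sub[name].sum()) for name in names}
    if len(sub) == 0:
        warnings.warn(f"compartment {compartment!r} is empty", stacklevel=2)
        ratio = float("nan")
    elif totals[names[1]] == 0:
        warnings.warn(
            f"compartment {compartment!r}: zero reads in {names[1]}; ratio undefined",
            stacklevel=2,
        )
        ratio = float("nan")
    else:
        ratio = totals[names[0]] / totals[names[1]]
    return AggregateReadSummary(
        compartment=compartment,
        per_library_totals=totals,
        ratio_fe_minus_over_fe_plus=ratio,
    )
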
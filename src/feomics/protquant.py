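"""14N/15N metabolic-labeling proteomics quantification.

Iron-replete and iron-limited cells are grown on different nitrogen
isotopes, mixed at equal total protein, fractionated by SDS-PAGE and
measured by LC-MS/MS. This module takes match-level records (one row
per peptide-spectrum match with light/heavy precursor intensities) to
per-protein-group Fe(-)/Fe(+) ratios through the filter cascade

    hit distinctiveness  ->  target-decoy FDR  ->  precursor ppm

followed by parsimony protein grouping, per-(peptide, band, charge)
ratio formation ("PBC" ratios, the atomic unit of quantification) and
median/interquartile aggregation per protein group. The equal-protein
ratios can finally be rescaled to a per-cell basis with the measured
Fe(-)/Fe(+) total-protein biomass ratio.

PSM tables are plain pandas DataFrames with columns
``spectrum_id, peptide, protein_ids, evalue, evalue_second_best,
ppm_dev, band, charge, is_decoy, intensity_light, intensity_heavy``
(``protein_ids`` is a ';'-joined label list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinGroup",
    "ProteinGroupRatio",
    "filter_distinctiveness",
    "filter_fdr",
    "filter_ppm",
    "apply_filter_cascade",
    "infer_protein_groups",
    "pbc_ratios",
    "protein_ratio",
    "protein_group_ratios",
    "scale_to_cellular_unit",
]

PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "protein_ids",
    "evalue",
    "evalue_second_best",
    "ppm_dev",
    "band",
    "charge",
    "is_decoy",
    "intensity_light",
    "intensity_heavy",
]


def _check_psms(psms: pd.DataFrame, needed: set[str]) -> None:
    missing = needed - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")


def filter_distinctiveness(psms: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Keep matches whose best E-value beats the runner-up by >= `threshold`.

    The hit distinctiveness of a spectrum is the ratio of its second-best
    to its best candidate E-value; ambiguous spectra (ratio < threshold)
    are discarded. Records without a second-best candidate are retained.
    Records with non-positive E-values are rejected with a log entry.
    """
    if threshold <= 1:
        raise ValueError("distinctiveness threshold must exceed 1")
    _check_psms(psms, {"evalue", "evalue_second_best"})
    bad = psms["evalue"] <= 0
    if bad.any():
        logger.warning("dropping %d records with non-positive E-values", int(bad.sum()))
        psms = psms[~bad]
    second = psms["evalue_second_best"]
    keep = second.isna() | (second / psms["evalue"] >= threshold)
    return psms[keep].copy()


def filter_fdr(
    psms: pd.DataFrame, fdr_target: float = 0.01
) -> tuple[pd.DataFrame, float]:
    """Dynamic E-value threshold for a target-decoy estimated FDR.

    Selects the largest threshold ``t`` such that

        #decoys(E <= t) / #targets(E <= t)  <=  fdr_target,

    returns the surviving *target* records (decoys are removed from the
    output) together with ``t``. If no threshold achieves the target the
    output is empty with a warning and ``t`` is NaN.
    """
    if not 0 <= fdr_target < 1:
        raise ValueError("fdr_target must be in [0, 1)")
    _check_psms(psms, {"evalue", "is_decoy"})
    if (~psms["is_decoy"].astype(bool)).sum() == 0:
        raise ValueError("FDR filtering requires at least one target record")
    ev = psms["evalue"].to_numpy(dtype=float)
    decoy = psms["is_decoy"].to_numpy(dtype=bool)
    order = np.argsort(ev, kind="mergesort")
    ev_sorted = ev[order]
    decoy_sorted = decoy[order]
    cum_decoy = np.cumsum(decoy_sorted)
    cum_target = np.cumsum(~decoy_sorted)
    # candidate cut points: positions where the next E-value differs
    # (a threshold between ties is meaningless)
    is_last_of_value = np.r_[ev_sorted[1:] != ev_sorted[:-1], True]
    with np.errstate(divide="ignore", invalid="ignore"):
        est_fdr = np.where(cum_target > 0, cum_decoy / cum_target, np.inf)
    ok = is_last_of_value & (est_fdr <= fdr_target) & (cum_target > 0)
    if not ok.any():
        logger.warning(
            "no E-value threshold achieves FDR <= %g; returning empty table",
            fdr_target,
        )
        return psms.iloc[0:0].copy(), float("nan")
    t = float(ev_sorted[np.nonzero(ok)[0][-1]])
    out = psms[(~decoy) & (ev <= t)].copy()
    return out, t


def filter_ppm(psms: pd.DataFrame, max_ppm: float = 5.0) -> pd.DataFrame:
    """Discard matches with precursor mass deviation beyond `max_ppm`.

    The boundary is inclusive: |ppm_dev| <= max_ppm survives.
    """
    _check_psms(psms, {"ppm_dev"})
    return psms[psms["ppm_dev"].abs() <= max_ppm].copy()


def apply_filter_cascade(
    psms: pd.DataFrame,
    distinctiveness: float = 2.0,
    fdr_target: float = 0.01,
    max_ppm: float = 5.0,
) -> tuple[pd.DataFrame, float]:
    """Run the full filter chain in its fixed order.

    Order matters: distinctiveness first (spectrum-level ambiguity),
    then the decoy-based FDR threshold on the survivors, then the ppm
    filter. Returns the filtered targets and the E-value threshold.
    """
    step1 = filter_distinctiveness(psms, threshold=distinctiveness)
    step2, evalue_threshold = filter_fdr(step1, fdr_target=fdr_target)
    step3 = filter_ppm(step2, max_ppm=max_ppm)
    return step3, evalue_threshold


# ---------------------------------------------------------------------------
# protein inference and ratio aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinGroup:
    group_id: str
    member_proteins: frozenset[str]
    peptides: frozenset[str]
    unique_peptides: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ProteinGroupRatio:
    group_id: str
    member_proteins: frozenset[str]
    median_ratio: float
    q1: float
    q3: float
    n_pbc: int


def _protein_peptide_map(psms: pd.DataFrame) -> dict[str, frozenset[str]]:
    mapping: dict[str, set[str]] = {}
    for pep, prots in zip(psms["peptide"], psms["protein_ids"]):
        for prot in str(prots).split(";"):
            prot = prot.strip()
            if prot:
                mapping.setdefault(prot, set()).add(pep)
    return {p: frozenset(s) for p, s in mapping.items()}


def infer_protein_groups(psms: pd.DataFrame) -> list[ProteinGroup]:
    """Parsimony protein grouping from surviving peptide evidence.

    Proteins with identical peptide sets merge into one group; a protein
    whose peptide set is a strict subset of another's is absorbed into
    every group with a strict superset (it adds no evidence of its own).
    Group peptides shared with another group are excluded from the
    group's ``unique_peptides``.
    """
    _check_psms(psms, {"peptide", "protein_ids"})
    prot2pep = _protein_peptide_map(psms)
    distinct_sets = sorted(set(prot2pep.values()), key=lambda s: (-len(s), sorted(s)))
    maximal = [
        s
        for s in distinct_sets
        if not any(s < other for other in distinct_sets)
    ]
    groups: list[ProteinGroup] = []
    # peptide -> how many maximal sets contain it (for uniqueness marking)
    pep_multiplicity: dict[str, int] = {}
    for s in maximal:
        for pep in s:
            pep_multiplicity[pep] = pep_multiplicity.get(pep, 0) + 1
    for i, s in enumerate(maximal):
        members = frozenset(p for p, peps in prot2pep.items() if peps <= s)
        unique = frozenset(p for p in s if pep_multiplicity[p] == 1)
        anchor = sorted(p for p, peps in prot2pep.items() if peps == s)[0]
        groups.append(
            ProteinGroup(
                group_id=f"grp_{anchor}",
                member_proteins=members,
                peptides=s,
                unique_peptides=unique,
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def pbc_ratios(
    psms: pd.DataFrame,
    heavy_condition: Literal["fe_plus", "fe_minus"] = "fe_plus",
) -> pd.DataFrame:
    """One Fe(-)/Fe(+) ratio per (peptide, SDS-PAGE band, charge) combination.

    Spectra sharing a PBC key are pooled (mean light / mean heavy) before
    the ratio is formed, so duplicate spectra within a PBC collapse. The
    labeling orientation defaults to heavy = Fe(+) (15N fed to the
    iron-replete culture), giving ratio = light/heavy; the inverse
    orientation flips it.

    PBCs with zero pooled heavy intensity are dropped with a log entry.
    """
    _check_psms(psms, {"peptide", "band", "charge", "intensity_light", "intensity_heavy"})
    if (psms[["intensity_light", "intensity_heavy"]] < 0).any().any():
        raise ValueError("intensities must be non-negative")
    pooled = (
        psms.groupby(["peptide", "band", "charge"], sort=True)
        .agg(
            light=("intensity_light", "mean"),
            heavy=("intensity_heavy", "mean"),
            n_spectra=("peptide", "size"),
        )
        .reset_index()
    )
    zero = pooled["heavy"] == 0
    if zero.any():
        logger.warning("dropping %d PBCs with zero heavy intensity", int(zero.sum()))
        pooled = pooled[~zero]
    raw = pooled["light"] / pooled["heavy"]
    pooled["ratio"] = raw if heavy_condition == "fe_plus" else 1.0 / raw
    return pooled[["peptide", "band", "charge", "ratio", "n_spectra"]].reset_index(drop=True)


def protein_ratio(group: ProteinGroup, pbc_table: pd.DataFrame) -> ProteinGroupRatio | None:
    """Median and quartiles of a group's member PBC ratios.

    Quartiles use the linear-interpolation convention (numpy default), so
    [1, 2, 3] gives q1 = 1.5, q3 = 2.5. Groups without any PBC are
    excluded (None).
    """
    member = pbc_table[pbc_table["peptide"].isin(group.peptides)]
    if len(member) == 0:
        return None
    ratios = member["ratio"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(ratios, [25.0, 50.0, 75.0])
    return ProteinGroupRatio(
        group_id=group.group_id,
        member_proteins=group.member_proteins,
        median_ratio=float(med),
        q1=float(q1),
        q3=float(q3),
        n_pbc=int(len(member)),
    )


def protein_group_ratios(
    groups: list[ProteinGroup], pbc_table: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate :func:`protein_ratio` over all groups (empty groups dropped)."""
    rows = []
    for g in groups:
        r = protein_ratio(g, pbc_table)
        if r is None:
            continue
        rows.append(
            {
                "group_id": r.group_id,
                "member_proteins": ";".join(sorted(r.member_proteins)),
                "median_ratio": r.median_ratio,
                "q1": r.q1,
                "q3": r.q3,
                "n_pbc": r.n_pbc,
            }
        )
    return pd.DataFrame(
        rows, columns=["group_id", "member_proteins", "median_ratio", "q1", "q3", "n_pbc"]
    )


def scale_to_cellular_unit(ratio: float, biomass_scale: float) -> float:
    """Convert an equal-protein ratio to a per-cell ratio.

    The mass-spectrometric ratios refer to equal amounts of total protein;
    multiplying by the Fe(-)/Fe(+) cellular protein-biomass ratio (BCA
    assay) expresses the regulation per cell.
    """
    if biomass_scale <= 0:
        raise ValueError("biomass scale must be positive")
    return ratio * biomass_scale
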
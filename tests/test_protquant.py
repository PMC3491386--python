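"""Proteomics filter cascade, protein grouping and ratio aggregation."""

import numpy as np
import pandas as pd
import pytest

from feomics import protquant, synthio


def make_psms(rows):
    defaults = {
        "spectrum_id": None,
        "peptide": "PEPTIDEK",
        "protein_ids": "p1",
        "evalue": 1e-6,
        "evalue_second_best": 1e-2,
        "ppm_dev": 0.0,
        "band": 1,
        "charge": 2,
        "is_decoy": False,
        "intensity_light": 100.0,
        "intensity_heavy": 100.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, **row)
        rec["spectrum_id"] = rec["spectrum_id"] or f"s{i}"
        out.append(rec)
    return pd.DataFrame(out, columns=protquant.PSM_COLUMNS)


# ---------------------------------------------------------------------------
# distinctiveness
# ---------------------------------------------------------------------------


def test_distinctiveness_examples():
    psms = make_psms(
        [
            {"evalue": 1e-6, "evalue_second_best": 1e-2},  # ratio 1e4 -> kept
            {"evalue": 1e-3, "evalue_second_best": 1.5e-3},  # ratio 1.5 -> removed
            {"evalue": 1e-3, "evalue_second_best": None},  # no runner-up -> kept
        ]
    )
    out = protquant.filter_distinctiveness(psms, threshold=2)
    assert list(out["spectrum_id"]) == ["s0", "s2"]


def test_distinctiveness_matches_brute_force(rng):
    evalues = 10.0 ** rng.uniform(-8, -1, size=100)
    seconds = evalues * 10.0 ** rng.uniform(-0.5, 2.0, size=100)
    psms = make_psms(
        [{"evalue": e, "evalue_second_best": s} for e, s in zip(evalues, seconds)]
    )
    out = protquant.filter_distinctiveness(psms, threshold=2)
    expected = {
        f"s{i}" for i in range(100) if seconds[i] / evalues[i] >= 2.0
    }
    assert set(out["spectrum_id"]) == expected


def test_distinctiveness_rejects_nonpositive_evalues(caplog):
    psms = make_psms([{"evalue": 0.0}, {"evalue": 1e-5}])
    out = protquant.filter_distinctiveness(psms)
    assert list(out["spectrum_id"]) == ["s1"]


# ---------------------------------------------------------------------------
# target-decoy FDR
# ---------------------------------------------------------------------------


def test_fdr_no_decoys_passes_everything():
    psms = make_psms([{"evalue": e} for e in (1e-6, 1e-4, 1e-2)])
    out, t = protquant.filter_fdr(psms, fdr_target=0.01)
    assert len(out) == 3
    assert t == pytest.approx(1e-2)


def test_fdr_hand_constructed_threshold():
    """300 targets below 3 decoys give exactly 1% FDR; a 4th decoy breaks it."""
    targets = [{"evalue": 1e-9 * (1 + i), "is_decoy": False} for i in range(300)]
    decoys = [{"evalue": 1e-6, "is_decoy": True} for _ in range(3)]
    late_decoy = [{"evalue": 2e-6, "is_decoy": True}]
    late_targets = [{"evalue": 3e-6 * (1 + i), "is_decoy": False} for i in range(5)]
    psms = make_psms(targets + decoys + late_decoy + late_targets)
    out, t = protquant.filter_fdr(psms, fdr_target=0.01)
    # threshold sits at the 3-decoy point: 3/300 = 0.01; the 4th decoy would
    # give 4/300 and no later target recovers below 1%
    assert t == pytest.approx(1e-6)
    assert len(out) == 300
    assert not out["is_decoy"].any()


def test_fdr_matches_brute_force_scan(rng):
    evalues = 10.0 ** rng.uniform(-8, 0, size=200)
    decoy = rng.random(200) < 0.2
    psms = make_psms(
        [{"evalue": e, "is_decoy": bool(d)} for e, d in zip(evalues, decoy)]
    )
    out, t = protquant.filter_fdr(psms, fdr_target=0.05)

    # oracle: try every observed E-value as the threshold
    best = None
    for cand in sorted(evalues):
        n_d = int(((evalues <= cand) & decoy).sum())
        n_t = int(((evalues <= cand) & ~decoy).sum())
        if n_t > 0 and n_d / n_t <= 0.05:
            best = cand
    assert t == pytest.approx(best)
    expected = {f"s{i}" for i in range(200) if evalues[i] <= best and not decoy[i]}
    assert set(out["spectrum_id"]) == expected


def test_fdr_unachievable_target_returns_empty():
    psms = make_psms(
        [{"evalue": 1e-6, "is_decoy": True}, {"evalue": 1e-5, "is_decoy": False}]
    )
    out, t = protquant.filter_fdr(psms, fdr_target=0.01)
    assert len(out) == 0
    assert np.isnan(t)


# ---------------------------------------------------------------------------
# ppm filter and cascade order
# ---------------------------------------------------------------------------


def test_ppm_boundary_inclusive():
    psms = make_psms([{"ppm_dev": 0.0}, {"ppm_dev": 5.0}, {"ppm_dev": 5.01}, {"ppm_dev": -6.0}])
    out = protquant.filter_ppm(psms, max_ppm=5)
    assert list(out["spectrum_id"]) == ["s0", "s1"]


def test_ppm_matches_brute_force(rng):
    devs = rng.normal(0, 4, size=50)
    psms = make_psms([{"ppm_dev": d} for d in devs])
    out = protquant.filter_ppm(psms)
    assert set(out["spectrum_id"]) == {f"s{i}" for i in range(50) if abs(devs[i]) <= 5}


def test_cascade_order_matters():
    """A high-ppm decoy tightens the FDR threshold because ppm runs last."""
    targets = [{"evalue": 1e-6 * 10**i, "is_decoy": False} for i in range(9)]
    decoy = [{"evalue": 5e-6, "is_decoy": True, "ppm_dev": 10.0}]
    psms = make_psms(targets + decoy)
    in_order, _ = protquant.apply_filter_cascade(psms, fdr_target=0.1)
    # ppm-first would remove the decoy before FDR estimation
    reordered, _ = protquant.filter_fdr(protquant.filter_ppm(psms), fdr_target=0.1)
    assert len(in_order) == 1  # only the target below the decoy survives
    assert len(reordered) == 9
    assert set(in_order["spectrum_id"]) != set(reordered["spectrum_id"])


# ---------------------------------------------------------------------------
# protein grouping
# ---------------------------------------------------------------------------


def test_identical_peptide_sets_merge():
    psms = make_psms(
        [
            {"peptide": "AAAK", "protein_ids": "pA;pB"},
            {"peptide": "CCCK", "protein_ids": "pA;pB"},
        ]
    )
    groups = protquant.infer_protein_groups(psms)
    assert len(groups) == 1
    assert groups[0].member_proteins == frozenset({"pA", "pB"})


def test_subset_protein_absorbed():
    psms = make_psms(
        [
            {"peptide": "AAAK", "protein_ids": "pA"},
            {"peptide": "CCCK", "protein_ids": "pA;pB"},
        ]
    )
    groups = protquant.infer_protein_groups(psms)
    assert len(groups) == 1
    assert groups[0].member_proteins == frozenset({"pA", "pB"})
    assert groups[0].peptides == frozenset({"AAAK", "CCCK"})


def test_shared_peptides_marked_non_unique():
    psms = make_psms(
        [
            {"peptide": "AAAK", "protein_ids": "pA"},
            {"peptide": "SHAREDK", "protein_ids": "pA;pB"},
            {"peptide": "CCCK", "protein_ids": "pB"},
        ]
    )
    groups = protquant.infer_protein_groups(psms)
    assert len(groups) == 2
    for g in groups:
        assert "SHAREDK" in g.peptides
        assert "SHAREDK" not in g.unique_peptides


def test_group_count_matches_brute_force(rng):
    """Random bipartite peptide/protein instances vs a pairwise-subset oracle."""
    for trial in range(20):
        n_prot, n_pep = 8, 10
        peptides = [f"PEP{j}" for j in range(n_pep)]
        rows = []
        for i in range(n_prot):
            mask = rng.random(n_pep) < 0.35
            if not mask.any():
                mask[rng.integers(n_pep)] = True
            for j in np.flatnonzero(mask):
                rows.append({"peptide": peptides[j], "protein_ids": f"prot{i}"})
        psms = make_psms(rows)
        groups = protquant.infer_protein_groups(psms)

        prot2pep = {}
        for r in rows:
            prot2pep.setdefault(r["protein_ids"], set()).add(r["peptide"])
        sets = {frozenset(s) for s in prot2pep.values()}
        n_maximal = sum(
            1 for s in sets if not any(s < t for t in sets if t is not s)
        )
        assert len(groups) == n_maximal


# ---------------------------------------------------------------------------
# PBC ratios and aggregation
# ---------------------------------------------------------------------------


def test_pbc_ratio_light_equals_heavy():
    pbc = protquant.pbc_ratios(make_psms([{"intensity_light": 50.0, "intensity_heavy": 50.0}]))
    assert pbc.loc[0, "ratio"] == pytest.approx(1.0)


def test_pbc_key_separates_charges():
    psms = make_psms(
        [
            {"peptide": "AAAK", "charge": 2, "intensity_light": 10, "intensity_heavy": 5},
            {"peptide": "AAAK", "charge": 3, "intensity_light": 20, "intensity_heavy": 5},
        ]
    )
    pbc = protquant.pbc_ratios(psms)
    assert len(pbc) == 2
    assert sorted(pbc["ratio"]) == [2.0, 4.0]


def test_pbc_duplicate_spectra_collapse():
    """Median aggregation is invariant to duplicating spectra within a PBC."""
    base = make_psms(
        [
            {"peptide": "AAAK", "intensity_light": 10, "intensity_heavy": 5},
            {"peptide": "CCCK", "intensity_light": 30, "intensity_heavy": 10},
        ]
    )
    doubled = pd.concat([base, base.assign(spectrum_id=["d0", "d1"])], ignore_index=True)
    p1 = protquant.pbc_ratios(base)
    p2 = protquant.pbc_ratios(doubled)
    assert list(p1["ratio"]) == list(p2["ratio"])


def test_pbc_zero_heavy_dropped():
    psms = make_psms([{"intensity_heavy": 0.0}])
    assert len(protquant.pbc_ratios(psms)) == 0


def test_labeling_orientation_flips_ratio():
    psms = make_psms([{"intensity_light": 10, "intensity_heavy": 5}])
    assert protquant.pbc_ratios(psms, heavy_condition="fe_plus").loc[0, "ratio"] == 2.0
    assert protquant.pbc_ratios(psms, heavy_condition="fe_minus").loc[0, "ratio"] == 0.5


def test_protein_ratio_quartile_convention():
    group = protquant.ProteinGroup("g", frozenset({"p"}), frozenset({"A", "B", "C"}))
    pbc = pd.DataFrame(
        {"peptide": ["A", "B", "C"], "band": [1, 1, 1], "charge": [2, 2, 2],
         "ratio": [1.0, 2.0, 3.0], "n_spectra": [1, 1, 1]}
    )
    r = protquant.protein_ratio(group, pbc)
    assert (r.q1, r.median_ratio, r.q3) == (1.5, 2.0, 2.5)


def test_protein_ratio_single_pbc():
    group = protquant.ProteinGroup("g", frozenset({"p"}), frozenset({"A"}))
    pbc = pd.DataFrame(
        {"peptide": ["A"], "band": [1], "charge": [2], "ratio": [2.0], "n_spectra": [1]}
    )
    r = protquant.protein_ratio(group, pbc)
    assert r.median_ratio == r.q1 == r.q3 == 2.0
    assert r.n_pbc == 1


@pytest.mark.parametrize(
    "ratio, scale, expected",
    [(1.0, 0.5, 0.5), (1.7, 0.5, 0.85), (2.3, 1.0, 2.3)],
)
def test_scale_to_cellular_unit(ratio, scale, expected):
    assert protquant.scale_to_cellular_unit(ratio, scale) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# end-to-end on synthetic PSMs
# ---------------------------------------------------------------------------


def test_noiseless_planted_ratios_recovered_exactly():
    spec = synthio.SynthPsmSpec(
        true_ratios={"prot001": 2.0, "prot002": 1.0},
        n_proteins=5,
        decoy_fraction=0.0,
        ppm_noise_sd=0.0,
        intensity_cv=0.0,
        seed=1,
    )
    psms, _ = synthio.gen_psms(spec)
    filtered, _ = protquant.apply_filter_cascade(psms)
    assert len(filtered) == len(psms)  # everything survives the chain
    groups = protquant.infer_protein_groups(filtered)
    ratios = protquant.protein_group_ratios(groups, protquant.pbc_ratios(filtered))
    by_id = ratios.set_index("group_id")
    assert by_id.loc["grp_prot001", "median_ratio"] == pytest.approx(2.0)
    assert by_id.loc["grp_prot002", "median_ratio"] == pytest.approx(1.0)


def test_estimated_fdr_never_exceeds_target():
    for seed in range(5):
        psms, _ = synthio.gen_psms(synthio.SynthPsmSpec(decoy_fraction=0.25, seed=seed))
        surv = protquant.filter_distinctiveness(psms)
        out, t = protquant.filter_fdr(surv, fdr_target=0.01)
        if np.isnan(t):
            continue
        n_d = int((surv["is_decoy"] & (surv["evalue"] <= t)).sum())
        n_t = int((~surv["is_decoy"] & (surv["evalue"] <= t)).sum())
        assert n_d / n_t <= 0.01
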
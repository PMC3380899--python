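"""Target-decoy FDR estimation, grouping, and dynamic filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aggquant import chem, fdr

LETTERS = list(chem.STANDARD_RESIDUES)


def _psm(
    i,
    xcorr=3.0,
    delta_cn=0.4,
    is_decoy=False,
    charge=2,
    trypticity="full",
    ppm=0.0,
    protein=None,
    sequence=None,
):
    rng = np.random.default_rng(i)
    seq = sequence or "".join(rng.choice(LETTERS, size=9)) + "K"
    pep = chem.Peptide(seq)
    theo = chem.monoisotopic_mass(pep).mh
    protein = protein or (f"REV_P{i}" if is_decoy else f"P{i}")
    return fdr.PSM(
        spectrum_id=f"S{i:05d}",
        peptide=pep,
        charge=charge,
        xcorr=xcorr,
        delta_cn=delta_cn,
        observed_mh=theo * (1 + ppm * 1e-6),
        trypticity=trypticity,
        is_decoy=is_decoy,
        protein_ids=(protein,),
    )


def test_ppm_error_is_recomputable():
    psm = _psm(1, ppm=7.5)
    assert psm.ppm_error == pytest.approx(7.5, abs=1e-6)


# --- FDR estimator ----------------------------------------------------------


def test_estimate_fdr_direct_arithmetic():
    psms = [_psm(i, is_decoy=i < 5) for i in range(1000)]
    assert fdr.estimate_fdr(psms) == pytest.approx(2 * 5 / 1000)
    assert fdr.estimate_fdr([_psm(i) for i in range(50)]) == 0.0
    assert fdr.estimate_fdr([]) == 0.0


@settings(derandomize=True, max_examples=50)
@given(flags=st.lists(st.booleans(), min_size=1, max_size=200))
def test_estimate_fdr_matches_independent_recount(flags):
    psms = [_psm(i, is_decoy=flag) for i, flag in enumerate(flags)]
    recount = 2 * sum(flags) / len(flags)
    assert fdr.estimate_fdr(psms) == pytest.approx(recount)


def test_estimator_calibrated_against_realized_false_fraction():
    """Over repeated draws with decoys and false targets generated by the
    same process, the mean estimated FDR tracks the realized incorrect
    fraction within its 95% binomial interval."""
    rng = np.random.default_rng(11)
    n_true, p = 1000, 0.02
    estimates, realized = [], []
    for _ in range(50):
        n_false = rng.binomial(n_true, p)
        n_decoy = rng.binomial(n_true, p)
        psms = [_psm(i) for i in range(n_true + n_false)]
        psms += [_psm(10_000 + i, is_decoy=True) for i in range(n_decoy)]
        estimates.append(fdr.estimate_fdr(psms))
        realized.append((n_false + n_decoy) / len(psms))
    mean_realized = float(np.mean(realized))
    n_total = 50 * (n_true + int(2 * p * n_true))
    half = 1.96 * np.sqrt(mean_realized * (1 - mean_realized) / n_total)
    assert abs(float(np.mean(estimates)) - mean_realized) <= half + 1e-3


# --- grouping ---------------------------------------------------------------


def test_group_psms_six_combinations():
    psms = [
        _psm(i, charge=z, trypticity=t)
        for i, (t, z) in enumerate(
            (t, z) for t in ("full", "partial") for z in (2, 3, 4)
        )
    ]
    groups, rejected = fdr.group_psms(psms)
    assert len(groups) == 6 and not rejected
    assert all(len(g) == 1 for g in groups.values())


def test_group_psms_single_group_and_rejects():
    psms = [_psm(i, charge=2, trypticity="full") for i in range(5)]
    psms.append(_psm(99, charge=5))
    groups, rejected = fdr.group_psms(psms)
    assert set(groups) == {("full", 2)}
    assert [p.spectrum_id for p in rejected] == ["S00099"]


def test_group_partition_conserves_input():
    rng = np.random.default_rng(5)
    psms = [
        _psm(i, charge=int(rng.choice([1, 2, 3, 4, 5])), trypticity=str(rng.choice(["full", "partial"])))
        for i in range(200)
    ]
    groups, rejected = fdr.group_psms(psms)
    assert sum(len(g) for g in groups.values()) + len(rejected) == 200
    seen = {p.spectrum_id for g in groups.values() for p in g}
    seen |= {p.spectrum_id for p in rejected}
    assert len(seen) == 200  # disjoint partition


# --- protein families -------------------------------------------------------


def test_family_grouping_examples():
    shared = _psm(1, sequence="ACDEFGHIK")
    shared.protein_ids = ("P1", "P2")
    groups = fdr.group_protein_families([shared])
    assert groups == [frozenset({"P1", "P2"})]

    disjoint = [_psm(i, protein=f"P{i}") for i in range(4)]
    groups = fdr.group_protein_families(disjoint)
    assert len(groups) == 4 and all(len(g) == 1 for g in groups)


def test_family_grouping_matches_connected_components():
    """Random bipartite peptide-protein graphs: family groups equal the
    connected components computed independently with networkx."""
    import networkx as nx

    rng = np.random.default_rng(17)
    for trial in range(10):
        n_prot, n_pep = 15, 25
        psms = []
        graph = nx.Graph()
        graph.add_nodes_from(f"P{j}" for j in range(n_prot))
        for i in range(n_pep):
            owners = tuple(
                f"P{j}" for j in rng.choice(n_prot, size=int(rng.integers(1, 4)), replace=False)
            )
            psm = _psm(trial * 100 + i)
            psm.protein_ids = owners
            psms.append(psm)
            for a in owners:
                for b in owners:
                    graph.add_edge(a, b)
        got = set(fdr.group_protein_families(psms))
        expected = {
            frozenset(c) for c in nx.connected_components(graph) if len(c) > 1 or any(
                set(p.protein_ids) & c for p in psms
            )
        }
        assert got == expected


# --- dynamic filter ---------------------------------------------------------


def _score_set(seed, n_targets=800, decoy_fraction=0.3, false_fraction=0.01):
    """Targets from a high-score distribution, decoys (and a known fraction
    of false targets) from a low one; returns (psms, false_ids)."""
    rng = np.random.default_rng(seed)
    psms, false_ids = [], []
    for i in range(n_targets):
        is_false = rng.random() < false_fraction
        if is_false:
            xc = max(0.0, rng.normal(1.4, 0.45))
            dc = float(np.clip(rng.normal(0.08, 0.04), 0, 1))
            ppm = rng.uniform(-40, 40)
        else:
            xc = max(0.0, rng.normal(3.2, 0.8))
            dc = float(np.clip(rng.normal(0.40, 0.12), 0, 1))
            ppm = rng.normal(0, 3)
        psm = _psm(
            seed * 1_000_000 + i,
            xcorr=xc,
            delta_cn=dc,
            ppm=ppm,
            charge=int(rng.choice([2, 3, 4])),
            trypticity=str(rng.choice(["full", "partial"])),
        )
        psms.append(psm)
        if is_false:
            false_ids.append(psm.spectrum_id)
    n_decoys = int(decoy_fraction * n_targets)
    for i in range(n_decoys):
        xc = max(0.0, rng.normal(1.4, 0.45))
        dc = float(np.clip(rng.normal(0.08, 0.04), 0, 1))
        psms.append(
            _psm(
                seed * 1_000_000 + n_targets + i,
                xcorr=xc,
                delta_cn=dc,
                ppm=rng.uniform(-40, 40),
                is_decoy=True,
                charge=int(rng.choice([2, 3, 4])),
                trypticity=str(rng.choice(["full", "partial"])),
            )
        )
    return psms, false_ids


def test_all_decoy_input_accepts_nothing():
    psms = [_psm(i, is_decoy=True, xcorr=4.0, delta_cn=0.5) for i in range(50)]
    result = fdr.dynamic_filter(psms)
    assert result.nt == 0 and result.accepted == []
    assert result.diagnostics


def test_pure_high_scoring_targets_all_accepted():
    psms = [_psm(i, xcorr=3.5, delta_cn=0.45) for i in range(60)]
    result = fdr.dynamic_filter(psms)
    assert result.nt == 60
    assert result.fdr_estimate == 0.0
    assert all(thr == (1.0, 0.05) for thr in result.thresholds.values())


def test_ppm_gate_enforced():
    good = [_psm(i, ppm=3.0) for i in range(20)]
    bad = [_psm(100 + i, ppm=30.0) for i in range(5)]
    result = fdr.dynamic_filter(good + bad)
    assert result.nt == 20
    assert all(abs(p.ppm_error) <= 15 for p in result.accepted)


def test_threshold_monotonicity():
    """Raising either threshold never increases nd or nt."""
    psms, _ = _score_set(23)
    def counts(xc, dc):
        acc = [p for p in psms if p.xcorr >= xc and p.delta_cn >= dc]
        return sum(p.is_decoy for p in acc), len(acc)
    base = counts(1.0, 0.05)
    for xc, dc in [(1.5, 0.05), (1.0, 0.2), (2.5, 0.3)]:
        nd, nt = counts(xc, dc)
        assert nd <= base[0] and nt <= base[1]


def test_dynamic_filter_controls_realized_false_fraction():
    """With a 1% known false-target rate, the realized false-target fraction
    among accepted PSMs stays below 1.5x the 1% target over 20 seeded runs."""
    total_false, total_accepted = 0, 0
    for seed in range(20):
        psms, false_ids = _score_set(seed)
        result = fdr.dynamic_filter(psms, target_fdr=0.01)
        targets = [p for p in result.accepted if not p.is_decoy]
        total_accepted += len(targets)
        total_false += sum(1 for p in targets if p.spectrum_id in set(false_ids))
        assert result.protein_fdr <= 0.01
    assert total_accepted > 0
    assert total_false / total_accepted <= 0.015


def test_determinism():
    psms, _ = _score_set(77)
    a = fdr.dynamic_filter(psms)
    b = fdr.dynamic_filter(psms)
    assert a.thresholds == b.thresholds
    assert [p.spectrum_id for p in a.accepted] == [p.spectrum_id for p in b.accepted]
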
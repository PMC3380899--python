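"""Peptide chemistry: masses, digestion, fragment ladders, decoys, planning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aggquant import chem, pipeline

GG = chem.MODIFICATIONS["GG"]
ME2 = chem.MODIFICATIONS["Me2"]
OX = chem.MODIFICATIONS["Ox"]

peptide_seq = st.text(alphabet=chem.STANDARD_RESIDUES, min_size=2, max_size=25)
protein_seq = st.text(alphabet=chem.STANDARD_RESIDUES, min_size=10, max_size=80)


def _ref_rows():
    """All shipped reference peptides with printed [M+H]+ values.

    Ubiquitination-site reference masses agree within one unit in the
    fourth decimal place; the methylation-table masses (3+/4+ rows) carry
    up to 2e-4 Da of printing inconsistency, so they get a wider band.
    """
    t5 = pipeline.load_reference_table("gg_reference_peptides")
    t4 = pipeline.load_reference_table("methylation_sites")
    rows = [(r["peptide"], float(r["mh_printed"]), 0.00011) for _, r in t5.iterrows()]
    rows += [(r["peptide"], float(r["expected_mh"]), 0.0002) for _, r in t4.iterrows()]
    return rows


@pytest.mark.parametrize("notation,printed,tol", _ref_rows())
def test_reference_mh_values_reproduce(notation, printed, tol):
    pep = chem.parse_flanked(notation)
    assert chem.monoisotopic_mass(pep).mh == pytest.approx(printed, abs=tol)


def test_gg_peptide_exact_printed_masses():
    """The two ubiquitination-site peptides whose printed masses are exact
    4-dp roundings reproduce digit for digit."""
    k145 = chem.Peptide("TGHSKGFGFVR", mods=[(5, GG)])
    assert round(chem.monoisotopic_mass(k145).mh, 4) == 1306.6651
    k84 = chem.Peptide("KMDETDASSAVK", mods=[(1, GG)])
    assert round(chem.monoisotopic_mass(k84).mh, 4) == 1395.6420


def test_single_residue_mass_additivity():
    g = chem.Peptide("G")
    assert chem.monoisotopic_mass(g).mh == pytest.approx(76.0393, abs=1e-4)


def test_mass_result_invariants():
    pep = chem.Peptide("FTEYETQVK")
    m = chem.monoisotopic_mass(pep)
    assert m.mh == pytest.approx(m.neutral_mass + 1.00728, abs=1e-6)
    for z, mz in m.mz_by_charge.items():
        assert mz == pytest.approx((m.neutral_mass + z * 1.00728) / z, abs=1e-9)


@settings(derandomize=True, max_examples=50)
@given(a=peptide_seq, b=peptide_seq)
def test_mass_additivity_on_concatenation(a, b):
    """mass(A+B) = mass(A) + mass(B) - water for any peptide pair."""
    ma = chem.monoisotopic_mass(chem.Peptide(a)).neutral_mass
    mb = chem.monoisotopic_mass(chem.Peptide(b)).neutral_mass
    mab = chem.monoisotopic_mass(chem.Peptide(a + b)).neutral_mass
    assert mab == pytest.approx(ma + mb - chem.WATER, abs=1e-9)


def test_pseudo_gg_mass_identity():
    """A lysine dialkylated to a 2-acetamidoacetamide adduct is mass-identical
    to the same peptide carrying the tryptic ubiquitin GG remnant."""
    dialkyl = chem.MODIFICATIONS["dialkyl"]
    a = chem.Peptide("TGHSKGFGFVR", mods=[(5, GG)])
    b = chem.Peptide("TGHSKGFGFVR", mods=[(5, dialkyl)])
    assert chem.monoisotopic_mass(a) == chem.monoisotopic_mass(b)


# --- fragment ladders -------------------------------------------------------


@pytest.mark.parametrize(
    "seq,label,expected",
    [
        ("FGVHLISNVYGR", "y6", 695.35),
        ("FTEYETQVK", "y5", 604.33),
    ],
)
def test_fragment_mz_matches_targeted_method(seq, label, expected):
    ladder = dict(chem.fragment_ladder(chem.Peptide(seq)))
    assert round(ladder[label], 2) == expected


@settings(derandomize=True, max_examples=50)
@given(seq=peptide_seq)
def test_ladder_complementarity(seq):
    """b_i + y_{n-i} = MH + proton at every cleavage point."""
    pep = chem.Peptide(seq)
    mh = chem.monoisotopic_mass(pep).mh
    ladder = dict(chem.fragment_ladder(pep))
    n = len(seq)
    for i in range(1, n):
        assert ladder[f"b{i}"] + ladder[f"y{n - i}"] == pytest.approx(
            mh + chem.PROTON, abs=1e-9
        )


def test_ladder_carries_modifications():
    pep = chem.Peptide("TGHSKGFGFVR", mods=[(5, GG)])
    plain = chem.Peptide("TGHSKGFGFVR")
    mod_ladder = dict(chem.fragment_ladder(pep))
    plain_ladder = dict(chem.fragment_ladder(plain))
    # GG sits at position 5: b5 carries it, y6 (positions 6-11) does not
    assert mod_ladder["b5"] == pytest.approx(plain_ladder["b5"] + 114.0429, abs=1e-9)
    assert mod_ladder["y6"] == pytest.approx(plain_ladder["y6"], abs=1e-9)


# --- heavy SILAC partner ----------------------------------------------------


@settings(derandomize=True, max_examples=50)
@given(seq=peptide_seq)
def test_heavy_partner_by_residue_count(seq):
    """Heavy - light mass equals 8.01420 per K plus 10.00827 per R (an
    independent composition count)."""
    pep = chem.Peptide(seq)
    delta = (
        chem.heavy_partner_mass(pep).neutral_mass
        - chem.monoisotopic_mass(pep).neutral_mass
    )
    expected = 8.01420 * seq.count("K") + 10.00827 * seq.count("R")
    assert delta == pytest.approx(expected, abs=1e-9)


def test_heavy_partner_unlabeled_peptide():
    pep = chem.Peptide("GASPVTML")
    assert chem.heavy_partner_mass(pep) == chem.monoisotopic_mass(pep)


# --- digestion --------------------------------------------------------------


def test_digest_no_cleavage_sites():
    rules = chem.DigestRules(max_missed_cleavages=0, min_length=1)
    peps = chem.digest("MAAAG", rules)
    assert [p.sequence for p in peps] == ["MAAAG"]
    assert peps[0].preceding_residue == "-" and peps[0].following_residue == "-"


def test_digest_gg_blocks_cleavage_and_preserves_flanks():
    """A GG-modified lysine does not terminate a peptide: the digest yields
    the spanning peptide with the modification at its K and K/F flanks."""
    protein = "MAK" + "TGHSKGFGFVR" + "FLE"
    rules = chem.DigestRules(max_missed_cleavages=0, min_length=4)
    peps = chem.digest(protein, rules, mods=[(8, GG)])
    spanning = [p for p in peps if p.sequence == "TGHSKGFGFVR"]
    assert len(spanning) == 1
    pep = spanning[0]
    assert pep.mods == [(5, GG)]
    assert pep.preceding_residue == "K" and pep.following_residue == "F"
    assert pep.start == 4
    # without the modification the same digest cleaves after that K
    plain = chem.digest(protein, rules)
    assert not any(p.sequence == "TGHSKGFGFVR" for p in plain)


def _brute_force(seq, rules, blocked):
    sites = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P" and i not in blocked
    ]
    out = []
    for s in range(len(seq)):
        for e in range(s + 1, len(seq) + 1):
            if e - s < rules.min_length:
                continue
            start_ok = s == 0 or (s - 1 in sites)
            end_ok = e == len(seq) or (e - 1 in sites)
            if rules.trypticity == "full" and not (start_ok and end_ok):
                continue
            if rules.trypticity == "partial" and not (start_ok or end_ok):
                continue
            if sum(1 for i in sites if s <= i < e - 1) > rules.max_missed_cleavages:
                continue
            out.append((s + 1, seq[s:e]))
    return sorted(out)


@pytest.mark.parametrize("trypticity", ["full", "partial"])
@pytest.mark.parametrize("missed", [0, 1, 2])
def test_digest_agrees_with_brute_force(trypticity, missed):
    """digest() equals substring enumeration checked against the rules, for
    random sequences and all rule combinations."""
    rng = np.random.default_rng(42)
    letters = list(chem.STANDARD_RESIDUES)
    rules = chem.DigestRules(
        max_missed_cleavages=missed, trypticity=trypticity, min_length=4
    )
    for _ in range(15):
        seq = "".join(rng.choice(letters, size=60))
        got = sorted((p.start, p.sequence) for p in chem.digest(seq, rules))
        assert got == _brute_force(seq, rules, blocked=set())


def test_digest_brute_force_with_blocked_site():
    rng = np.random.default_rng(7)
    letters = list(chem.STANDARD_RESIDUES)
    rules = chem.DigestRules(max_missed_cleavages=1, min_length=4)
    for _ in range(10):
        seq = "".join(rng.choice(letters, size=60))
        ks = [i for i, aa in enumerate(seq) if aa == "K"]
        if not ks:
            continue
        pos = ks[0] + 1
        got = sorted(
            (p.start, p.sequence) for p in chem.digest(seq, rules, mods=[(pos, GG)])
        )
        assert got == _brute_force(seq, rules, blocked={pos - 1})


def test_digest_rejects_bad_input():
    with pytest.raises(chem.ChemistryError, match="B"):
        chem.digest("MABK", chem.DigestRules())
    with pytest.raises(chem.ChemistryError):
        chem.digest("MAGK", chem.DigestRules(), mods=[(2, GG)])  # A is not K


# --- decoy database ---------------------------------------------------------


def _write_fasta(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


def test_decoy_database_doubles_entries(tmp_path):
    rng = np.random.default_rng(3)
    entries = [
        (f"P{i}", "".join(rng.choice(list(chem.STANDARD_RESIDUES), size=30)))
        for i in range(10)
    ]
    fin = tmp_path / "in.fasta"
    fout = tmp_path / "out.fasta"
    _write_fasta(fin, entries)
    assert chem.reverse_decoy_database(str(fin), str(fout)) == 20
    db = {r.id: str(r.seq) for r in __import__("Bio.SeqIO", fromlist=["parse"]).parse(str(fout), "fasta")}
    for name, seq in entries:
        assert db[name] == seq
        assert db[f"REV_{name}"] == seq[::-1]
        assert sorted(db[f"REV_{name}"]) == sorted(seq)


def test_decoy_palindrome_and_involution(tmp_path):
    fin = tmp_path / "in.fasta"
    mid = tmp_path / "mid.fasta"
    _write_fasta(fin, [("PAL", "MAGAM")])
    chem.reverse_decoy_database(str(fin), str(mid))
    from Bio import SeqIO

    recs = {r.id: str(r.seq) for r in SeqIO.parse(str(mid), "fasta")}
    assert recs["REV_PAL"] == recs["PAL"]  # palindrome: decoy == target
    assert recs["PAL"][::-1][::-1] == recs["PAL"]  # reversal is an involution


def test_decoy_duplicate_ids_rejected(tmp_path):
    fin = tmp_path / "in.fasta"
    _write_fasta(fin, [("P1", "MAGK"), ("P1", "MAGR")])
    with pytest.raises(chem.ChemistryError, match="duplicate"):
        chem.reverse_decoy_database(str(fin), str(tmp_path / "out.fasta"))


# --- inclusion-list planning ------------------------------------------------


@pytest.mark.parametrize(
    "seq,printed",
    [
        ("FTEYETQVK", 573.28),
        ("FGGNPGGFGNQGGFGNSR", 864.39),
        ("FGVHLISNVYGR", 681.87),
        ("DQIYDIFQK", 585.80),
        ("HVFGESDELIGQK", 730.37),
        ("VVLAYEPVWAIGTGK", 802.45),
    ],
)
def test_inclusion_centers_match_printed_method(seq, printed):
    """Window centers (monoisotopic 2+ m/z + 0.50) reproduce the printed
    targeted-method centers within 0.03 m/z."""
    plan = chem.plan_inclusion_list([chem.Peptide(seq)], charge=2)
    (_pep, center), = plan.segments[0]
    assert center == pytest.approx(printed, abs=0.03)
    assert plan.isolation_width == 1.7


def test_inclusion_list_segmentation_preserves_order():
    peps = [chem.Peptide(s) for s in ("FTEYETQVK", "DQIYDIFQK", "FGVHLISNVYGR")]
    plan = chem.plan_inclusion_list(peps, charge=2, segment_size=2)
    assert [len(s) for s in plan.segments] == [2, 1]
    flattened = [p.sequence for seg in plan.segments for p, _ in seg]
    assert flattened == ["FTEYETQVK", "DQIYDIFQK", "FGVHLISNVYGR"]


# --- notation ---------------------------------------------------------------


def test_notation_roundtrip_and_mass_offsets():
    pep = chem.parse_flanked("K.TGHSK[+114.0429]GFGFVR.F")
    assert pep.mods == [(5, GG)]
    assert chem.format_flanked(pep) == "K.TGHSK[GG]GFGFVR.F"
    again = chem.parse_flanked(chem.format_flanked(pep))
    assert again.sequence == pep.sequence and again.mods == pep.mods


def test_notation_rejects_unknown_mod():
    with pytest.raises(chem.ChemistryError, match="unregistered"):
        chem.parse_flanked("K.TGHSK[Phos]GFGFVR.F")
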
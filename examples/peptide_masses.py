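"""Masses and targeted-method planning for ubiquitination-site peptides.

Builds the K145 GG-remnant peptide of TDP-43, prints its monoisotopic
[M+H]+ and b/y fragment ladder, and plans a 1.7 m/z isolation window for a
2+ targeted MS/MS method.
"""

from aggquant import chem

gg = chem.MODIFICATIONS["GG"]
pep = chem.Peptide("TGHSKGFGFVR", mods=[(5, gg)], preceding_residue="K", following_residue="F")

mass = chem.monoisotopic_mass(pep)
print(f"peptide          {chem.format_flanked(pep)}")
print(f"[M+H]+           {mass.mh:.4f} Da")
print(f"m/z (2+)         {mass.mz(2):.4f}")

ladder = chem.fragment_ladder(pep)
for label, mz in ladder[:6]:
    print(f"fragment {label:<4s} {mz:9.2f}")

plan = chem.plan_inclusion_list([pep], charge=2)
(_p, center), = plan.segments[0]
print(f"isolation window {plan.isolation_width} m/z centered at {center}")
print()
print("The [M+H]+ identifies the dialkylated reference standard that is")
print("mass-identical to the true ubiquitinated peptide; the window center")
print("sits 0.5 m/z above the monoisotopic 2+ m/z to cover the isotope envelope.")
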
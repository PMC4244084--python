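"""Reference amino-acid sequences used as defaults and in the test suite.

All three are public UniProt/PDB sequences:

* ``ABETA_17_42`` — the 26-residue amyloid-beta fragment Aβ17–42 (p3
  peptide), numbered 17–42 in the Aβ1–42 convention.
* ``ACD_66_150`` — the α-crystallin core domain of human αB-crystallin
  (UniProt P02511 residues 66–150, the construct crystallized in PDB 2WJ7);
  simulated systems use a dimer of this domain.
* ``LYSOZYME_1_130`` — mature human lysozyme (UniProt P61626 chain,
  residues 1–130 as in PDB 1REX).
"""

ABETA_17_42 = "LVFFAEDVGSNKGAIIGLMVGGVVIA"
ABETA_FIRST_RESIDUE = 17

ACD_66_150 = (
    "SEMRLEKDRFSVNLDVKHFSPEELKVKVLGDVIEVHGKHEERQDEHGFISREFHRKYRIP"
    "ADVDPLTITSSLSSDGVLTVNGPRK"
)
ACD_FIRST_RESIDUE = 66

LYSOZYME_1_130 = (
    "KVFERCELARTLKRLGMDGYRGISLANWMCLAKWESGYNTRATNYNAGDRSTDYGIFQIN"
    "SRYWCNDGKTPGAVNACHLSCSALLQDNIADAVACAKRVVRDPQGIRAWVAWRNRCQNRD"
    "VRQYVQGCGV"
)
LYSOZYME_FIRST_RESIDUE = 1
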
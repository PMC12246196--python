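"""Place molecules on the rod-disk-sphere triangle with PMI descriptors.

NPR1 = PM1/PM3 and NPR2 = PM2/PM3 (principal moments of inertia of the
lowest-energy conformer) locate each structure between the rod (0, 1),
disk (0.5, 0.5) and sphere (1, 1) corners. Planar aromatic substrates --
the ones glycosyltransferases prefer -- sit along the rod-disk edge.
"""

from glycoscreen.shapes import conformer_descriptors

molecules = {
    "butadiyne (rod)": "C#CC#C",
    "benzene (disk)": "c1ccccc1",
    "adamantane (sphere-like)": "C1C2CC3CC1CC(C2)C3",
    "formononetin (planar flavonoid)": "COc1ccc(cc1)C1=COc2cc(O)ccc2C1=O",
}

print(f"{'molecule':<32} {'NPR1':>6} {'NPR2':>6}")
for name, smiles in molecules.items():
    d = conformer_descriptors(smiles, n_conformers=10, seed=42)
    print(f"{name:<32} {d.npr1:6.3f} {d.npr2:6.3f}")
# NPR1 + NPR2 >= 1 always; low NPR1 with the sum near 1 means flat/elongated.
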
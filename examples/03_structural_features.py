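"""Structural operators on a single chain.

For one generated member: the closest long-range contact (nearest residue in
space with sequence separation > 5, Cbeta/Calpha distances), solvent
accessibility, backbone dihedrals and the 3-state secondary-structure label.
"""

from disorderlink import (
    FamilyConfig,
    backbone_dihedrals,
    assign_ss3,
    build_seed_backbone,
    find_all_clrcs,
    relative_asa,
    shrake_rupley_asa,
)

chain = build_seed_backbone(FamilyConfig(length=120, seed=42))
contacts = find_all_clrcs(chain, min_separation=5)
asa = shrake_rupley_asa(chain)

print("res  type  ss  phi      psi      ASA(A^2)  RSA    CLRC  d(A)")
for i in (10, 47, 74, 100):  # residues 11, 48, 75, 101
    r = chain.residues[i]
    phi, psi = backbone_dihedrals(chain, i)
    ss = assign_ss3(phi, psi)
    rsa = relative_asa(r.res_type, asa[i])
    ca = contacts.get(i)
    clrc = f"{chain.residues[ca.j].seq_num:4d}  {ca.distance:5.2f}" if ca else "  --     --"
    print(f"{r.seq_num:3d}  {r.res_type}     {ss}   {phi:+7.1f}  {psi:+7.1f}  "
          f"{asa[i]:7.1f}  {rsa:.2f}  {clrc}")
print("\nResidue 75 sits on the exposed coil loop: high RSA and a distant"
      " closest long-range contact; residue 48 is in the packed hairpin"
      " with a ~5 A strand-to-strand contact.")
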
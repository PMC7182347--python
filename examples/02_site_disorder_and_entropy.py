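"""Per-site disorder propensity and sequence entropy.

Maps each member's full sequence onto its structure (ordered residues vs
REMARK 465 missing residues), builds the per-column occupancy of the family
alignment, and prints delta = (N_dis - N_ord)/N_res together with the
residue-type Shannon entropy s1 for a few columns.  delta runs from -1
(every member ordered there) to +1 (every member disordered there).
"""

from disorderlink import (
    FamilyConfig,
    build_site_occupancy,
    compute_delta,
    filter_sites,
    generate_family,
    map_sequence_to_structure,
    residue_entropy,
)

fam = generate_family(FamilyConfig(n_proteins=30, length=120, seed=42))
maps = {s.id: map_sequence_to_structure(s, fam.chains[s.id]) for s in fam.sequences}
occupancy = build_site_occupancy(fam.msa, maps)
retained = filter_sites(occupancy, min_count=20)
print(f"{len(retained)}/{len(occupancy)} sites have >= 20 contributing residues\n")

print("site  N_res  N_dis  N_ord  delta    s1")
for occ in retained[::12]:
    delta = compute_delta(occ).delta
    s1 = residue_entropy(occ.letters.values())
    print(f"{occ.site:4d}  {occ.n_res:5d}  {occ.n_dis:5d}  {occ.n_ord:5d}  "
          f"{delta:+.3f}  {s1:.3f}")
print("\nColumns inside the disorder segment (middle rows) show delta near"
      " 2p-1; fully ordered columns sit at -1.")
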
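"""TM-scores of family members against the seed structure.

The TM-score (1/Lt * sum 1/(1+(d_i/d0)^2), maximized over rigid
superpositions for a fixed residue correspondence) is 1 for identical
structures and > 0.5 for same-fold pairs; d0 = 1.24(Lt-15)^(1/3) - 1.8.
"""

import numpy as np

from disorderlink import FamilyConfig, d0, generate_family, tm_score
from disorderlink.pipeline import _seqnum_pairs

fam = generate_family(FamilyConfig(n_proteins=20, length=120, seed=42))
seed = fam.seed_chain
print(f"target length Lt = {seed.n_residues}, d0 = {d0(seed.n_residues):.3f} A")
print(f"self-score: {tm_score(seed, seed).score:.4f}\n")

scores = []
for pid in sorted(fam.chains)[:5]:
    member = fam.chains[pid]
    res = tm_score(seed, member, _seqnum_pairs(seed, member))
    scores.append(res.score)
    print(f"{pid}: TM = {res.score:.4f}  (La = {res.La} aligned residues)")
all_scores = [tm_score(seed, c, _seqnum_pairs(seed, c)).score
              for c in fam.chains.values()]
print(f"\nfamily: mean {np.mean(all_scores):.3f}, median {np.median(all_scores):.3f}, "
      f"sd {np.std(all_scores):.3f}")
print("Members differ from the seed by coordinate noise and missing disordered"
      "\nsegments, so scores sit well above the 0.5 same-fold threshold.")
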
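"""Protein descriptors: K-PSSM-composition and CTD.

Generates a synthetic protein with a PSI-BLAST-style PSSM and extracts the
two protein feature blocks: the 400-dim PSSM composition (row sums of the
scoring matrix grouped by residue type) and the 273-dim CTD descriptor
(composition / transition / distribution over 13 physicochemical
properties, each splitting the 20 amino acids into 3 groups).
"""

import numpy as np

from lpifuse.protein import ctd, kpssm_composition, load_ctd_table
from lpifuse.synth import gen_pssm, gen_sequences

(protein,) = gen_sequences(1, "protein", (80, 80), seed=7)
(pssm,) = gen_pssm([protein], seed=8)
print(f"protein {protein.id}: length {len(protein)}, PSSM shape {pssm.scores.shape}")

kp = kpssm_composition(pssm, k=1)
print(f"\nK-PSSM-composition (k=1): {kp.shape[0]} dimensions "
      f"(20 residue types x 20 PSSM columns)")
print(f"  non-zero blocks: {int((kp.reshape(20, 20).any(axis=1)).sum())} of 20 "
      f"(one per residue type present in the sequence)")

table = load_ctd_table()
c, t, d = ctd(protein.sequence, table)
print(f"\nCTD: C={c.shape[0]} + T={t.shape[0]} + D={d.shape[0]} "
      f"= {c.shape[0] + t.shape[0] + d.shape[0]} dimensions")
print(f"  property 1 ({table.property_names[0]}): "
      f"group fractions {np.round(c[:3], 3)} (sum {c[:3].sum():.3f})")
print(f"  transition fractions between its groups: {np.round(t[:3], 3)}")
print(f"  distribution percentiles of group 1: {np.round(d[:5], 1)} "
      "(percent of sequence length at the 1st/25%/50%/75%/last occurrence)")
print(f"\nfull protein block: {kp.shape[0]} + 273 = {kp.shape[0] + 273} dimensions")
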
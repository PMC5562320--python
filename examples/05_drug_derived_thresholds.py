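"""Derive permutation-test thresholds from approved-drug P-values.

The screen sets its P-value cutoffs at the per-channel maxima over the
approved drugs that pass the association test, so no candidate is held to
a stricter standard than the worst-scoring approved drug.  Here the
published measurements of the ten approved NSCLC drugs are used.
"""

from chemscreen.reference import APPROVED_NSCLC_DRUG_TABLE, approved_drug_assessments
from chemscreen.screening import select_thresholds

for cid, (name, rs_c, rs_g, p_c, p_g) in sorted(APPROVED_NSCLC_DRUG_TABLE.items()):
    print(f"CID{cid:<9} {name:<16} RS_c={rs_c:7.3f} RS_g={rs_g:7.3f} "
          f"P_c={p_c:.3f} P_g={p_g:.3f}")

t_c, t_g = select_thresholds(approved_drug_assessments())
print(f"\nscreening thresholds: P_chemicals <= {t_c}, P_genes <= {t_g}")
# Candidates with both P-values at or below these maxima are retained.
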
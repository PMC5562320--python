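"""Published benchmark measurements for ten approved NSCLC drugs.

Rating scores (mean combined interaction score, STITCH 0-1000 scale) and
empirical permutation P-values of the ten approved non-small-cell lung
cancer drugs that pass the association test against the NSCLC-related
chemical and gene sets, as computed on the STITCH v4.0 interaction network.
They serve as reference inputs for drug-derived threshold selection: the
per-channel maxima (0.469 for chemicals, 0.292 for genes) are the
published screening thresholds.
"""

from __future__ import annotations

from chemscreen.screening import CompoundAssessment

# compound id -> (name, RS_chemicals, RS_genes, P_chemicals, P_genes)
APPROVED_NSCLC_DRUG_TABLE: dict[int, tuple[str, float, float, float, float]] = {
    4033: ("Mechlorethamine", 296.299, 358.250, 0.248, 0.115),
    36314: ("Paclitaxel", 306.485, 462.889, 0.346, 0.221),
    38904: ("Carboplatin", 307.897, 332.267, 0.196, 0.238),
    57166: ("Porfimer Sodium", 307.231, 218.000, 0.312, 0.032),
    60843: ("Pemetrexed", 278.798, 233.750, 0.337, 0.124),
    123631: ("Gefitinib", 303.047, 493.275, 0.289, 0.292),
    126941: ("Methotrexate", 330.201, 362.250, 0.469, 0.150),
    176870: ("Erlotinib", 320.090, 579.929, 0.273, 0.175),
    10184653: ("Afatinib", 365.038, 451.091, 0.128, 0.063),
    11626560: ("Crizotinib", 293.407, 579.500, 0.263, 0.187),
}


def approved_drug_assessments() -> list[CompoundAssessment]:
    """The reference drug measurements as :class:`CompoundAssessment` rows."""
    return [
        CompoundAssessment(
            compound=cid,
            rs_chemicals=rs_c,
            rs_genes=rs_g,
            pvalue_chemicals=p_c,
            pvalue_genes=p_g,
        )
        for cid, (_, rs_c, rs_g, p_c, p_g) in sorted(APPROVED_NSCLC_DRUG_TABLE.items())
    ]
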
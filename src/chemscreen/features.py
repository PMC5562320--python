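"""15-dimensional mean-interaction-score encoding of compounds.

Each compound is summarized by fifteen features on the STITCH 0-1000 scale:

* f1-f5   mean Similarity / Experimental / Database / Textmining / Combined
          of its chemical links to the approved drugs;
* f6-f10  the same five channels for links to the disease-related chemicals;
* f11-f15 mean Experimental / Prediction / Database / Textmining / Combined
          of its protein links to the disease-related genes' proteins.

Each channel is averaged over the partners with a strictly positive score
on that channel (per-channel support); a feature with empty support is 0.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from chemscreen.index import NeighborIndex, ScreenInputs, gene_partner_links

FEATURE_NAMES = tuple(
    f"{group}_{channel}"
    for group, channels in (
        ("drug", ("similarity", "experimental", "database", "textmining", "combined")),
        ("chem", ("similarity", "experimental", "database", "textmining", "combined")),
        ("gene", ("experimental", "prediction", "database", "textmining", "combined")),
    )
    for channel in channels
)


def _channel_means(score_rows: list[tuple[int, ...]]) -> list[float]:
    """Per-channel mean over strictly positive entries; 0 on empty support."""
    if not score_rows:
        return [0.0] * 5
    arr = np.asarray(score_rows, dtype=np.float64)
    out = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        pos = col[col > 0]
        out.append(float(pos.mean()) if pos.size else 0.0)
    return out


def encode(c: int, inputs: ScreenInputs, index: NeighborIndex) -> np.ndarray:
    """The 15-feature vector of compound ``c`` (see module docstring)."""
    neighbors = index.neighbors(c)
    drug_rows = [neighbors[d].channel_scores() for d in sorted(inputs.drugs) if d in neighbors]
    chem_rows = [
        neighbors[s].channel_scores()
        for s in sorted(inputs.disease_chemicals)
        if s in neighbors
    ]
    gene_rows = [
        l.channel_scores() for l in gene_partner_links(c, inputs.disease_genes, index)
    ]
    return np.array(
        _channel_means(drug_rows) + _channel_means(chem_rows) + _channel_means(gene_rows)
    )


def encode_cohort(
    compounds: Iterable[int],
    drugs: Iterable[int],
    inputs: ScreenInputs,
    index: NeighborIndex,
) -> pd.DataFrame:
    """Stacked feature vectors for candidates and drugs.

    Returns a DataFrame indexed by compound id (sorted), with an ``is_drug``
    label column followed by the fifteen feature columns.  A compound
    appearing in both sets is kept once, flagged as a drug.
    """
    drugs = set(drugs)
    ids = sorted(set(compounds) | drugs)
    rows = [encode(c, inputs, index) for c in ids]
    df = pd.DataFrame(rows, index=pd.Index(ids, name="compound"), columns=list(FEATURE_NAMES))
    df.insert(0, "is_drug", [c in drugs for c in ids])
    return df
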
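"""Parse STITCH-dialect interaction tables and look up neighbors.

Builds a tiny chemical-chemical links file inline, reads it through the
dialect parser (combined_score > 0 defines interaction) and queries the
neighbor index.
"""

import tempfile
from pathlib import Path

from chemscreen import build_index, read_chemical_links
from chemscreen.stitch_io import InteractionTables

TSV = """\
chemical_a\tchemical_b\tsimilarity\texperimental\tdatabase\ttextmining\tcombined_score
CIDm00004033\tCID36314\t120\t0\t300\t410\t520
CID36314\tCID38904\t0\t250\t0\t180\t330
CID4033\tCID57166\t0\t0\t0\t0\t0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "chemical_links.tsv"
    path.write_text(TSV)
    links = read_chemical_links(path)

index = build_index(InteractionTables(chemical_links=links))

print(f"parsed {len(links)} interacting pairs (zero-combined rows dropped)")
for link in links:
    print(f"  CID{link.chem_a} -- CID{link.chem_b}  combined={link.combined}")
print("neighbors of CID36314:", sorted(index.neighbors(36314)))
# The CIDm prefix and leading zeros are normalized away, the pair with
# combined_score 0 is not an interaction, and lookups are symmetric.
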
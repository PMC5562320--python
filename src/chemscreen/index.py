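"""Neighbor lookups over parsed interaction tables.

The screening stages only ever ask two questions: which chemicals does a
compound interact with (combined score > 0), and which proteins.  Both are
served by :class:`NeighborIndex` dictionaries built once per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from chemscreen.stitch_io import ChemicalLink, InteractionTables, ProteinLink


@dataclass
class ScreenInputs:
    """Reference sets for a screen.

    drugs
        Approved-drug compound ids.
    disease_chemicals
        Disease-related chemical set (compound ids).
    disease_genes
        Mapping gene symbol -> set of protein ids; a gene may map to
        several proteins.
    """

    drugs: set[int]
    disease_chemicals: set[int]
    disease_genes: dict[str, frozenset[str]]

    @property
    def disease_proteins(self) -> frozenset[str]:
        """Union of protein ids over all disease genes."""
        out: set[str] = set()
        for proteins in self.disease_genes.values():
            out |= proteins
        return frozenset(out)

    def validate(self) -> None:
        if not self.drugs:
            raise ValueError("drug set is empty")
        if not self.disease_chemicals:
            raise ValueError("disease chemical set is empty")
        if not self.disease_genes:
            raise ValueError("disease gene set is empty")


@dataclass
class NeighborIndex:
    """Adjacency maps over positive-combined links."""

    chem_neighbors: dict[int, dict[int, ChemicalLink]] = field(default_factory=dict)
    protein_partners: dict[int, dict[str, ProteinLink]] = field(default_factory=dict)
    chemical_universe: frozenset[int] = frozenset()
    protein_universe: frozenset[str] = frozenset()

    def neighbors(self, c: int) -> dict[int, ChemicalLink]:
        return self.chem_neighbors.get(c, {})

    def proteins_of(self, c: int) -> dict[str, ProteinLink]:
        return self.protein_partners.get(c, {})


def build_index(tables: InteractionTables) -> NeighborIndex:
    """Index the tables for O(1) neighbor lookups; chemical links symmetric."""
    chem: dict[int, dict[int, ChemicalLink]] = {}
    for link in tables.chemical_links:
        if link.combined <= 0:
            continue
        chem.setdefault(link.chem_a, {})[link.chem_b] = link
        chem.setdefault(link.chem_b, {})[link.chem_a] = link
    prot: dict[int, dict[str, ProteinLink]] = {}
    for plink in tables.protein_links:
        if plink.combined <= 0:
            continue
        prot.setdefault(plink.chemical, {})[plink.protein] = plink
    return NeighborIndex(
        chem_neighbors=chem,
        protein_partners=prot,
        chemical_universe=frozenset(chem),
        protein_universe=frozenset(p for d in prot.values() for p in d),
    )


def gene_partner_links(
    c: int,
    genes: dict[str, frozenset[str]],
    index: NeighborIndex,
) -> list[ProteinLink]:
    """Links from compound ``c`` to proteins mapped by any gene in ``genes``.

    Genes sharing a protein id contribute that protein once (set semantics);
    the result is sorted by protein id for determinism.
    """
    wanted: set[str] = set()
    for proteins in genes.values():
        wanted |= proteins
    partners = index.proteins_of(c)
    return [partners[p] for p in sorted(wanted) if p in partners]
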
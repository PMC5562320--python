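import numpy as np
import pytest

from chemscreen.index import ScreenInputs, build_index
from chemscreen.pipeline import RunConfig, load_inputs
from chemscreen.stitch_io import ChemicalLink, InteractionTables, ProteinLink, read_tables
from chemscreen.synth import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic screening fixture (seed 1)."""
    return generate_fixture(FixtureSpec(seed=1), tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def tables(bundle):
    return read_tables(bundle.chemical_links, bundle.protein_links)


@pytest.fixture(scope="session")
def index(tables):
    return build_index(tables)


@pytest.fixture(scope="session")
def inputs(bundle) -> ScreenInputs:
    cfg = RunConfig(
        chemical_links=bundle.chemical_links,
        protein_links=bundle.protein_links,
        drugs=bundle.drugs,
        disease_chemicals=bundle.disease_chemicals,
        gene_map=bundle.gene_map,
        outdir="unused",
    )
    return load_inputs(cfg)


def random_tables(rng: np.random.Generator, n_compounds: int = 50,
                  n_proteins: int = 10, p_link: float = 0.12) -> InteractionTables:
    """Small random interaction tables for oracle comparisons."""
    compounds = list(range(1, n_compounds + 1))
    proteins = [f"ENSP{i:07d}" for i in range(1, n_proteins + 1)]
    chem = []
    for i, a in enumerate(compounds):
        for b in compounds[i + 1:]:
            if rng.random() < p_link:
                scores = rng.integers(0, 1001, size=4)
                combined = int(rng.integers(1, 1001))
                chem.append(ChemicalLink(a, b, *[int(s) for s in scores], combined))
    prot = []
    for p in proteins:
        for c in compounds:
            if rng.random() < p_link:
                scores = rng.integers(0, 1001, size=4)
                combined = int(rng.integers(1, 1001))
                prot.append(ProteinLink(p, c, *[int(s) for s in scores], combined))
    return InteractionTables(chemical_links=chem, protein_links=prot)
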
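"""Synthetic STITCH-dialect fixtures with planted ground truth.

The generator emits the five input files the screening pipeline consumes
(chemical links, protein links, drug list, disease-chemical list, gene ->
protein map) plus a manifest recording each compound's intended fate:

``positive``
    mimics the approved drugs' interaction profile (strong links to drugs,
    disease chemicals and disease genes; weak background links) and should
    survive all three screening steps;
``decoy_no_drug``
    identical profile but no drug link -- fails preliminary screening;
``decoy_no_gene``
    drug and disease-chemical links but no disease-gene link -- fails the
    association test;
``decoy_nonspecific``
    promiscuous average-strength links to much of the universe, with
    disease-set links no stronger than its background links -- the observed
    rating score sits at or below its permutation-null mean, so the
    permutation test rejects it;
``background``
    sparse filler links, no guaranteed fate.

The drug cohort is heterogeneous on purpose: *strong* drugs share the
positives' profile, *weak* drugs are only mildly enriched toward the
disease sets (their moderate P-values anchor the drug-derived thresholds,
mirroring the spread seen in real screens), and one *inert* drug has no
disease links at all and drops out at the association test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chemscreen.stitch_io import (
    CHEMICAL_COLUMNS,
    PROTEIN_COLUMNS,
)

# combined-score ranges (inclusive ints) per link class; STITCH's customary
# evidence floor is 150
SCORE_RANGES: dict[str, tuple[int, int]] = {
    "strong": (700, 950),        # drug-like enrichment toward disease sets
    "low_bg": (150, 500),        # strong entities' background links
    "weak_disease": (350, 750),  # weak drugs' disease links
    "weak_bg": (300, 700),       # weak drugs' background links
    "ns_disease": (300, 600),    # nonspecific decoys' disease links
    "ns_bg": (450, 750),         # nonspecific decoys' promiscuous links
    "filler": (150, 700),        # background-background links
}

CHANNEL_DROPOUT = 0.3  # per-channel probability that a non-combined score is 0


@dataclass
class FixtureSpec:
    """Size and seed of a synthetic screening fixture."""

    n_compounds: int = 200
    n_drugs: int = 10
    n_disease_chemicals: int = 30
    n_genes: int = 15
    n_planted_positives: int = 12
    n_decoys_no_drug: int = 8
    n_decoys_no_gene: int = 8
    n_decoys_nonspecific: int = 8
    n_background_proteins: int = 60
    score_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(SCORE_RANGES)
    )
    seed: int = 0

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if name.startswith("n_") and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        planted = (
            self.n_planted_positives
            + self.n_decoys_no_drug
            + self.n_decoys_no_gene
            + self.n_decoys_nonspecific
        )
        n_background = self.n_compounds - planted
        if n_background < self.n_disease_chemicals:
            raise ValueError(
                "not enough background compounds to host the disease-chemical "
                f"set: {n_background} background vs {self.n_disease_chemicals} needed"
            )
        if self.n_drugs < 1 or self.n_genes < 1 or self.n_disease_chemicals < 1:
            raise ValueError("drugs, genes and disease chemicals must be non-empty")


@dataclass
class FixtureBundle:
    """Paths and ground truth of a generated fixture."""

    chemical_links: Path
    protein_links: Path
    drugs: Path
    disease_chemicals: Path
    gene_map: Path
    manifest: Path
    fates: dict[int, str]
    drug_roles: dict[int, str]

    def compounds_with_fate(self, fate: str) -> set[int]:
        return {c for c, f in self.fates.items() if f == fate}


def _sample_scores(
    rng: np.random.Generator, lo: int, hi: int, n_channels: int = 4
) -> tuple[int, list[int]]:
    """Combined score plus the other channels with per-channel dropout."""
    combined = int(rng.integers(lo, hi + 1))
    others = []
    for _ in range(n_channels):
        if rng.random() < CHANNEL_DROPOUT:
            others.append(0)
        else:
            others.append(int(rng.integers(lo, hi + 1)))
    return combined, others


class _ChemEdges:
    """Unordered chemical-pair store; first writer of a pair wins."""

    def __init__(self, rng: np.random.Generator, ranges: dict[str, tuple[int, int]]):
        self.rng = rng
        self.ranges = ranges
        self.edges: dict[tuple[int, int], tuple[int, int, int, int, int]] = {}

    def add(self, a: int, b: int, klass: str) -> None:
        if a == b:
            return
        key = (min(a, b), max(a, b))
        if key in self.edges:
            return
        lo, hi = self.ranges[klass]
        combined, (sim, exp, db, tm) = _sample_scores(self.rng, lo, hi)
        self.edges[key] = (sim, exp, db, tm, combined)


class _ProtEdges:
    def __init__(self, rng: np.random.Generator, ranges: dict[str, tuple[int, int]]):
        self.rng = rng
        self.ranges = ranges
        self.edges: dict[tuple[str, int], tuple[int, int, int, int, int]] = {}

    def add(self, protein: str, chemical: int, klass: str) -> None:
        key = (protein, chemical)
        if key in self.edges:
            return
        lo, hi = self.ranges[klass]
        combined, (exp, pred, db, tm) = _sample_scores(self.rng, lo, hi)
        self.edges[key] = (exp, pred, db, tm, combined)


def _choose(rng: np.random.Generator, pool: list, n: int) -> list:
    n = min(n, len(pool))
    if n <= 0:
        return []
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureBundle:
    """Write a fixture bundle to ``outdir`` and return paths + ground truth.

    Deterministic: the same spec and seed yield byte-identical files.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ranges = spec.score_ranges

    drugs = [100 + i for i in range(1, spec.n_drugs + 1)]
    compounds = [1000 + i for i in range(1, spec.n_compounds + 1)]

    # drug roles: one inert, a few weak threshold anchors, the rest strong
    n_inert = 1 if spec.n_drugs >= 5 else 0
    n_weak = 3 if spec.n_drugs >= 5 else (1 if spec.n_drugs >= 3 else 0)
    drug_roles: dict[int, str] = {}
    for i, d in enumerate(drugs):
        if i < n_inert:
            drug_roles[d] = "inert"
        elif i < n_inert + n_weak:
            drug_roles[d] = "weak"
        else:
            drug_roles[d] = "strong"
    strong_drugs = [d for d in drugs if drug_roles[d] == "strong"]
    active_drugs = [d for d in drugs if drug_roles[d] != "inert"]

    # compound fates
    fates: dict[int, str] = {}
    cursor = 0
    for fate, count in (
        ("positive", spec.n_planted_positives),
        ("decoy_no_drug", spec.n_decoys_no_drug),
        ("decoy_no_gene", spec.n_decoys_no_gene),
        ("decoy_nonspecific", spec.n_decoys_nonspecific),
    ):
        for c in compounds[cursor:cursor + count]:
            fates[c] = fate
        cursor += count
    background = compounds[cursor:]
    for c in background:
        fates[c] = "background"

    disease_chemicals = _choose(rng, background, spec.n_disease_chemicals)
    plain_background = [c for c in background if c not in set(disease_chemicals)]

    # genes and proteins
    gene_map: dict[str, list[str]] = {}
    next_protein = 1
    for g in range(1, spec.n_genes + 1):
        n_prot = int(rng.integers(1, 3))  # 1 or 2 proteins per gene
        prots = [f"ENSP{next_protein + j:07d}" for j in range(n_prot)]
        next_protein += n_prot
        gene_map[f"GENE{g}"] = prots
    disease_proteins = sorted({p for ps in gene_map.values() for p in ps})
    bg_proteins = [
        f"ENSP{next_protein + j:07d}" for j in range(spec.n_background_proteins)
    ]

    chem = _ChemEdges(rng, ranges)
    prot = _ProtEdges(rng, ranges)

    n_sc_links = max(1, round(0.6 * len(disease_chemicals)))
    n_bg_links = max(1, round(0.25 * len(plain_background)))
    n_dp_links = min(8, len(disease_proteins))
    n_bp_links = min(16, len(bg_proteins))

    # drug-drug clique
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            chem.add(a, b, "strong")

    def _disease_profile(c: int, disease_klass: str, bg_klass: str) -> None:
        for s in _choose(rng, disease_chemicals, n_sc_links):
            chem.add(c, s, disease_klass)
        for b in _choose(rng, plain_background, n_bg_links):
            chem.add(c, b, bg_klass)
        for p in _choose(rng, disease_proteins, n_dp_links):
            prot.add(p, c, disease_klass)
        for p in _choose(rng, bg_proteins, n_bp_links):
            prot.add(p, c, bg_klass)

    for d in drugs:
        role = drug_roles[d]
        if role == "strong":
            _disease_profile(d, "strong", "low_bg")
        elif role == "weak":
            _disease_profile(d, "weak_disease", "weak_bg")
        else:  # inert: background links only
            for b in _choose(rng, plain_background, 2):
                chem.add(d, b, "low_bg")

    for c in compounds:
        fate = fates[c]
        if fate == "positive":
            for d in _choose(rng, strong_drugs or active_drugs, 3):
                chem.add(c, d, "strong")
            _disease_profile(c, "strong", "low_bg")
        elif fate == "decoy_no_drug":
            _disease_profile(c, "strong", "low_bg")
        elif fate == "decoy_no_gene":
            for d in _choose(rng, strong_drugs or active_drugs, 2):
                chem.add(c, d, "strong")
            for s in _choose(rng, disease_chemicals, n_sc_links):
                chem.add(c, s, "strong")
            for b in _choose(rng, plain_background, n_bg_links):
                chem.add(c, b, "low_bg")
            for p in _choose(rng, bg_proteins, 10):
                prot.add(p, c, "low_bg")
        elif fate == "decoy_nonspecific":
            for d in _choose(rng, active_drugs, 1):
                chem.add(c, d, "ns_bg")
            for s in _choose(rng, disease_chemicals, 5):
                chem.add(c, s, "ns_disease")
            n_promiscuous = max(1, round(0.3 * len(plain_background)))
            for b in _choose(rng, plain_background, n_promiscuous):
                chem.add(c, b, "ns_bg")
            for p in _choose(rng, disease_proteins, min(6, len(disease_proteins))):
                prot.add(p, c, "ns_disease")
            for p in _choose(rng, bg_proteins, 18):
                prot.add(p, c, "ns_bg")

    # filler links keep every background compound in the chemical universe
    non_drug = compounds
    for c in background:
        for b in _choose(rng, non_drug, 2):
            chem.add(c, b, "filler")
    # anchor every protein into the protein-link table
    for p in disease_proteins + bg_proteins:
        for b in _choose(rng, plain_background, 1):
            prot.add(p, b, "low_bg")

    # ---- write files -------------------------------------------------
    chem_rows = [
        {
            "chemical_a": f"CID{a}",
            "chemical_b": f"CID{b}",
            "similarity": sim,
            "experimental": exp,
            "database": db,
            "textmining": tm,
            "combined_score": comb,
        }
        for (a, b), (sim, exp, db, tm, comb) in sorted(chem.edges.items())
    ]
    prot_rows = [
        {
            "protein": f"9606.{p}",
            "chemical": f"CID{c}",
            "experimental": exp,
            "prediction": pred,
            "database": db,
            "textmining": tm,
            "combined_score": comb,
        }
        for (p, c), (exp, pred, db, tm, comb) in sorted(prot.edges.items())
    ]

    paths = {
        "chemical_links": outdir / "chemical_links.tsv",
        "protein_links": outdir / "protein_links.tsv",
        "drugs": outdir / "drugs.txt",
        "disease_chemicals": outdir / "disease_chemicals.txt",
        "gene_map": outdir / "gene_map.tsv",
        "manifest": outdir / "manifest.tsv",
    }
    pd.DataFrame(chem_rows, columns=list(CHEMICAL_COLUMNS)).to_csv(
        paths["chemical_links"], sep="\t", index=False
    )
    pd.DataFrame(prot_rows, columns=list(PROTEIN_COLUMNS)).to_csv(
        paths["protein_links"], sep="\t", index=False
    )
    paths["drugs"].write_text(
        "# approved drugs\n" + "".join(f"CID{d}\n" for d in drugs)
    )
    paths["disease_chemicals"].write_text(
        "# disease-related chemicals\n"
        + "".join(f"CID{c}\n" for c in sorted(disease_chemicals))
    )
    paths["gene_map"].write_text(
        "".join(
            f"{gene}\t{p}\n"
            for gene in sorted(gene_map)
            for p in sorted(gene_map[gene])
        )
    )
    manifest = pd.DataFrame(
        sorted(fates.items()), columns=["compound", "planted_fate"]
    )
    manifest.to_csv(paths["manifest"], sep="\t", index=False)

    return FixtureBundle(fates=fates, drug_roles=drug_roles, **paths)


def generate_gmm_data(
    n: int, dims: int, k: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sample a diagonal-Gaussian mixture with planted unit-variance components.

    Component means are spaced ``separation`` within-component standard
    deviations apart along distinct axes; rows are split near-evenly
    across components.  Returns (data, labels, planted parameters).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    means = np.zeros((k, dims))
    for j in range(k):
        means[j, j % dims] = j * separation
    counts = [n // k + (1 if j < n % k else 0) for j in range(k)]
    X = np.vstack(
        [rng.normal(loc=means[j], scale=1.0, size=(counts[j], dims)) for j in range(k)]
    )
    labels = np.repeat(np.arange(k), counts)
    params = {"means": means, "sds": np.ones((k, dims)), "weights": np.array(counts) / n}
    return X, labels, params
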
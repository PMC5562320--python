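"""Preliminary screening, association test and permutation test.

Step 1 keeps every non-drug compound interacting with at least one approved
drug.  Step 2 first requires an association with both reference sets
(rating scores RS_c > 0 and RS_g > 0, where a rating score is the mean
combined score of a compound's existing links into the reference set), then
computes empirical P-values against random reference sets of equal size:

    P = W / n_permutations

with W the number of random sets whose rating score strictly exceeds the
observed one.  Thresholds are taken as the per-channel maxima of the
approved drugs' own P-values, and candidates with both P-values at or below
the thresholds survive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Literal, Sequence

import numpy as np

from chemscreen.index import NeighborIndex, ScreenInputs, gene_partner_links

Mode = Literal["chemicals", "genes"]

# substream tags so the chemical- and gene-side draws never collide
_STREAM = {"chemicals": 0, "genes": 1}


@dataclass
class CompoundAssessment:
    """Per-compound rating scores and (optional) permutation P-values."""

    compound: int
    rs_chemicals: float
    rs_genes: float
    pvalue_chemicals: float | None = None
    pvalue_genes: float | None = None

    def passed_association(self) -> bool:
        return self.rs_chemicals > 0 and self.rs_genes > 0


@dataclass
class PermutationConfig:
    """Configuration of the random-set null.

    universe
        Ids to sample reference sets from (compound ids for the chemical
        channel, protein ids for the gene channel).  The assessed compound
        itself is always excluded from the sampling frame.
    exhaustive
        Enumerate every subset instead of sampling (tiny universes only).
    share_sets
        Reuse one sequence of random sets for every compound in a run
        instead of per-compound substreams.
    """

    universe: frozenset = field(default_factory=frozenset)
    n_permutations: int = 1000
    seed: int = 0
    exhaustive: bool = False
    share_sets: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def preliminary_screen(index: NeighborIndex, drugs: set[int]) -> set[int]:
    """Compounds interacting with >=1 approved drug, drugs themselves excluded."""
    if not drugs:
        raise ValueError("empty drug set")
    out: set[int] = set()
    for d in drugs:
        out |= set(index.neighbors(d))
    return out - set(drugs)


def rating_score(
    c: int,
    reference: Iterable[Hashable],
    index: NeighborIndex,
    mode: Mode = "chemicals",
) -> float:
    """Mean combined score of the links between ``c`` and the reference set.

    ``reference`` holds compound ids (mode "chemicals") or protein ids
    (mode "genes").  Returns 0.0 when no link exists.
    """
    if mode == "chemicals":
        partners = index.neighbors(c)
    else:
        partners = index.proteins_of(c)
    scores = [partners[r].combined for r in reference if r in partners]
    return float(np.mean(scores)) if scores else 0.0


def assess(c: int, inputs: ScreenInputs, index: NeighborIndex) -> CompoundAssessment:
    """Rating scores of ``c`` against the disease chemical and gene sets."""
    rs_c = rating_score(c, inputs.disease_chemicals, index, mode="chemicals")
    gene_links = gene_partner_links(c, inputs.disease_genes, index)
    rs_g = float(np.mean([l.combined for l in gene_links])) if gene_links else 0.0
    return CompoundAssessment(compound=c, rs_chemicals=rs_c, rs_genes=rs_g)


def association_test(
    candidates: Iterable[int],
    inputs: ScreenInputs,
    index: NeighborIndex,
) -> list[CompoundAssessment]:
    """Keep candidates linked to >=1 disease chemical AND >=1 disease gene.

    The same rule applies when the approved drugs themselves are assessed
    for threshold derivation: drugs failing it drop out of the reference
    cohort.
    """
    out = [assess(c, inputs, index) for c in sorted(set(candidates))]
    return [a for a in out if a.passed_association()]


def _score_vector(
    c: int, universe: Sequence, index: NeighborIndex, mode: Mode
) -> np.ndarray:
    partners = index.neighbors(c) if mode == "chemicals" else index.proteins_of(c)
    return np.array(
        [partners[u].combined if u in partners else 0 for u in universe],
        dtype=np.float64,
    )


def _set_scores(scores: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Rating score of each sampled set (rows of ``idx`` index into scores)."""
    picked = scores[idx]
    sums = picked.sum(axis=1)
    counts = (picked > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return rs


def permute_pvalue(
    c: int,
    observed_rs: float,
    reference_size: int,
    cfg: PermutationConfig,
    index: NeighborIndex,
    mode: Mode = "chemicals",
) -> float:
    """Empirical P-value of ``observed_rs`` against random reference sets.

    Draws ``cfg.n_permutations`` sets of ``reference_size`` ids without
    replacement from ``cfg.universe`` (minus ``c``), scores each with
    :func:`rating_score` semantics, and returns the fraction strictly
    exceeding the observed score.  In exhaustive mode every subset is
    enumerated and the exact fraction returned.
    """
    universe = sorted(u for u in cfg.universe if u != c)
    if reference_size > len(universe):
        raise ValueError(
            f"reference_size {reference_size} exceeds universe size {len(universe)}"
        )
    if reference_size < 1:
        raise ValueError("reference_size must be >= 1")
    scores = _score_vector(c, universe, index, mode)

    if cfg.exhaustive:
        combos = np.array(
            list(itertools.combinations(range(len(universe)), reference_size)),
            dtype=np.intp,
        )
        rs = _set_scores(scores, combos)
        return float((rs > observed_rs).sum() / len(rs))

    if cfg.share_sets:
        rng = np.random.default_rng([cfg.seed, _STREAM[mode]])
    else:
        rng = np.random.default_rng([cfg.seed, _STREAM[mode], c])
    n = cfg.n_permutations
    u = len(universe)
    w = 0
    chunk = max(1, min(n, 20_000_000 // max(u, 1)))
    done = 0
    while done < n:
        m = min(chunk, n - done)
        idx = rng.permuted(
            np.broadcast_to(np.arange(u, dtype=np.intp), (m, u)).copy(), axis=1
        )[:, :reference_size]
        rs = _set_scores(scores, idx)
        w += int((rs > observed_rs).sum())
        done += m
    return w / n


def permute_assessments(
    assessments: Iterable[CompoundAssessment],
    inputs: ScreenInputs,
    index: NeighborIndex,
    n_permutations: int = 1000,
    seed: int = 0,
    share_sets: bool = False,
) -> list[CompoundAssessment]:
    """Fill both P-value channels for a batch of assessments.

    Chemical-channel sets are drawn from the chemical universe with the size
    of the disease chemical set; gene-channel sets from the protein
    universe with the size of the disease genes' mapped protein set.
    """
    cfg_c = PermutationConfig(
        universe=index.chemical_universe,
        n_permutations=n_permutations,
        seed=seed,
        share_sets=share_sets,
    )
    cfg_g = replace(cfg_c, universe=index.protein_universe)
    size_c = len(inputs.disease_chemicals)
    size_g = len(inputs.disease_proteins)
    out = []
    for a in assessments:
        p_c = permute_pvalue(a.compound, a.rs_chemicals, size_c, cfg_c, index, "chemicals")
        p_g = permute_pvalue(a.compound, a.rs_genes, size_g, cfg_g, index, "genes")
        out.append(replace(a, pvalue_chemicals=p_c, pvalue_genes=p_g))
    return out


def select_thresholds(
    drug_assessments: Sequence[CompoundAssessment],
) -> tuple[float, float]:
    """Per-channel maxima of the approved drugs' P-values."""
    if not drug_assessments:
        raise ValueError("no drug assessments to derive thresholds from")
    for a in drug_assessments:
        if a.pvalue_chemicals is None or a.pvalue_genes is None:
            raise ValueError(f"P-values unset for drug {a.compound}")
    return (
        max(a.pvalue_chemicals for a in drug_assessments),
        max(a.pvalue_genes for a in drug_assessments),
    )


def apply_thresholds(
    assessments: Iterable[CompoundAssessment],
    thresholds: tuple[float, float],
) -> list[CompoundAssessment]:
    """Keep compounds with both P-values <= the thresholds (inclusive)."""
    t_c, t_g = thresholds
    out = []
    for a in assessments:
        if a.pvalue_chemicals is None or a.pvalue_genes is None:
            raise ValueError(f"P-values unset for compound {a.compound}")
        if a.pvalue_chemicals <= t_c and a.pvalue_genes <= t_g:
            out.append(a)
    return out
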
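"""End-to-end orchestration of the three screening steps.

``run_pipeline`` wires the stages together: parse the interaction tables,
screen for drug neighbors, apply the association and permutation tests with
drug-derived thresholds, then iteratively co-cluster survivors with the
approved drugs; outputs (assessments, features, cluster labels, subnetwork
edges, report) are written as TSV with commented headers recording version,
seed and configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

import chemscreen
from chemscreen import em as em_mod
from chemscreen import screening as scr
from chemscreen.features import FEATURE_NAMES, encode_cohort
from chemscreen.index import NeighborIndex, ScreenInputs, build_index
from chemscreen.stitch_io import read_compound_list, read_gene_map, read_tables

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a screening run."""

    chemical_links: Path
    protein_links: Path
    drugs: Path
    disease_chemicals: Path
    gene_map: Path
    outdir: Path
    organism: str = "9606"
    n_permutations: int = 1000
    seed: int = 0
    threshold_overrides: tuple[float, float] | None = None
    folds: int = 10
    k_max: int = 10
    tol: float = 1e-6
    max_iter: int = 100
    policy: str = "plurality"
    rounds: int = 2
    share_sets: bool = False

    def __post_init__(self) -> None:
        for name in ("chemical_links", "protein_links", "drugs",
                     "disease_chemicals", "gene_map", "outdir"):
            setattr(self, name, Path(getattr(self, name)))

    def validate(self) -> None:
        for name in ("chemical_links", "protein_links", "drugs",
                     "disease_chemicals", "gene_map"):
            p: Path = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-stage counts and the final putative compounds."""

    seed: int
    config_hash: str
    n_preliminary: int = 0
    n_association: int = 0
    n_permutation: int = 0
    thresholds: tuple[float, float] | None = None
    drug_cohort: list[int] = field(default_factory=list)
    clustering_audit: list[dict] = field(default_factory=list)
    putative: list[scr.CompoundAssessment] = field(default_factory=list)
    stopped_at: str | None = None

    @property
    def putative_compounds(self) -> set[int]:
        return {a.compound for a in self.putative}


def load_inputs(cfg: RunConfig) -> ScreenInputs:
    return ScreenInputs(
        drugs=read_compound_list(cfg.drugs),
        disease_chemicals=read_compound_list(cfg.disease_chemicals),
        disease_genes=read_gene_map(cfg.gene_map),
    )


def _header(cfg: RunConfig) -> str:
    return (
        f"# chemscreen {chemscreen.__version__}\n"
        f"# seed: {cfg.seed}\n"
        f"# config: {cfg.config_hash()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index)


def _assessment_frame(assessments, drugs: set[int]) -> pd.DataFrame:
    rows = [
        {
            "compound": a.compound,
            "is_drug": a.compound in drugs,
            "rs_chemicals": a.rs_chemicals,
            "rs_genes": a.rs_genes,
            "pvalue_chemicals": a.pvalue_chemicals,
            "pvalue_genes": a.pvalue_genes,
        }
        for a in sorted(assessments, key=lambda a: a.compound)
    ]
    return pd.DataFrame(
        rows,
        columns=["compound", "is_drug", "rs_chemicals", "rs_genes",
                 "pvalue_chemicals", "pvalue_genes"],
    )


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run preliminary screen -> association/permutation -> EM co-clustering.

    Fully deterministic under a fixed seed.  Any stage yielding an empty
    set ends the run cleanly with the report filled up to that stage.
    """
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed, config_hash=cfg.config_hash())
    t0 = time.perf_counter()

    tables = read_tables(cfg.chemical_links, cfg.protein_links, organism=cfg.organism)
    index = build_index(tables)
    inputs = load_inputs(cfg)
    inputs.validate()
    logger.info("parsed %d chemical links, %d protein links in %.2fs",
                len(tables.chemical_links), len(tables.protein_links),
                time.perf_counter() - t0)

    # step 1: preliminary screening
    t1 = time.perf_counter()
    candidates = scr.preliminary_screen(index, inputs.drugs)
    report.n_preliminary = len(candidates)
    logger.info("step 1: %d compounds interact with >=1 drug (%.2fs)",
                len(candidates), time.perf_counter() - t1)
    if not candidates:
        report.stopped_at = "preliminary"
        _write_report(report, cfg)
        return report

    # step 2: association test, then permutation test
    t2 = time.perf_counter()
    assessed = scr.association_test(candidates, inputs, index)
    report.n_association = len(assessed)
    drug_assessed = scr.association_test(inputs.drugs, inputs, index)
    report.drug_cohort = [a.compound for a in drug_assessed]
    logger.info("step 2a: %d candidates and %d/%d drugs pass the association test",
                len(assessed), len(drug_assessed), len(inputs.drugs))
    if not assessed or not drug_assessed:
        report.stopped_at = "association"
        _write_report(report, cfg)
        return report

    assessed = scr.permute_assessments(
        assessed, inputs, index,
        n_permutations=cfg.n_permutations, seed=cfg.seed, share_sets=cfg.share_sets,
    )
    drug_assessed = scr.permute_assessments(
        drug_assessed, inputs, index,
        n_permutations=cfg.n_permutations, seed=cfg.seed, share_sets=cfg.share_sets,
    )
    thresholds = cfg.threshold_overrides or scr.select_thresholds(drug_assessed)
    report.thresholds = tuple(thresholds)
    survivors = scr.apply_thresholds(assessed, thresholds)
    report.n_permutation = len(survivors)
    _write_tsv(
        _assessment_frame(assessed + drug_assessed, inputs.drugs),
        cfg.outdir / "assessments.tsv", cfg,
    )
    logger.info("step 2b: thresholds (%.3f, %.3f); %d candidates survive (%.2fs)",
                thresholds[0], thresholds[1], len(survivors),
                time.perf_counter() - t2)
    if not survivors:
        report.stopped_at = "permutation"
        _write_report(report, cfg)
        return report

    # step 3: iterative EM co-clustering with the passing drugs
    t3 = time.perf_counter()
    survivor_ids = {a.compound for a in survivors}
    drug_ids = {a.compound for a in drug_assessed}
    cohort = encode_cohort(survivor_ids, drug_ids, inputs, index)
    _write_tsv(cohort, cfg.outdir / "features.tsv", cfg, index=True)
    final_ids, audit = em_mod.iterative_refine(
        survivor_ids, drug_ids, inputs, index,
        rounds=cfg.rounds, folds=cfg.folds, k_max=cfg.k_max,
        seed=cfg.seed, tol=cfg.tol, max_iter=cfg.max_iter, policy=cfg.policy,
    )
    report.clustering_audit = audit
    report.putative = [a for a in survivors if a.compound in final_ids]
    logger.info("step 3: %d putative compounds after %d round(s) (%.2fs)",
                len(final_ids), len(audit), time.perf_counter() - t3)

    _write_tsv(
        _assessment_frame(report.putative, inputs.drugs),
        cfg.outdir / "putative.tsv", cfg,
    )
    edges = export_subnetwork(report, inputs, index)
    _write_tsv(edges, cfg.outdir / "subnetwork.tsv", cfg)
    _write_report(report, cfg)
    return report


def _write_report(report: RunReport, cfg: RunConfig) -> None:
    payload = {
        "seed": report.seed,
        "config_hash": report.config_hash,
        "n_preliminary": report.n_preliminary,
        "n_association": report.n_association,
        "n_permutation": report.n_permutation,
        "thresholds": list(report.thresholds) if report.thresholds else None,
        "drug_cohort": report.drug_cohort,
        "clustering_audit": report.clustering_audit,
        "putative": sorted(report.putative_compounds),
        "stopped_at": report.stopped_at,
    }
    (cfg.outdir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")


def export_subnetwork(
    report: RunReport,
    inputs: ScreenInputs,
    index: NeighborIndex,
) -> pd.DataFrame:
    """Weighted edge list among putative compounds, drugs and disease proteins.

    Every positive-combined chemical-chemical edge within {putative} U
    {drugs} and every protein-chemical edge from those compounds to the
    disease genes' proteins is emitted, weighted by its combined score.
    """
    putative = report.putative_compounds
    node_compounds = sorted(putative | inputs.drugs)
    disease_proteins = inputs.disease_proteins

    def node_type(c: int) -> str:
        return "drug" if c in inputs.drugs else "putative"

    rows = []
    for i, a in enumerate(node_compounds):
        neighbors = index.neighbors(a)
        for b in node_compounds[i + 1:]:
            if b in neighbors:
                rows.append(
                    {
                        "source": f"CID{a}", "target": f"CID{b}",
                        "source_type": node_type(a), "target_type": node_type(b),
                        "weight": neighbors[b].combined,
                    }
                )
        for p, link in sorted(index.proteins_of(a).items()):
            if p in disease_proteins:
                rows.append(
                    {
                        "source": f"CID{a}", "target": p,
                        "source_type": node_type(a), "target_type": "protein",
                        "weight": link.combined,
                    }
                )
    return pd.DataFrame(
        rows, columns=["source", "target", "source_type", "target_type", "weight"]
    )
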
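"""Readers and writers for STITCH detailed-links TSV dialects.

Two tables are understood:

* chemical-chemical links with five evidence channels
  (``similarity``, ``experimental``, ``database``, ``textmining``,
  ``combined_score``), undirected;
* protein-chemical links with five channels (``experimental``,
  ``prediction``, ``database``, ``textmining``, ``combined_score``) and
  organism-prefixed protein identifiers such as ``9606.ENSP00000123456``.

All scores are dimensionless integers on the STITCH 0-1000 scale.  A link
*exists* (for screening purposes) iff its combined score is strictly
positive; other channels are carried along for the feature encoder only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

CHEMICAL_COLUMNS = (
    "chemical_a",
    "chemical_b",
    "similarity",
    "experimental",
    "database",
    "textmining",
    "combined_score",
)
PROTEIN_COLUMNS = (
    "protein",
    "chemical",
    "experimental",
    "prediction",
    "database",
    "textmining",
    "combined_score",
)

_CID_RE = re.compile(r"^(?:CID([ms]?)0*)?(\d+)$")


class StitchParseError(ValueError):
    """Malformed identifier or score in a STITCH-dialect file."""


class StitchSchemaError(ValueError):
    """Required column missing from a STITCH-dialect file."""


def normalize_cid(raw_id: str, flatten_stereo: bool = True) -> int:
    """Parse a PubChem compound identifier to its integer CID.

    Accepts ``CID<digits>``, STITCH's ``CIDm<digits>`` (merged) and
    ``CIDs<digits>`` (stereo-specific) encodings, and bare digits.  Leading
    zeros are stripped.  With ``flatten_stereo`` (default) the flavor letter
    is discarded; otherwise the flavor is still folded into the same integer
    CID but callers may inspect it via :func:`cid_flavor`.
    """
    m = _CID_RE.match(raw_id.strip())
    if not m:
        raise StitchParseError(f"malformed compound identifier: {raw_id!r}")
    return int(m.group(2))


def cid_flavor(raw_id: str) -> str:
    """Return the STITCH CID flavor: 'm' (merged), 's' (stereo) or '' (plain)."""
    m = _CID_RE.match(raw_id.strip())
    if not m:
        raise StitchParseError(f"malformed compound identifier: {raw_id!r}")
    return m.group(1) or ""


@dataclass(frozen=True, order=True)
class ChemicalLink:
    """Undirected chemical-chemical link; ``chem_a < chem_b`` canonically."""

    chem_a: int
    chem_b: int
    similarity: int
    experimental: int
    database: int
    textmining: int
    combined: int

    def __post_init__(self) -> None:
        if self.chem_a == self.chem_b:
            raise ValueError(f"self-link for compound {self.chem_a}")
        if self.chem_a > self.chem_b:
            a, b = self.chem_b, self.chem_a
            object.__setattr__(self, "chem_a", a)
            object.__setattr__(self, "chem_b", b)
        for name in ("similarity", "experimental", "database", "textmining", "combined"):
            v = getattr(self, name)
            if not 0 <= v <= 1000:
                raise ValueError(f"{name} score {v} outside [0, 1000]")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.chem_a, self.chem_b)

    def channel_scores(self) -> tuple[int, int, int, int, int]:
        return (self.similarity, self.experimental, self.database,
                self.textmining, self.combined)


@dataclass(frozen=True, order=True)
class ProteinLink:
    """Protein-chemical link; ``protein`` is organism-stripped (e.g. ENSP...)."""

    protein: str
    chemical: int
    experimental: int
    prediction: int
    database: int
    textmining: int
    combined: int

    def __post_init__(self) -> None:
        for name in ("experimental", "prediction", "database", "textmining", "combined"):
            v = getattr(self, name)
            if not 0 <= v <= 1000:
                raise ValueError(f"{name} score {v} outside [0, 1000]")

    def channel_scores(self) -> tuple[int, int, int, int, int]:
        return (self.experimental, self.prediction, self.database,
                self.textmining, self.combined)


@dataclass
class InteractionTables:
    """Parsed chemical-chemical and protein-chemical interaction tables."""

    chemical_links: list[ChemicalLink] = field(default_factory=list)
    protein_links: list[ProteinLink] = field(default_factory=list)

    @property
    def chemical_universe(self) -> set[int]:
        """All compound ids appearing in the chemical-chemical table."""
        out: set[int] = set()
        for link in self.chemical_links:
            out.add(link.chem_a)
            out.add(link.chem_b)
        return out

    @property
    def protein_universe(self) -> set[str]:
        """All protein ids appearing in the protein-chemical table."""
        return {link.protein for link in self.protein_links}


def _read_tsv(path: str | Path, columns: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    except pd.errors.EmptyDataError:
        raise StitchSchemaError(f"{path}: empty file with no header row")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StitchSchemaError(f"{path}: missing column(s) {missing}")
    return df


def _int_scores(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise StitchParseError(
                f"{path}: non-integer score in column {c!r} at line {line}"
            )
        df[c] = vals.astype(int)
    return df


def read_chemical_links(path: str | Path, min_combined: int = 0) -> list[ChemicalLink]:
    """Read a ``chemical_chemical.links.detailed`` TSV (optionally gzipped).

    Records with combined score <= ``min_combined`` are dropped (the
    screening definition of interaction is combined > 0).  Duplicate
    orientations of the same unordered pair are merged; if the duplicate
    carries conflicting scores the record with the larger combined score
    wins and a warning is logged.
    """
    path = Path(path)
    df = _read_tsv(path, CHEMICAL_COLUMNS)
    score_cols = list(CHEMICAL_COLUMNS[2:])
    df = _int_scores(df, score_cols, path)

    seen: dict[tuple[int, int], ChemicalLink] = {}
    for row in df.itertuples(index=False):
        a = normalize_cid(row.chemical_a)
        b = normalize_cid(row.chemical_b)
        if row.combined_score <= min_combined:
            continue
        link = ChemicalLink(
            chem_a=a,
            chem_b=b,
            similarity=row.similarity,
            experimental=row.experimental,
            database=row.database,
            textmining=row.textmining,
            combined=row.combined_score,
        )
        prev = seen.get(link.pair)
        if prev is None:
            seen[link.pair] = link
        elif prev != link:
            winner = link if link.combined > prev.combined else prev
            logger.warning(
                "conflicting scores for pair %s; keeping combined=%d",
                link.pair, winner.combined,
            )
            seen[link.pair] = winner
    return sorted(seen.values())


def read_protein_links(path: str | Path, organism: str = "9606") -> list[ProteinLink]:
    """Read a ``protein_chemical.links.detailed`` TSV, keeping one organism.

    Only records whose protein identifier carries the configured organism
    prefix (``<organism>.<protein-id>``) are retained; the prefix is
    stripped.  Records with combined score <= 0 are dropped.
    """
    path = Path(path)
    df = _read_tsv(path, PROTEIN_COLUMNS)
    score_cols = list(PROTEIN_COLUMNS[2:])
    df = _int_scores(df, score_cols, path)

    prefix = organism + "."
    seen: dict[tuple[str, int], ProteinLink] = {}
    for row in df.itertuples(index=False):
        if not str(row.protein).startswith(prefix):
            continue
        if row.combined_score <= 0:
            continue
        link = ProteinLink(
            protein=str(row.protein)[len(prefix):],
            chemical=normalize_cid(row.chemical),
            experimental=row.experimental,
            prediction=row.prediction,
            database=row.database,
            textmining=row.textmining,
            combined=row.combined_score,
        )
        key = (link.protein, link.chemical)
        prev = seen.get(key)
        if prev is None:
            seen[key] = link
        elif prev != link:
            winner = link if link.combined > prev.combined else prev
            logger.warning(
                "conflicting scores for protein-chemical pair %s; keeping combined=%d",
                key, winner.combined,
            )
            seen[key] = winner
    return sorted(seen.values())


def read_tables(
    chemical_path: str | Path,
    protein_path: str | Path,
    organism: str = "9606",
    min_combined: int = 0,
) -> InteractionTables:
    """Read both link tables into one :class:`InteractionTables`."""
    return InteractionTables(
        chemical_links=read_chemical_links(chemical_path, min_combined=min_combined),
        protein_links=read_protein_links(protein_path, organism=organism),
    )


def write_chemical_links(links: Iterable[ChemicalLink], path: str | Path) -> None:
    """Write links back to the chemical_chemical.links.detailed dialect."""
    rows = [
        {
            "chemical_a": f"CID{l.chem_a}",
            "chemical_b": f"CID{l.chem_b}",
            "similarity": l.similarity,
            "experimental": l.experimental,
            "database": l.database,
            "textmining": l.textmining,
            "combined_score": l.combined,
        }
        for l in sorted(links)
    ]
    pd.DataFrame(rows, columns=list(CHEMICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_protein_links(
    links: Iterable[ProteinLink], path: str | Path, organism: str = "9606"
) -> None:
    """Write links back to the protein_chemical.links.detailed dialect."""
    rows = [
        {
            "protein": f"{organism}.{l.protein}",
            "chemical": f"CID{l.chemical}",
            "experimental": l.experimental,
            "prediction": l.prediction,
            "database": l.database,
            "textmining": l.textmining,
            "combined_score": l.combined,
        }
        for l in sorted(links)
    ]
    pd.DataFrame(rows, columns=list(PROTEIN_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_compound_list(path: str | Path) -> set[int]:
    """Read a plain-text compound list: one id per line, '#' comments allowed."""
    out: set[int] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.add(normalize_cid(line))
    return out


def read_gene_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV mapping gene symbol -> protein id.

    A gene may map to several protein ids (one row per mapping).  Lines
    starting with '#' are ignored.
    """
    mapping: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise StitchParseError(f"{path}: expected two tab-separated fields: {raw!r}")
        gene, protein = parts[0].strip(), parts[1].strip()
        mapping.setdefault(gene, set()).add(protein)
    return {g: frozenset(ps) for g, ps in mapping.items()}
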
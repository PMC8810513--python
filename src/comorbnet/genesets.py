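"""Disease gene lists: reading, GDA filtering, merging, and intersection.

Gene–disease association (GDA) catalogues such as DisGeNET attach a
confidence score in [0, 1] to each gene; literature-curated lists usually
carry no score.  This module treats the integer Entrez identifier as the
canonical key (symbols are metadata only) and provides the set algebra
needed to build per-disease gene lists and their shared-gene intersection.
"""

from __future__ import annotations

import numbers
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class GeneListError(Exception):
    """Base class for gene-list problems."""


class UnreadableGeneListError(GeneListError):
    """The gene-list file does not exist or cannot be parsed as TSV."""


class InvalidGeneIDError(GeneListError):
    """A gene identifier is not a positive integer."""


class EmptyGeneListError(GeneListError):
    """The file contains no data rows after the header."""


_SOURCE_SPLIT = re.compile(r"[,;/|]")

# recognised (lower-cased) header names, in priority order
_ID_COLUMNS = ("gene_id", "geneid", "entrez_id", "entrez", "entrezgene", "id", "gene")
_SYMBOL_COLUMNS = ("symbol", "gene_symbol", "genesymbol")
_SOURCE_COLUMNS = ("sources", "source", "gene_source")
_SCORE_COLUMNS = ("gda_score", "gda", "score")


@dataclass(frozen=True)
class GeneRecord:
    """A single gene with provenance and an optional GDA confidence score."""

    gene_id: int
    symbol: str = ""
    sources: frozenset[str] = frozenset()
    gda_score: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.gene_id, bool) or not isinstance(self.gene_id, numbers.Integral):
            raise InvalidGeneIDError(f"gene_id must be an integer, got {self.gene_id!r}")
        object.__setattr__(self, "gene_id", int(self.gene_id))
        if self.gene_id <= 0:
            raise InvalidGeneIDError(f"gene_id must be positive, got {self.gene_id}")
        if self.gda_score is not None and not (0.0 <= self.gda_score <= 1.0):
            raise ValueError(f"gda_score must lie in [0, 1], got {self.gda_score}")
        object.__setattr__(self, "sources", frozenset(self.sources))


@dataclass
class GeneSet:
    """A disease-labelled collection of unique gene records.

    Records are kept sorted by ascending ``gene_id`` so that every
    downstream table and file diff is stable.
    """

    disease_label: str
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene_id in GeneSet {self.disease_label!r}")
        self.records = sorted(self.records, key=lambda r: r.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: int) -> bool:
        return gene_id in self.gene_ids

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> frozenset[int]:
        return frozenset(r.gene_id for r in self.records)

    def get(self, gene_id: int) -> GeneRecord | None:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        return None


def _pick_column(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def _parse_sources(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return frozenset()
    parts = _SOURCE_SPLIT.split(str(value))
    return frozenset(p.strip().lower() for p in parts if p.strip())


def _collapse(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Collapse duplicate gene_ids: union sources, keep the maximum score."""
    merged: dict[int, GeneRecord] = {}
    for rec in records:
        prev = merged.get(rec.gene_id)
        if prev is None:
            merged[rec.gene_id] = rec
            continue
        score = prev.gda_score
        if rec.gda_score is not None and (score is None or rec.gda_score > score):
            score = rec.gda_score
        merged[rec.gene_id] = replace(
            prev,
            symbol=prev.symbol or rec.symbol,
            sources=prev.sources | rec.sources,
            gda_score=score,
        )
    return [merged[g] for g in sorted(merged)]


def read_gene_list(path: str | Path, disease_label: str) -> GeneSet:
    """Read a TSV gene list into a :class:`GeneSet`.

    The header must name a gene-ID column (``gene_id``, ``entrez_id``,
    ...); symbol, source, and GDA-score columns are optional.  Duplicate
    rows for the same gene are collapsed with sources unioned and the
    maximum score kept.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise UnreadableGeneListError(f"cannot read gene list {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise EmptyGeneListError(f"gene list {path} is empty") from exc
    if frame.empty:
        raise EmptyGeneListError(f"gene list {path} has no rows after the header")

    id_col = _pick_column(frame.columns, _ID_COLUMNS) or frame.columns[0]
    sym_col = _pick_column(frame.columns, _SYMBOL_COLUMNS)
    src_col = _pick_column(frame.columns, _SOURCE_COLUMNS)
    score_col = _pick_column(frame.columns, _SCORE_COLUMNS)

    records = []
    for _, row in frame.iterrows():
        raw = str(row[id_col]).strip()
        try:
            gene_id = int(raw)
        except ValueError as exc:
            raise InvalidGeneIDError(f"non-integer gene ID {raw!r} in {path}") from exc
        score = None
        if score_col is not None and str(row[score_col]).strip() != "":
            score = float(row[score_col])
        records.append(
            GeneRecord(
                gene_id=gene_id,
                symbol=str(row[sym_col]).strip() if sym_col else "",
                sources=_parse_sources(row[src_col]) if src_col else frozenset(),
                gda_score=score,
            )
        )
    return GeneSet(disease_label=disease_label, records=_collapse(records))


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    """Write a GeneSet as a sorted four-column TSV."""
    rows = [
        {
            "gene_id": r.gene_id,
            "symbol": r.symbol,
            "sources": ",".join(sorted(r.sources)),
            "gda_score": "" if r.gda_score is None else repr(r.gda_score),
        }
        for r in gene_set.records
    ]
    pd.DataFrame(rows, columns=["gene_id", "symbol", "sources", "gda_score"]).to_csv(
        path, sep="\t", index=False
    )


def filter_by_gda(
    records: Iterable[GeneRecord], threshold: float, strict: bool = True
) -> list[GeneRecord]:
    """Keep records whose GDA score exceeds ``threshold``.

    With ``strict`` (default) the inequality is strict — a score equal to
    the threshold is excluded, matching the "score > 0.2" convention.
    Records lacking a score are dropped.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if strict:
        return [r for r in records if r.gda_score is not None and r.gda_score > threshold]
    return [r for r in records if r.gda_score is not None and r.gda_score >= threshold]


def apply_gda_policy(gene_set: GeneSet, threshold: float, strict: bool = True) -> GeneSet:
    """Pipeline GDA policy: unscored (literature) records pass; scored
    records must exceed the threshold.  This is the union semantics under
    which a literature list without scores merges with a score-filtered
    database list."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    unscored = [r for r in gene_set.records if r.gda_score is None]
    scored = filter_by_gda(gene_set.records, threshold, strict=strict)
    return GeneSet(gene_set.disease_label, _collapse(unscored + scored))


def merge_gene_sets(a: GeneSet, b: GeneSet, disease_label: str) -> GeneSet:
    """Union of two gene sets by gene_id; sources unioned per gene."""
    return GeneSet(disease_label, _collapse(list(a.records) + list(b.records)))


def intersect_gene_sets(a: GeneSet, b: GeneSet, disease_label: str | None = None) -> GeneSet:
    """Genes present in both sets, sources unioned, sorted by gene_id."""
    common = a.gene_ids & b.gene_ids
    label = disease_label or f"{a.disease_label}&{b.disease_label}"
    picked = [r for r in a.records if r.gene_id in common]
    picked += [r for r in b.records if r.gene_id in common]
    return GeneSet(label, _collapse(picked))
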
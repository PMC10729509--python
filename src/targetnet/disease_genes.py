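"""Assembly of the disease gene set from per-source tables plus the DEG screen.

Each disease-gene database snapshot carries its own inclusion rule:

* CTD — keep records whose Direct Evidence tag is ``marker/mechanism``,
  ``marker/mechanism|therapeutic`` or ``therapeutic``;
* DisGeNET — gene-disease association score strictly greater than 0.1;
* GeneCards — relevance score strictly greater than 5;
* OMIM — a definite (non-empty) Entrez gene id;
* PharmGKB / TTD / custom — keep everything.

Filtered source genes are unioned with the differential-expression hits after
canonicalising symbols through an offline synonym table (upper-case canonical
form; live nomenclature services are out of contract).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import EmptyResultError

logger = logging.getLogger(__name__)

SOURCE_NAMES = {"CTD", "DisGeNET", "GeneCards", "OMIM", "PharmGKB", "TTD", "custom"}

#: CTD Direct Evidence tags retained (whitespace around '|' is normalised away).
CTD_KEEP_EVIDENCE = {"marker/mechanism", "marker/mechanism|therapeutic", "therapeutic"}

DISGENET_SCORE_MIN = 0.1  # strict
GENECARDS_SCORE_MIN = 5.0  # strict


@dataclass(frozen=True)
class SourceRecord:
    symbol: str
    score: Optional[float] = None
    evidence: Optional[str] = None
    entrez_id: Optional[str] = None


@dataclass(frozen=True)
class SourceTable:
    """One disease-gene database snapshot with the rows it exported."""

    source_name: str
    records: tuple[SourceRecord, ...]

    def __post_init__(self) -> None:
        if self.source_name not in SOURCE_NAMES:
            raise ValueError(f"unknown source {self.source_name!r}")
        if not self.records:
            raise ValueError("source table must contain at least one record")

    @classmethod
    def from_tsv(cls, path, source_name: str) -> "SourceTable":
        """Read a snapshot TSV with columns symbol[, score][, evidence][, entrez_id]."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            score = d.get("score")
            records.append(
                SourceRecord(
                    symbol=str(d["symbol"]),
                    score=float(score) if score not in (None, "") and pd.notna(score) else None,
                    evidence=d.get("evidence") if pd.notna(d.get("evidence", None)) else None,
                    entrez_id=d.get("entrez_id") if pd.notna(d.get("entrez_id", None)) else None,
                )
            )
        return cls(source_name=source_name, records=tuple(records))


@dataclass(frozen=True)
class GeneUniverse:
    """Offline alias -> canonical symbol table (idempotent on canonical symbols)."""

    canonical: dict
    members: frozenset

    @classmethod
    def from_aliases(cls, aliases: dict) -> "GeneUniverse":
        canon = {}
        for alias, target in aliases.items():
            canon[alias.upper()] = target.upper()
        members = frozenset(canon.values())
        for m in members:  # canonical symbols map to themselves
            canon.setdefault(m, m)
        return cls(canonical=canon, members=members)

    @classmethod
    def from_tsv(cls, path) -> "GeneUniverse":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_aliases(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def canonicalize(self, symbol: str) -> str:
        s = str(symbol).upper()
        return self.canonical.get(s, s)


def _normalize_evidence(evidence: str) -> str:
    return "".join(evidence.split())


def filter_source(table: SourceTable) -> set:
    """Apply the per-database inclusion rule and return the surviving symbols."""
    name = table.source_name
    kept: set = set()
    dropped_missing = 0
    for rec in table.records:
        if name == "CTD":
            if rec.evidence and _normalize_evidence(rec.evidence) in CTD_KEEP_EVIDENCE:
                kept.add(rec.symbol)
        elif name == "DisGeNET":
            if rec.score is None:
                dropped_missing += 1
            elif rec.score > DISGENET_SCORE_MIN:
                kept.add(rec.symbol)
        elif name == "GeneCards":
            if rec.score is None:
                dropped_missing += 1
            elif rec.score > GENECARDS_SCORE_MIN:
                kept.add(rec.symbol)
        elif name == "OMIM":
            if rec.entrez_id is not None and str(rec.entrez_id).strip():
                kept.add(rec.symbol)
        else:  # PharmGKB, TTD, custom: keep all
            kept.add(rec.symbol)
    if dropped_missing:
        logger.warning(
            "%s: dropped %d record(s) with missing score", name, dropped_missing
        )
    return kept


def assemble_disease_set(
    deg_genes: Iterable[str],
    sources: Iterable[SourceTable],
    universe: Optional[GeneUniverse] = None,
) -> set:
    """Union the DEG hits with all filtered sources under canonical symbols.

    Symbols absent from the synonym table pass through upper-cased with a
    logged note.  An empty total union aborts the pipeline.
    """
    raw: set = set(deg_genes)
    for table in sources:
        raw |= filter_source(table)
    if universe is None:
        out = {str(s).upper() for s in raw}
    else:
        out = set()
        unknown = 0
        for s in raw:
            c = universe.canonicalize(s)
            if c not in universe.members:
                unknown += 1
            out.add(c)
        if unknown:
            logger.info("%d symbol(s) not in synonym table passed through", unknown)
    if not out:
        raise EmptyResultError("disease gene set is empty; pipeline cannot proceed")
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
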
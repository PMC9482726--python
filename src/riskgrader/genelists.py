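"""Validate discovered gene sets against external autism gene lists.

Emulates the five-database validation step (AutismKB, SFARI, HuVarBase,
DisGeNET, OpenTargets): each source is a plain-text file of gene symbols,
one per line; a query gene is "known" when it appears in the union of the
sources and "novel" otherwise. Matching is exact after case-folding to
upper case — no HGNC alias resolution is attempted, since database exports
vary by version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    query_name: str
    known: set[str]
    novel: set[str]
    per_source: dict[str, set[str]]

    @property
    def counts(self) -> tuple[int, int]:
        """(novel n, known n), the layout of a per-severity validation row."""
        return len(self.novel), len(self.known)

    def to_json(self) -> str:
        return json.dumps(
            {
                "query": self.query_name,
                "n_novel": len(self.novel),
                "n_known": len(self.known),
                "novel": sorted(self.novel),
                "known": sorted(self.known),
                "per_source": {k: sorted(v) for k, v in sorted(self.per_source.items())},
            },
            indent=2,
        )


def load_gene_list(path: str | Path) -> set[str]:
    """One newline-delimited symbol list: upper-cased, trimmed, deduplicated.

    '#' comment lines and empty lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: set[str] = set()
    for line in path.read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            genes.add(token.upper())
    if not genes:
        logger.warning("gene list %s is empty", path)
    return genes


def load_gene_lists(paths: Mapping[str, str | Path]) -> dict[str, set[str]]:
    """Load each named source file; unreadable files raise with their path."""
    return {name: load_gene_list(p) for name, p in paths.items()}


def validate_genes(
    query: set[str], sources: Mapping[str, set[str]], query_name: str = "query"
) -> ValidationReport:
    """Partition a query gene set into known vs novel against the sources."""
    if not sources:
        raise ValueError("at least one validation source is required")
    query = {g.upper() for g in query}
    union = set().union(*sources.values())
    known = query & union
    return ValidationReport(
        query_name=query_name,
        known=known,
        novel=query - known,
        per_source={name: query & s for name, s in sources.items()},
    )
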
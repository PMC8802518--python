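"""NCBI taxonomy parsing and rank-level aggregation of abundance estimates.

Reads the standard NCBI taxonomy dump dialect (``nodes.dmp`` / ``names.dmp``,
fields separated by ``\\t|\\t`` and records terminated by ``\\t|``), exposes
lineage walks, and aggregates per-reference estimated read counts to an
arbitrary taxonomic rank.

Aggregation never drops mass: references whose lineage lacks the requested
rank are reported under a reserved "no-rank-at-level" row, and references
missing from the reference→taxid map go to an "unmapped-taxonomy" row, so
the output total always equals the input total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: taxid grouping key for references whose lineage lacks the requested rank
NO_RANK_AT_LEVEL = -1
#: taxid grouping key for references absent from the reference→taxid map
UNMAPPED_TAXONOMY = -2


class TaxonomyError(Exception):
    """Base class for taxonomy failures."""


class TaxonomyParseError(TaxonomyError):
    """A dump file record did not follow the NCBI dialect."""


class UnknownTaxidError(TaxonomyError, KeyError):
    """A queried taxid is not present in the database."""


class BrokenLineageError(TaxonomyError):
    """A parent chain left the database before reaching the root."""


@dataclass
class TaxonomyDB:
    """Parsed taxonomy: parent pointers, ranks and scientific names."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str] = field(default_factory=dict)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def lineage(self, taxid: int) -> list[tuple[int, str]]:
        """Ordered (taxid, rank) pairs from ``taxid`` up to the root.

        The first element is the query node itself, the last is the root
        (detected as a node that is its own parent).
        """
        if taxid not in self.parent:
            raise UnknownTaxidError(f"taxid {taxid} not in taxonomy")
        out: list[tuple[int, str]] = []
        node = taxid
        seen: set[int] = set()
        while True:
            out.append((node, self.rank.get(node, "no rank")))
            parent = self.parent.get(node)
            if parent is None:
                raise BrokenLineageError(
                    f"lineage of taxid {taxid} leaves the database at node {node}"
                )
            if parent == node:
                return out
            if node in seen:  # defensive; load_taxonomy guarantees no cycles
                raise BrokenLineageError(f"cycle in lineage of taxid {taxid}")
            seen.add(node)
            node = parent

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """First ancestor (including the node itself) with the given rank."""
        for node, r in self.lineage(taxid):
            if r == rank:
                return node
        return None


def _parse_dmp_line(line: str, path: str, lineno: int, nfields: int) -> list[str]:
    stripped = line.rstrip("\n")
    if stripped.endswith("\t|"):
        stripped = stripped[: -len("\t|")]
    fields = stripped.split("\t|\t")
    if len(fields) < nfields:
        raise TaxonomyParseError(
            f"{path}:{lineno}: expected at least {nfields} fields separated by "
            f"'\\t|\\t', got {len(fields)}"
        )
    return fields


def load_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyDB:
    """Parse ``nodes.dmp`` and ``names.dmp`` into a :class:`TaxonomyDB`.

    Only "scientific name" rows of the names file are kept. Names for taxids
    absent from the nodes file are dropped with a warning. Malformed records
    raise :class:`TaxonomyParseError` naming the offending line.
    """
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    with open(nodes_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, str(nodes_path), ln, 3)
            try:
                taxid, par = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxonomyParseError(
                    f"{nodes_path}:{ln}: non-integer taxid field"
                ) from exc
            parent[taxid] = par
            rank[taxid] = fields[2].strip()

    name: dict[int, str] = {}
    with open(names_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, str(names_path), ln, 4)
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise TaxonomyParseError(
                    f"{names_path}:{ln}: non-integer taxid field"
                ) from exc
            if fields[3].strip() != "scientific name":
                continue
            if taxid not in parent:
                warnings.warn(
                    f"{names_path}:{ln}: taxid {taxid} has a name but no nodes "
                    "entry; dropped",
                    stacklevel=2,
                )
                continue
            name[taxid] = fields[1].strip()

    db = TaxonomyDB(parent=parent, rank=rank, name=name)
    # Fail fast on cycles that do not reach a self-parent root. Chains that
    # leave the db entirely are tolerated here and reported at lineage() time.
    for taxid in parent:
        node, seen = taxid, set()
        while node in parent and parent[node] != node:
            if node in seen:
                raise TaxonomyParseError(f"cycle detected at taxid {taxid}")
            seen.add(node)
            node = parent[node]
    return db


def lineage(db: TaxonomyDB, taxid: int) -> list[tuple[int, str]]:
    """Functional alias for :meth:`TaxonomyDB.lineage`."""
    return db.lineage(taxid)


def aggregate_to_rank(
    est: Mapping[str, float],
    taxid_of: Mapping[str, int],
    db: TaxonomyDB,
    rank: str,
) -> pd.DataFrame:
    """Aggregate per-reference estimated counts to a taxonomic rank.

    ``rank="strain"`` means no aggregation beyond each reference's own taxid.
    The result preserves total mass exactly: references with no ancestor at
    the requested rank appear under the ``NO_RANK_AT_LEVEL`` row and
    references missing from ``taxid_of`` under ``UNMAPPED_TAXONOMY``.

    Returns a DataFrame with columns ``taxid, scientific_name, rank,
    estimated_reads, relative_abundance`` sorted by decreasing count.
    """
    counts: dict[int, float] = {}
    for ref_id, value in est.items():
        taxid = taxid_of.get(ref_id)
        if taxid is None:
            key = UNMAPPED_TAXONOMY
        elif rank == "strain":
            key = taxid
        else:
            try:
                anc = db.ancestor_at_rank(taxid, rank)
            except TaxonomyError as exc:
                raise type(exc)(f"reference {ref_id!r}: {exc}") from exc
            key = anc if anc is not None else NO_RANK_AT_LEVEL
        counts[key] = counts.get(key, 0.0) + float(value)

    total = sum(counts.values())
    rows = []
    for taxid, value in counts.items():
        if taxid == NO_RANK_AT_LEVEL:
            nm, rk = "no-rank-at-level", ""
        elif taxid == UNMAPPED_TAXONOMY:
            nm, rk = "unmapped-taxonomy", ""
        else:
            nm = db.name.get(taxid, "")
            rk = db.rank.get(taxid, "strain" if rank == "strain" else "")
        rows.append(
            {
                "taxid": taxid,
                "scientific_name": nm,
                "rank": rk,
                "estimated_reads": value,
                "relative_abundance": value / total if total > 0 else 0.0,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["taxid", "scientific_name", "rank", "estimated_reads", "relative_abundance"],
    )
    return df.sort_values("estimated_reads", ascending=False, ignore_index=True)


def write_rank_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
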
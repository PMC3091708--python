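"""Taxonomy lineage screening and the bacterial hit-rank fingerprint.

A homology hit is "bacterial" when the parent chain of its subject taxon
reaches a rank=superkingdom node named Bacteria. The fingerprint is the
cumulative curve f(r) = number of queries whose best (lowest-rank)
bacterial hit sits at rank <= r, over ranks 1..20, with a plateau
detector flagging where the curve converges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, TaxonomyLookupError

SUPERKINGDOM = "superkingdom"
DEFAULT_MAX_RANK = 20


@dataclass
class TaxonNode:
    parent: int
    rank: str
    name: str


@dataclass
class TaxonomyTable:
    """taxid -> (parent, rank, name) map supporting lineage walks.

    The root is self-parented; every parent chain must terminate there.
    """

    nodes: dict[int, TaxonNode]
    root: int = 1

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def lineage(self, taxid: int) -> list[int]:
        """Parent chain from taxid (inclusive) up to the root."""
        if taxid not in self.nodes:
            raise TaxonomyLookupError(f"unknown taxid {taxid}")
        chain = [taxid]
        guard = len(self.nodes) + 1
        while chain[-1] != self.root:
            node = self.nodes.get(chain[-1])
            if node is None:
                raise TaxonomyLookupError(
                    f"broken parent chain at taxid {chain[-1]}")
            chain.append(node.parent)
            if len(chain) > guard:
                raise FormatError(f"cycle in taxonomy at taxid {taxid}")
        return chain

    def superkingdom_of(self, taxid: int) -> Optional[str]:
        """Name of the rank=superkingdom ancestor, or None if the chain
        reaches the root without one."""
        for tid in self.lineage(taxid):
            node = self.nodes[tid]
            if node.rank == SUPERKINGDOM:
                return node.name
        return None

    def is_bacterial(self, taxid: int) -> bool:
        return self.superkingdom_of(taxid) == "Bacteria"

    def leaves(self, superkingdom: Optional[str] = None) -> list[int]:
        parents = {n.parent for t, n in self.nodes.items() if t != n.parent}
        out = [t for t in self.nodes if t not in parents]
        if superkingdom is not None:
            out = [t for t in out if self.superkingdom_of(t) == superkingdom]
        return sorted(out)

    # NCBI-dump dialect: fields separated by "\t|\t", lines ending "\t|"
    def to_dmp(self, nodes_path, names_path) -> None:
        with open(nodes_path, "w") as fh:
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                fh.write(f"{tid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
        with open(names_path, "w") as fh:
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                fh.write(f"{tid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")

    @classmethod
    def from_dmp(cls, nodes_path, names_path) -> "TaxonomyTable":
        parents: dict[int, tuple[int, str]] = {}
        with open(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("|\n").split("\t|\t")]
                if len(fields) < 3:
                    raise FormatError(f"malformed nodes.dmp line: {line!r}")
                parents[int(fields[0])] = (int(fields[1]), fields[2].rstrip("\t|"))
        names: dict[int, str] = {}
        with open(names_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("|\n").split("\t|\t")]
                if len(fields) >= 4 and fields[3].startswith("scientific name"):
                    names[int(fields[0])] = fields[1]
                elif int(fields[0]) not in names:
                    names[int(fields[0])] = fields[1]
        nodes = {tid: TaxonNode(parent=p, rank=r, name=names.get(tid, ""))
                 for tid, (p, r) in parents.items()}
        roots = [t for t, n in nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise FormatError(f"expected one self-parented root, got {roots}")
        return cls(nodes=nodes, root=roots[0])


@dataclass
class RankCurve:
    """Cumulative bacterial-hit counts by best-hit rank."""

    f: np.ndarray  # f[r-1] = queries whose best bacterial hit has rank <= r
    total_queries: int
    max_rank: int = DEFAULT_MAX_RANK
    skipped_hits: int = 0  # hits dropped for unresolvable taxids
    plateau_value: Optional[int] = None
    plateau_rank: Optional[int] = None
    converged: bool = False

    def increments(self) -> np.ndarray:
        return np.diff(np.concatenate([[0], self.f]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, self.max_rank + 1),
            "f": self.f,
            "increment": self.increments(),
        })


def bacterial_rank_curve(hits: pd.DataFrame, taxonomy: TaxonomyTable,
                         max_rank: int = DEFAULT_MAX_RANK) -> RankCurve:
    """Cumulative curve of queries by the rank of their best bacterial hit.

    Ranks are positional within each query (row order). Queries with no
    bacterial hit within ``max_rank`` are never counted; hits whose
    taxid cannot be resolved are skipped and tallied in
    ``skipped_hits``.
    """
    if max_rank < 1:
        raise ConfigError(f"max_rank must be >= 1, got {max_rank}")
    ranked = hits.assign(
        rank=hits.groupby("qseqid", sort=False).cumcount() + 1)
    ranked = ranked[ranked["rank"] <= max_rank]

    skipped = 0
    bact_cache: dict[int, Optional[bool]] = {}

    def bacterial(taxid: int) -> Optional[bool]:
        if taxid not in bact_cache:
            try:
                bact_cache[taxid] = taxonomy.is_bacterial(int(taxid))
            except TaxonomyLookupError:
                bact_cache[taxid] = None
        return bact_cache[taxid]

    best_rank: dict[str, int] = {}
    for row in ranked.itertuples():
        flag = bacterial(row.staxid)
        if flag is None:
            skipped += 1
            continue
        if flag and row.qseqid not in best_rank:
            best_rank[row.qseqid] = row.rank

    f = np.zeros(max_rank, dtype=int)
    for r in best_rank.values():
        f[r - 1:] += 1
    return RankCurve(f=f, total_queries=hits["qseqid"].nunique(),
                     max_rank=max_rank, skipped_hits=skipped)


def detect_plateau(curve: RankCurve, tol: int = 0, window: int = 5,
                   ) -> RankCurve:
    """Find the earliest rank where the curve stops growing.

    The plateau rank is the earliest r such that all of the next
    ``window - 1`` increments f(r+1)-f(r), ..., are <= tol. The plateau
    value is always f(max_rank); a strictly growing curve is flagged
    non-converged (plateau_rank None).
    """
    if window < 2:
        raise ConfigError(f"window must be >= 2, got {window}")
    if tol < 0:
        raise ConfigError(f"tol must be >= 0, got {tol}")
    f = curve.f
    plateau_rank = None
    for r in range(1, curve.max_rank - (window - 1) + 1):
        incs = f[r: r + window - 1] - f[r - 1: r + window - 2]
        if np.all(incs <= tol):
            plateau_rank = r
            break
    curve.plateau_rank = plateau_rank
    curve.plateau_value = int(f[-1]) if curve.max_rank else 0
    curve.converged = plateau_rank is not None
    return curve
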
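"""Per-GO-term taxonomic attribution via lowest common ancestors (step 2).

A peptide shared across organisms is taxonomically ambiguous.  For each GO
term we collate the peptides that contributed to it, take each peptide's
matched proteins' taxa, and find their lowest common ancestor (LCA) — the
most specific taxon for which the peptide is unambiguous spectral evidence.
The peptide's count is then added to the LCA and every ancestor up to the
taxonomy root.  Summing each rank's share of the GO term's count gives the
diagnostic for picking the most specific usable taxonomic level: the sums
are monotone non-increasing from superkingdom down to species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .go_quant import GoCountTable
from .peptides import PeptideObservation

logger = logging.getLogger("peptigo")

CANONICAL_RANKS = (
    "superkingdom", "phylum", "class", "order", "family", "genus", "species",
)


class TaxonomyTree:
    """NCBI-taxdump-style taxonomy: per-node name/rank/parent, merged-id
    resolution, a single root (the node that is its own parent)."""

    def __init__(
        self,
        nodes: Mapping[int, tuple[str, str, int]],  # taxid -> (name, rank, parent)
        merged: Mapping[int, int] | None = None,
    ) -> None:
        self.nodes = dict(nodes)
        self.merged = dict(merged or {})
        roots = [t for t, (_, _, parent) in self.nodes.items() if parent == t]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for taxid, (_, _, parent) in self.nodes.items():
            if parent not in self.nodes:
                raise ValueError(f"taxid {taxid} references missing parent {parent}")
        self._lineage_cache: dict[int, tuple[int, ...]] = {}
        # cycle check: every node must reach the root
        for taxid in self.nodes:
            self.lineage(taxid)

    def resolve(self, taxid: int) -> int:
        if taxid in self.nodes:
            return taxid
        if taxid in self.merged:
            return self.merged[taxid]
        raise KeyError(f"unknown taxid {taxid}")

    def name(self, taxid: int) -> str:
        return self.nodes[self.resolve(taxid)][0]

    def rank(self, taxid: int) -> str:
        return self.nodes[self.resolve(taxid)][1]

    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Root-to-node path, both endpoints included."""
        taxid = self.resolve(taxid)
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        path = [taxid]
        seen = {taxid}
        node = taxid
        while node != self.root:
            node = self.nodes[node][2]
            if node in seen:
                raise ValueError(f"cycle in taxonomy at taxid {node}")
            seen.add(node)
            path.append(node)
        result = tuple(reversed(path))
        self._lineage_cache[taxid] = result
        return result


def _parse_dmp(path: str | Path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            # taxdump rows are "<field>\t|\t<field>\t|...\t|"
            yield [f.strip("\t") for f in line.rstrip("|").rstrip("\t").split("\t|")]


def read_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> TaxonomyTree:
    """Load nodes.dmp / names.dmp (scientific names only) / optional
    merged.dmp in the NCBI taxdump dialect."""
    parents: dict[int, tuple[str, int]] = {}
    for fields in _parse_dmp(nodes_path):
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        parents[taxid] = (rank, parent)
    names: dict[int, str] = {}
    for fields in _parse_dmp(names_path):
        taxid, name = int(fields[0]), fields[1]
        name_class = fields[3] if len(fields) > 3 else "scientific name"
        if name_class == "scientific name":
            names[taxid] = name
    merged: dict[int, int] = {}
    if merged_path is not None:
        for fields in _parse_dmp(merged_path):
            merged[int(fields[0])] = int(fields[1])
    nodes = {
        taxid: (names.get(taxid, str(taxid)), rank, parent)
        for taxid, (rank, parent) in parents.items()
    }
    return TaxonomyTree(nodes, merged)


def lineage(taxid: int, tree: TaxonomyTree) -> tuple[int, ...]:
    """Functional wrapper around :meth:`TaxonomyTree.lineage`."""
    return tree.lineage(taxid)


def peptide_lca(taxids: Iterable[int], tree: TaxonomyTree) -> int:
    """Deepest taxon lying on every member's root-to-node lineage.

    Equivalently the last common element of the lineages: the most specific
    taxonomic unit for which the peptide provides unambiguous evidence.
    """
    lineages = [tree.lineage(t) for t in taxids]
    if not lineages:
        raise ValueError("cannot compute an LCA of an empty taxid set")
    lca = tree.root
    for level in zip(*lineages):
        first = level[0]
        if all(t == first for t in level[1:]):
            lca = first
        else:
            break
    return lca


@dataclass
class TaxonCountTable:
    """Per-taxon spectral counts scoped to one GO term.

    ``ratio_of_go`` divides by the GO term's own spectral count,
    ``ratio_of_experiment`` by the experiment's total PSMs; their quotient is
    constant across rows.  ``unattributed`` tallies spectra of contributing
    peptides whose matched proteins carried no taxonomy at all.
    """

    go_accession: str
    go_count: int
    total_psms: int
    counts: dict[int, int]
    tree: TaxonomyTree
    unattributed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_name": self.tree.name(taxid),
                "taxonomy_rank": self.tree.rank(taxid),
                "spectral_count": count,
                "ratio_of_go": count / self.go_count,
                "ratio_of_experiment": count / self.total_psms,
            }
            for taxid, count in self.counts.items()
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "taxon_name", "taxonomy_rank", "spectral_count",
                "ratio_of_go", "ratio_of_experiment",
            ],
        )
        return frame.sort_values(
            ["spectral_count", "taxon_name"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def go_term_taxon_table(
    go_term: str,
    peptides: Sequence[PeptideObservation],
    peptide_graphs: Mapping[str, frozenset[str]],
    peptide_taxids: Mapping[str, frozenset[int]],
    tree: TaxonomyTree,
    go_table: GoCountTable,
) -> TaxonCountTable:
    """Attribute one GO term's spectral count to taxa.

    Contributing peptides are exactly those whose GO graph contains the term.
    For each with a non-empty taxid set, its abundance is added to every node
    on the lineage of its LCA.  Peptides with no taxonomy are counted as
    "unattributed" and touch no taxon.
    """
    if go_term not in go_table.counts:
        raise KeyError(f"GO term {go_term!r} not present in the experiment")
    counts: dict[int, int] = {}
    unattributed = 0
    for obs in peptides:
        if go_term not in peptide_graphs[obs.peptide]:
            continue
        taxids = peptide_taxids.get(obs.peptide, frozenset())
        if not taxids:
            unattributed += obs.abundance
            continue
        lca = peptide_lca(taxids, tree)
        for node in tree.lineage(lca):
            counts[node] = counts.get(node, 0) + obs.abundance
    return TaxonCountTable(
        go_accession=go_term,
        go_count=go_table.counts[go_term],
        total_psms=go_table.total_psms,
        counts=counts,
        tree=tree,
        unattributed=unattributed,
    )


def summed_fraction_by_rank(table: TaxonCountTable, rank: str) -> float:
    """Σ ratio_of_go over taxa of one rank.

    Diagnostic for the most specific taxonomic level at which attribution is
    still nearly complete: the sums are non-increasing from superkingdom down
    to species.
    """
    return sum(
        count / table.go_count
        for taxid, count in table.counts.items()
        if table.tree.rank(taxid) == rank
    )
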
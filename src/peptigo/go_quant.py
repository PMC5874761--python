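"""Per-GO-term spectral count aggregation (step 1 of the pipeline).

Each peptide gets a non-redundant GO graph: the union, over all proteins it
matches, of every directly annotated GO term plus all "is a" ancestors up to
the aspect root.  The peptide's spectral count is then added once to every
term of that graph, so a spectrum increments each functional annotation at
most once no matter how many proteins share the peptide.  Per-aspect
"unknown" nodes, direct children of the aspect roots, absorb the counts of
peptides with no annotation in that aspect; this keeps each aspect root's
count equal to the experiment's total PSMs.

Only "is a" edges are traversed by default; ``part_of`` traversal can be
enabled at load time but is off because subsumption — not partonomy — is what
makes ancestor counts interpretable as "spectra attributable to this
function or anything more specific".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .peptides import PeptideObservation

logger = logging.getLogger("peptigo")

ASPECTS = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class UnknownNodeConfig:
    """Synthetic per-aspect accessions for peptides lacking annotation."""

    biological_process: str = "unknownprc"
    molecular_function: str = "unknownfun"
    cellular_component: str = "unknowncmp"

    def accession_for(self, aspect: str) -> str:
        return getattr(self, aspect)

    def name_for(self, aspect: str) -> str:
        return "unknown " + aspect.replace("_", " ")

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(
            (self.biological_process, self.molecular_function, self.cellular_component)
        )


class GoOntology:
    """The GO "is a" DAG: term names, aspects, parent sets, alt_id and
    obsolete bookkeeping, with memoized ancestor closures."""

    def __init__(
        self,
        terms: Mapping[str, tuple[str, str, frozenset[str]]],
        alt_ids: Mapping[str, str],
        obsolete: frozenset[str],
    ) -> None:
        self.terms = dict(terms)  # acc -> (name, aspect, parents)
        self.alt_ids = dict(alt_ids)
        self.obsolete = obsolete
        self._closure_cache: dict[str, frozenset[str]] = {}
        self.roots: dict[str, str] = {}
        for acc, (_, aspect, parents) in self.terms.items():
            if not parents and acc not in obsolete:
                if aspect in self.roots:
                    raise ValueError(
                        f"aspect {aspect!r} has multiple roots: "
                        f"{self.roots[aspect]}, {acc}"
                    )
                self.roots[aspect] = acc

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms or accession in self.alt_ids

    def resolve(self, accession: str) -> str:
        """Map an alt_id to its primary accession (identity for primaries)."""
        if accession in self.terms:
            return accession
        if accession in self.alt_ids:
            return self.alt_ids[accession]
        raise KeyError(f"unknown GO accession {accession!r}")

    def name(self, accession: str) -> str:
        return self.terms[self.resolve(accession)][0]

    def aspect(self, accession: str) -> str:
        return self.terms[self.resolve(accession)][1]

    def parents(self, accession: str) -> frozenset[str]:
        return self.terms[self.resolve(accession)][2]

    def ancestor_closure(self, accession: str) -> frozenset[str]:
        """The term itself plus everything reachable via repeated "is a"
        edges; memoized."""
        acc = self.resolve(accession)
        cached = self._closure_cache.get(acc)
        if cached is not None:
            return cached
        closure = {acc}
        for parent in self.terms[acc][2]:
            closure.update(self.ancestor_closure(parent))
        result = frozenset(closure)
        self._closure_cache[acc] = result
        return result

    def fingerprint(self) -> str:
        """Stable digest of the term structure, used to check that two runs
        were built against the same ontology."""
        payload = json.dumps(
            {
                acc: [name, aspect, sorted(parents)]
                for acc, (name, aspect, parents) in sorted(self.terms.items())
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_obo(path: str | Path, *, include_part_of: bool = False) -> GoOntology:
    """Load an OBO 1.2 ontology.

    Obsolete terms are flagged and excluded as closure targets; alt_ids are
    indexed to their primary term.  A cycle in the "is a" graph or a term
    without a namespace is a hard error.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()
    for acc, data in graph.nodes(data=True):
        aspect = data.get("namespace")
        if aspect is None:
            raise ValueError(f"GO term {acc!r} has no namespace")
        name = data.get("name", acc)
        parents = set()
        for _, parent, rel in graph.out_edges(acc, keys=True):
            if rel == "is_a" or (include_part_of and rel == "part_of"):
                parents.add(parent)
        if data.get("is_obsolete") == "true":
            obsolete.add(acc)
            parents = set()
        terms[acc] = (name, aspect, frozenset(parents))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = acc
    dag = nx.DiGraph((child, parent) for child, (_, _, ps) in terms.items() for parent in ps)
    if dag.number_of_nodes() and not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"cycle in the is_a graph: {cycle}")
    return GoOntology(terms, alt_ids, frozenset(obsolete))


def ancestor_closure(term: str, ontology: GoOntology) -> frozenset[str]:
    """Functional wrapper around :meth:`GoOntology.ancestor_closure`."""
    return ontology.ancestor_closure(term)


def peptide_go_graph(
    peptide: str,
    peptide_protein_map: Mapping[str, frozenset[str]],
    protein_annotations: Mapping[str, tuple[frozenset[str], frozenset[int]]],
    ontology: GoOntology,
    unknowns: UnknownNodeConfig = UnknownNodeConfig(),
) -> frozenset[str]:
    """The peptide's non-redundant GO graph, all aspects pooled.

    Union of ancestor closures of every direct term of every matched protein;
    then, independently per aspect, the aspect's synthetic unknown node and
    its root are added when the union holds no term of that aspect.  The
    three aspect roots are always present.
    """
    graph: set[str] = set()
    dropped: set[str] = set()
    for protein_id in peptide_protein_map.get(peptide, frozenset()):
        go_terms, _ = protein_annotations.get(protein_id, (frozenset(), frozenset()))
        for acc in go_terms:
            if acc not in ontology:
                dropped.add(acc)
                continue
            primary = ontology.resolve(acc)
            if primary in ontology.obsolete:
                dropped.add(acc)
                continue
            graph.update(ontology.ancestor_closure(primary))
    if dropped:
        logger.warning(
            "GOQ01 peptide %s: dropped %d unknown/obsolete GO accession(s): %s",
            peptide, len(dropped), ", ".join(sorted(dropped)),
        )
    present_aspects = {ontology.aspect(acc) for acc in graph}
    for aspect in ASPECTS:
        root = ontology.roots.get(aspect)
        if root is None:
            raise ValueError(f"ontology has no root for aspect {aspect!r}")
        if aspect not in present_aspects:
            graph.add(unknowns.accession_for(aspect))
        graph.add(root)
    return frozenset(graph)


@dataclass
class GoCountTable:
    """Aggregated per-GO-term spectral counts for one experiment.

    ``counts`` maps every observed accession (real or synthetic unknown) to
    its spectral count; ``term_info`` carries (aspect, name) per accession so
    the table is self-contained.  Ratios are counts divided by ``total_psms``
    and computed on demand at full precision.
    """

    counts: dict[str, int]
    total_psms: int
    term_info: dict[str, tuple[str, str]]
    unknown_config: UnknownNodeConfig = field(default_factory=UnknownNodeConfig)
    ontology_fingerprint: str | None = None
    flags: dict[str, object] = field(default_factory=dict)

    def ratio(self, accession: str) -> float:
        return self.counts[accession] / self.total_psms

    def to_frame(self) -> pd.DataFrame:
        """Report rows: accession, aspect, name, count, ratio — sorted by
        aspect, then count descending, then accession."""
        rows = [
            {
                "go_accession": acc,
                "go_aspect": self.term_info[acc][0],
                "go_name": self.term_info[acc][1],
                "spectral_count": count,
                "ratio": count / self.total_psms,
            }
            for acc, count in self.counts.items()
        ]
        frame = pd.DataFrame(
            rows, columns=["go_accession", "go_aspect", "go_name", "spectral_count", "ratio"]
        )
        return frame.sort_values(
            ["go_aspect", "spectral_count", "go_accession"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "total_psms": self.total_psms,
                "term_info": {k: list(v) for k, v in self.term_info.items()},
                "unknown_config": {
                    "biological_process": self.unknown_config.biological_process,
                    "molecular_function": self.unknown_config.molecular_function,
                    "cellular_component": self.unknown_config.cellular_component,
                },
                "ontology_fingerprint": self.ontology_fingerprint,
                "flags": self.flags,
            },
            sort_keys=True,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GoCountTable":
        data = json.loads(text)
        return cls(
            counts={k: int(v) for k, v in data["counts"].items()},
            total_psms=int(data["total_psms"]),
            term_info={k: (v[0], v[1]) for k, v in data["term_info"].items()},
            unknown_config=UnknownNodeConfig(**data["unknown_config"]),
            ontology_fingerprint=data.get("ontology_fingerprint"),
            flags=data.get("flags", {}),
        )


def aggregate_go_counts(
    peptides: Sequence[PeptideObservation],
    peptide_graphs: Mapping[str, frozenset[str]],
    ontology: GoOntology,
    unknowns: UnknownNodeConfig = UnknownNodeConfig(),
    *,
    flags: Mapping[str, object] | None = None,
) -> GoCountTable:
    """Sum peptide abundances into per-term spectral counts.

    ``count(term) = Σ abundance`` over peptides whose graph contains the
    term; ``total_psms`` is the sum of all abundances.  A zero total is a
    hard error (no spectra, no proportions).
    """
    for acc in unknowns.accessions:
        if acc in ontology:
            raise ValueError(
                f"unknown-node accession {acc!r} collides with a real GO term"
            )
    total = sum(obs.abundance for obs in peptides)
    if total == 0:
        raise ValueError("total PSM count is zero; cannot compute ratios")
    counts: dict[str, int] = {}
    for obs in peptides:
        for acc in peptide_graphs[obs.peptide]:
            counts[acc] = counts.get(acc, 0) + obs.abundance
    term_info: dict[str, tuple[str, str]] = {}
    unknown_by_acc = {unknowns.accession_for(a): a for a in ASPECTS}
    for acc in counts:
        if acc in unknown_by_acc:
            aspect = unknown_by_acc[acc]
            term_info[acc] = (aspect, unknowns.name_for(aspect))
        else:
            term_info[acc] = (ontology.aspect(acc), ontology.name(acc))
    return GoCountTable(
        counts=counts,
        total_psms=total,
        term_info=term_info,
        unknown_config=unknowns,
        ontology_fingerprint=ontology.fingerprint(),
        flags=dict(flags or {}),
    )
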
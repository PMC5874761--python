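"""Homology-hit filtering and annotation transfer.

Database proteins are functionally anonymous; they acquire GO terms and
taxonomy by homology to annotated reference proteins (e.g. UniProtKB).  This
module consumes precomputed hits in NCBI BLAST tabular format (-outfmt 6),
filters them by E-value cutoff and an optional top-hit rule, and resolves
each database protein to the union of GO terms / taxa of its retained
reference matches.

The top-hit rule keeps *all* hits tied for the best bit score, provided the
best hit passes the E-value cutoff; with the rule off, every hit meeting the
cutoff is kept.  One shared filtered hit set feeds both GO and taxonomy
transfer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger("peptigo")

_GO_ACC_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_accession: str
    e_value: float
    bit_score: float


@dataclass(frozen=True)
class HitFilterConfig:
    """E-value cutoff and top-hit behaviour for homology-hit filtering."""

    e_value_cutoff: float = 1e-10
    top_hit_only: bool = True

    def __post_init__(self) -> None:
        if self.e_value_cutoff <= 0:
            raise ValueError("e_value_cutoff must be > 0")


def read_blast_tabular(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column NCBI BLAST tabular output (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Lines starting with ``#`` are ignored.  Only query id, subject accession,
    e-value and bit score are retained.
    """
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                e_value = float(parts[10])
                bit_score = float(parts[11])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unparsable e-value/bit-score "
                    f"{parts[10]!r}/{parts[11]!r}"
                ) from None
            if e_value < 0:
                raise ValueError(f"{path}:{lineno}: negative e-value {e_value}")
            hits.append(HomologyHit(parts[0], parts[1], e_value, bit_score))
    return hits


def filter_hits(
    hits: Iterable[HomologyHit], config: HitFilterConfig = HitFilterConfig()
) -> dict[str, frozenset[str]]:
    """Retain subject accessions per query under the cutoff/top-hit rules.

    Hits with ``e_value > cutoff`` are discarded first.  If ``top_hit_only``,
    only survivors whose bit score equals the per-query maximum surviving bit
    score are kept — ties are all kept, never broken arbitrarily.  Queries
    with no surviving hit are absent from the result.
    """
    by_query: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        if hit.e_value <= config.e_value_cutoff:
            by_query.setdefault(hit.query_id, []).append(hit)
    result: dict[str, frozenset[str]] = {}
    for query, survivors in by_query.items():
        if config.top_hit_only:
            best = max(h.bit_score for h in survivors)
            kept = [h for h in survivors if h.bit_score == best]
        else:
            kept = survivors
        result[query] = frozenset(h.subject_accession for h in kept)
    return result


def _validate_go_accession(acc: str, where: str) -> None:
    if not _GO_ACC_RE.match(acc):
        raise ValueError(f"{where}: malformed GO accession {acc!r}")


def read_go_annotation_map(
    path: str | Path, dialect: str = "tsv"
) -> dict[str, frozenset[str]]:
    """Read reference-protein → GO annotations.

    ``dialect='tsv'``: 2 columns, accession then comma-separated GO ids.
    ``dialect='gaf'``: GAF 2.x — column 2 is the accession, column 5 the GO
    id; rows whose qualifier (column 4) contains ``NOT`` are skipped, as are
    ``!`` comment lines.  Accessions occurring on several rows accumulate the
    union of their GO sets.
    """
    if dialect not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    go_map: dict[str, set[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            where = f"{path}:{lineno}"
            if dialect == "gaf":
                if line.startswith("!"):
                    continue
                parts = line.split("\t")
                if len(parts) < 5:
                    raise ValueError(f"{where}: GAF row has fewer than 5 columns")
                accession, qualifier, go_acc = parts[1], parts[3], parts[4]
                if "NOT" in qualifier.split("|"):
                    continue
                _validate_go_accession(go_acc, where)
                go_map.setdefault(accession, set()).add(go_acc)
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{where}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                accession, go_field = parts[0].strip(), parts[1].strip()
                accs = [a.strip() for a in go_field.split(",") if a.strip()]
                for acc in accs:
                    _validate_go_accession(acc, where)
                go_map.setdefault(accession, set()).update(accs)
    return {k: frozenset(v) for k, v in go_map.items()}


def read_taxon_map(path: str | Path) -> dict[str, int]:
    """Read a 2-column accession → NCBI taxid TSV.

    Duplicate identical rows collapse to one entry; a duplicate accession
    with a *conflicting* taxid is a hard error.
    """
    taxon_map: dict[str, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            accession, taxid_str = parts[0].strip(), parts[1].strip()
            try:
                taxid = int(taxid_str)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: taxid {taxid_str!r} is not an integer"
                ) from None
            if accession in taxon_map and taxon_map[accession] != taxid:
                raise ValueError(
                    f"{path}:{lineno}: conflicting taxid for {accession!r}: "
                    f"{taxon_map[accession]} vs {taxid}"
                )
            taxon_map[accession] = taxid
    return taxon_map


def annotate_proteins(
    filtered_hits: Mapping[str, frozenset[str]],
    go_map: Mapping[str, frozenset[str]],
    taxon_map: Mapping[str, int],
) -> dict[str, tuple[frozenset[str], frozenset[int]]]:
    """Resolve each query protein to (GO term set, taxid set).

    Both sets are unions over the protein's retained subject accessions.
    Subject accessions missing from an annotation map contribute nothing to
    that map's union and are reported once in a warning.  Proteins with no
    retained hits may simply be absent from ``filtered_hits``; callers treat
    absence as (empty, empty).
    """
    missing_go: set[str] = set()
    missing_tax: set[str] = set()
    annotated: dict[str, tuple[frozenset[str], frozenset[int]]] = {}
    for query, subjects in filtered_hits.items():
        go_terms: set[str] = set()
        taxids: set[int] = set()
        for subject in subjects:
            if subject in go_map:
                go_terms.update(go_map[subject])
            else:
                missing_go.add(subject)
            if subject in taxon_map:
                taxids.add(taxon_map[subject])
            else:
                missing_tax.add(subject)
        annotated[query] = (frozenset(go_terms), frozenset(taxids))
    if missing_go:
        logger.warning(
            "ANN01 %d subject accession(s) missing from the GO annotation map: %s",
            len(missing_go), ", ".join(sorted(missing_go)[:10]),
        )
    if missing_tax:
        logger.warning(
            "ANN02 %d subject accession(s) missing from the taxon map: %s",
            len(missing_tax), ", ".join(sorted(missing_tax)[:10]),
        )
    return annotated
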
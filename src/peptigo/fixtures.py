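"""Synthetic input bundles with known ground truth.

Generates small, mutually consistent versions of all pipeline inputs —
protein FASTA, peptide/count lists for two experiments, BLAST tabular hits,
reference GO and taxon maps, an OBO ontology and an NCBI-style taxdump —
entirely offline and reproducibly from a seed.  Peptides are implanted into
proteins at explicit N-terminal or post-K/R positions so matching is
unambiguous by construction; decoy peptides with invalid boundaries exercise
the unmatched/unknown path.

Ground-truth GO count tables are computed inside the generator with
deliberately naive logic (positional scans, repeated edge expansion for
closures), independent of the package's optimized implementations, so the
bundle doubles as an end-to-end oracle.

What this emulates: the combinatorics of peptide sharing, annotation
transfer and ancestor propagation.  What it does not: real sequence
homology, search-engine score distributions, or realistic GO/taxonomy sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .peptides import STANDARD_RESIDUES

_ALPHABET = sorted(STANDARD_RESIDUES - {"K", "R"})  # interior residues
_ROOTS = {
    "biological_process": "GO:0008150",
    "molecular_function": "GO:0003674",
    "cellular_component": "GO:0005575",
}
_CANONICAL_RANKS = (
    "superkingdom", "phylum", "class", "order", "family", "genus", "species",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters for one synthetic bundle; the seed fully determines
    every emitted byte."""

    seed: int = 1
    n_reference_proteins: int = 12
    terms_per_aspect: int = 6
    taxonomy_children: int = 2
    n_superkingdoms: int = 2
    n_peptides: int = 20
    mean_count: float = 12.0
    n_decoys: int = 2
    n_planted_peptides: int = 3
    planted_fold: float = 4.0


@dataclass
class FixtureManifest:
    """Paths of the written files plus ground truth computed by construction."""

    paths: dict[str, Path]
    expected_peptide_protein_map: dict[str, frozenset[str]]
    expected_protein_annotations: dict[str, tuple[frozenset[str], frozenset[int]]]
    expected_peptide_taxids: dict[str, frozenset[int]]
    expected_go_counts_1: dict[str, int]
    expected_go_counts_2: dict[str, int]
    total_psms_1: int
    total_psms_2: int
    planted_peptides: list[str]
    go_parents: dict[str, frozenset[str]] = field(default_factory=dict)
    taxonomy_parent: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# naive helpers used only for ground truth


def _naive_matches(peptide: str, sequence: str) -> bool:
    pep = peptide.replace("I", "L")
    seq_folded = sequence.replace("I", "L")
    for pos in range(len(sequence) - len(peptide) + 1):
        if seq_folded[pos : pos + len(pep)] != pep:
            continue
        if pos == 0 or sequence[pos - 1] in "KR":
            return True
    return False


def _naive_closure(term: str, parents: dict[str, frozenset[str]]) -> set[str]:
    closure = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for parent in parents[node]:
            if parent not in closure:
                closure.add(parent)
                frontier.append(parent)
    return closure


def _go_counts(
    peptide_counts: dict[str, int],
    pep_map: dict[str, frozenset[str]],
    prot_go: dict[str, frozenset[str]],
    parents: dict[str, frozenset[str]],
    aspects: dict[str, str],
    unknowns: dict[str, str],
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for peptide, count in peptide_counts.items():
        graph: set[str] = set()
        for prot in pep_map[peptide]:
            for term in prot_go.get(prot, frozenset()):
                graph |= _naive_closure(term, parents)
        present = {aspects[t] for t in graph}
        for aspect, root in _ROOTS.items():
            if aspect not in present:
                graph.add(unknowns[aspect])
            graph.add(root)
        for term in graph:
            counts[term] = counts.get(term, 0) + count
    return counts


# ---------------------------------------------------------------------------
# writers


def _write_obo(
    path: Path,
    terms: list[tuple[str, str, str, list[str]]],
    alt_ids: dict[str, str],
    obsolete: list[tuple[str, str, str]],
) -> None:
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in alt_ids.items():
        alt_by_primary.setdefault(primary, []).append(alt)
    chunks = ["format-version: 1.2\nontology: synthetic-go\n"]
    for acc, name, aspect, parent_list in terms:
        lines = [f"[Term]", f"id: {acc}", f"name: {name}", f"namespace: {aspect}"]
        for alt in sorted(alt_by_primary.get(acc, [])):
            lines.append(f"alt_id: {alt}")
        for parent in parent_list:
            lines.append(f"is_a: {parent}")
        chunks.append("\n".join(lines) + "\n")
    for acc, name, aspect in obsolete:
        chunks.append(
            f"[Term]\nid: {acc}\nname: obsolete {name}\nnamespace: {aspect}\n"
            "is_obsolete: true\n"
        )
    path.write_text("\n".join(chunks), encoding="utf-8")


def _write_taxdump(
    out_dir: Path, nodes: dict[int, tuple[str, str, int]], merged: dict[int, int]
) -> tuple[Path, Path, Path]:
    nodes_path = out_dir / "nodes.dmp"
    names_path = out_dir / "names.dmp"
    merged_path = out_dir / "merged.dmp"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for taxid in sorted(nodes):
            name, rank, parent = nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for taxid in sorted(nodes):
            name, rank, parent = nodes[taxid]
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
            fh.write(f"{taxid}\t|\tsyn {name}\t|\t\t|\tsynonym\t|\n")
    with open(merged_path, "w", encoding="utf-8") as fh:
        for old in sorted(merged):
            fh.write(f"{old}\t|\t{merged[old]}\t|\n")
    return nodes_path, names_path, merged_path


def _write_peptide_list(path: Path, counts: dict[str, int]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide\tcount\n")
        for peptide in counts:
            fh.write(f"{peptide}\t{counts[peptide]}\n")


# ---------------------------------------------------------------------------
# generator


def generate_bundle(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Write a complete synthetic input bundle and return its manifest.

    Experiment 2 re-uses experiment 1's peptides with the first
    ``n_planted_peptides`` counts multiplied by ``planted_fold`` — a planted
    differential-abundance signal with known carriers.
    """
    if spec.n_planted_peptides > spec.n_peptides:
        raise ValueError(
            f"cannot plant {spec.n_planted_peptides} differential peptides "
            f"out of {spec.n_peptides}"
        )
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- ontology -----------------------------------------------------------
    terms: list[tuple[str, str, str, list[str]]] = []
    aspects: dict[str, str] = {}
    parents: dict[str, frozenset[str]] = {}
    annotatable: list[str] = []
    acc_counter = 1000001
    for aspect, root in _ROOTS.items():
        terms.append((root, aspect.replace("_", " "), aspect, []))
        aspects[root] = aspect
        parents[root] = frozenset()
        aspect_terms = [root]
        for i in range(spec.terms_per_aspect):
            acc = f"GO:{acc_counter:07d}"
            acc_counter += 1
            n_parents = 1 if len(aspect_terms) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(len(aspect_terms), size=min(n_parents, len(aspect_terms)), replace=False)
            parent_list = sorted(aspect_terms[j] for j in chosen)
            terms.append((acc, f"{aspect.split('_')[1]} term {i}", aspect, parent_list))
            aspects[acc] = aspect
            parents[acc] = frozenset(parent_list)
            aspect_terms.append(acc)
            annotatable.append(acc)
    alt_ids = {f"GO:{acc_counter:07d}": annotatable[0]}
    acc_counter += 1
    obsolete = [(f"GO:{acc_counter:07d}", "retired term", "molecular_function")]
    acc_counter += 1
    obo_path = out_dir / "ontology.obo"
    _write_obo(obo_path, terms, alt_ids, obsolete)

    # --- taxonomy -----------------------------------------------------------
    tax_nodes: dict[int, tuple[str, str, int]] = {1: ("root", "no rank", 1)}
    level = [1]
    next_id = 2
    species: list[int] = []
    for depth, rank in enumerate(_CANONICAL_RANKS):
        new_level = []
        for parent in level:
            n_children = spec.n_superkingdoms if depth == 0 else spec.taxonomy_children
            for _ in range(n_children):
                tax_nodes[next_id] = (f"{rank} {next_id}", rank, parent)
                new_level.append(next_id)
                next_id += 1
        level = new_level
    species = [t for t, (_, rank, _) in tax_nodes.items() if rank == "species"]
    merged = {next_id + 1000: species[0]}
    nodes_path, names_path, merged_path = _write_taxdump(out_dir, tax_nodes, merged)

    # --- reference proteins: GO + taxon maps --------------------------------
    ref_go: dict[str, frozenset[str]] = {}
    ref_tax: dict[str, int] = {}
    for i in range(spec.n_reference_proteins):
        accession = f"REF{i:04d}"
        if i == spec.n_reference_proteins - 1:
            ref_go[accession] = frozenset()  # unannotated reference: unknown path
        else:
            k = int(rng.integers(1, 4))
            chosen = rng.choice(len(annotatable), size=min(k, len(annotatable)), replace=False)
            ref_go[accession] = frozenset(annotatable[j] for j in chosen)
        ref_tax[accession] = int(species[int(rng.integers(len(species)))])
    go_map_path = out_dir / "go_map.tsv"
    with open(go_map_path, "w", encoding="utf-8") as fh:
        for accession in sorted(ref_go):
            if ref_go[accession]:
                fh.write(f"{accession}\t{','.join(sorted(ref_go[accession]))}\n")
    taxon_map_path = out_dir / "taxon_map.tsv"
    with open(taxon_map_path, "w", encoding="utf-8") as fh:
        for accession in sorted(ref_tax):
            fh.write(f"{accession}\t{ref_tax[accession]}\n")

    # --- peptides and user proteins ----------------------------------------
    def random_peptide() -> str:
        length = int(rng.integers(7, 13))
        body = "".join(rng.choice(_ALPHABET) for _ in range(length - 1))
        return body + ("K" if rng.random() < 0.5 else "R")

    peptides = []
    seen = set()
    while len(peptides) < spec.n_peptides + spec.n_decoys:
        pep = random_peptide()
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)
    decoys = peptides[spec.n_peptides :]
    peptides = peptides[: spec.n_peptides]

    n_prot = spec.n_reference_proteins
    assignments: dict[int, list[str]] = {i: [] for i in range(n_prot)}
    for pep in peptides:
        n_hosts = 2 if rng.random() < 0.3 else 1
        hosts = rng.choice(n_prot, size=n_hosts, replace=False)
        for host in hosts:
            assignments[int(host)].append(pep)

    def random_segment(lo: int = 4, hi: int = 10) -> str:
        return "".join(rng.choice(_ALPHABET) for _ in range(int(rng.integers(lo, hi))))

    protein_seqs: dict[str, str] = {}
    for i in range(n_prot):
        pid = f"prot{i:04d}"
        parts = []
        implanted = assignments[i]
        for j, pep in enumerate(implanted):
            if j == 0 and rng.random() < 0.3:
                parts.append(pep)  # N-terminal occurrence
            else:
                parts.append(random_segment() + ("K" if rng.random() < 0.5 else "R") + pep)
        parts.append(random_segment())
        if i < spec.n_decoys and decoys:
            # implant a decoy with an invalid (non-K/R) preceding residue
            parts.append("G" + decoys[i % len(decoys)] + random_segment())
        protein_seqs[pid] = "".join(parts)
    fasta_path = out_dir / "database.fasta"
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for pid in sorted(protein_seqs):
            fh.write(f">{pid} synthetic\n{protein_seqs[pid]}\n")

    # --- homology hits ------------------------------------------------------
    blast_path = out_dir / "hits.blast.tsv"
    expected_subjects: dict[str, set[str]] = {}
    with open(blast_path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic BLAST tabular\n")

        def row(q: str, s: str, evalue: float, bits: float) -> None:
            fh.write(f"{q}\t{s}\t100.0\t50\t0\t0\t1\t50\t1\t50\t{evalue:g}\t{bits:g}\n")

        for i in range(n_prot):
            pid = f"prot{i:04d}"
            primary = f"REF{i:04d}"
            row(pid, primary, 1e-50, 200.0)
            expected_subjects[pid] = {primary}
            if i % 5 == 1:  # tie for best score: both retained
                tie = f"REF{(i + 1) % n_prot:04d}"
                row(pid, tie, 1e-50, 200.0)
                expected_subjects[pid].add(tie)
            if i % 5 == 2:  # passes cutoff, loses the top-hit tie-break
                row(pid, f"REF{(i + 2) % n_prot:04d}", 1e-20, 100.0)
            if i % 5 == 3:  # fails the E-value cutoff
                row(pid, f"REF{(i + 3) % n_prot:04d}", 1e-3, 30.0)

    # --- ground truth -------------------------------------------------------
    unknowns = {
        "biological_process": "unknownprc",
        "molecular_function": "unknownfun",
        "cellular_component": "unknowncmp",
    }
    all_peps = peptides + decoys
    pep_map = {
        pep: frozenset(
            pid for pid, seq in protein_seqs.items() if _naive_matches(pep, seq)
        )
        for pep in all_peps
    }
    prot_annotations = {
        pid: (
            frozenset().union(*(ref_go[s] for s in subjects)) if subjects else frozenset(),
            frozenset(ref_tax[s] for s in subjects),
        )
        for pid, subjects in expected_subjects.items()
    }
    prot_go = {pid: go for pid, (go, _) in prot_annotations.items()}
    pep_taxids = {
        pep: frozenset().union(
            *(prot_annotations[pid][1] for pid in pep_map[pep]), frozenset()
        )
        for pep in all_peps
    }

    counts_1 = {
        pep: int(rng.poisson(spec.mean_count)) + 1 for pep in all_peps
    }
    planted = peptides[: spec.n_planted_peptides]
    counts_2 = {
        pep: (
            int(round(counts_1[pep] * spec.planted_fold)) if pep in planted
            else counts_1[pep]
        )
        for pep in all_peps
    }
    aspects_with_unknowns = dict(aspects)
    for aspect, acc in unknowns.items():
        aspects_with_unknowns[acc] = aspect
        parents.setdefault(acc, frozenset({_ROOTS[aspect]}))

    peptides_1_path = out_dir / "peptides_1.tsv"
    peptides_2_path = out_dir / "peptides_2.tsv"
    _write_peptide_list(peptides_1_path, counts_1)
    _write_peptide_list(peptides_2_path, counts_2)

    go_counts_1 = _go_counts(counts_1, pep_map, prot_go, parents, aspects_with_unknowns, unknowns)
    go_counts_2 = _go_counts(counts_2, pep_map, prot_go, parents, aspects_with_unknowns, unknowns)

    manifest = FixtureManifest(
        paths={
            "fasta": fasta_path,
            "peptides_1": peptides_1_path,
            "peptides_2": peptides_2_path,
            "blast": blast_path,
            "go_map": go_map_path,
            "taxon_map": taxon_map_path,
            "obo": obo_path,
            "nodes": nodes_path,
            "names": names_path,
            "merged": merged_path,
        },
        expected_peptide_protein_map=pep_map,
        expected_protein_annotations=prot_annotations,
        expected_peptide_taxids=pep_taxids,
        expected_go_counts_1=go_counts_1,
        expected_go_counts_2=go_counts_2,
        total_psms_1=sum(counts_1.values()),
        total_psms_2=sum(counts_2.values()),
        planted_peptides=list(planted),
        go_parents=parents,
        taxonomy_parent={t: p for t, (_, _, p) in tax_nodes.items()},
    )
    ground_truth_path = out_dir / "ground_truth.json"
    ground_truth_path.write_text(
        json.dumps(
            {
                "go_counts_1": go_counts_1,
                "go_counts_2": go_counts_2,
                "total_psms_1": manifest.total_psms_1,
                "total_psms_2": manifest.total_psms_2,
                "planted_peptides": manifest.planted_peptides,
            },
            sort_keys=True,
            indent=1,
        ),
        encoding="utf-8",
    )
    manifest.paths["ground_truth"] = ground_truth_path
    return manifest


def reference_count_bundle(out_dir: str | Path) -> FixtureManifest:
    """A hand-shaped bundle whose experiment-1 GO counts hit round numbers.

    Built so the pipeline produces total_psms = 12,217 with counts
    binding = 4185, ATP binding = 1712, unknown biological process = 5472,
    transporter complex = 200, and every aspect root equal to the total —
    a compact, fully specified worked example for documentation and
    end-to-end checks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    terms = [
        ("GO:0008150", "biological process", "biological_process", []),
        ("GO:0009987", "cellular process", "biological_process", ["GO:0008150"]),
        ("GO:0003674", "molecular function", "molecular_function", []),
        ("GO:0005488", "binding", "molecular_function", ["GO:0003674"]),
        ("GO:0005524", "ATP binding", "molecular_function", ["GO:0005488"]),
        ("GO:0003824", "catalytic activity", "molecular_function", ["GO:0003674"]),
        ("GO:0005575", "cellular component", "cellular_component", []),
        ("GO:1990351", "transporter complex", "cellular_component", ["GO:0005575"]),
        ("GO:0016020", "membrane", "cellular_component", ["GO:0005575"]),
    ]
    obo_path = out_dir / "ontology.obo"
    _write_obo(obo_path, terms, {}, [])

    tax_nodes = {
        1: ("root", "no rank", 1),
        2: ("Bacteria", "superkingdom", 1),
        3: ("Proteobacteria", "phylum", 2),
        4: ("Betaproteobacteria", "class", 3),
        5: ("Burkholderiales", "order", 4),
        6: ("Neisseriales", "order", 4),
        9: ("Burkholderiaceae", "family", 5),
        10: ("Neisseriaceae", "family", 6),
        11: ("Burkholderia", "genus", 9),
        12: ("Neisseria", "genus", 10),
        7: ("sp. one", "species", 11),
        8: ("sp. two", "species", 12),
    }
    nodes_path, names_path, merged_path = _write_taxdump(out_dir, tax_nodes, {})

    # peptide -> (count, direct GO terms of its reference protein, taxid)
    plan = [
        ("AAAGGGPEPK", 1712, "GO:0005524,GO:0009987", 7),   # ATP binding + a BP
        ("CCCDDDPEPK", 2473, "GO:0005488,GO:0009987", 7),   # binding directly + a BP
        ("EEEFFFPEPK", 200, "GO:1990351", 8),               # CC only: unknown BP + MF
        ("GGGHHHPEPK", 5272, "GO:0003824", 8),              # MF only: unknown BP + CC
        ("MMMNNNPEPK", 2560, "GO:0009987,GO:0003824,GO:0016020", 7),  # fills the total
    ]
    assert sum(c for _, c, _, _ in plan) == 12217

    fasta_path = out_dir / "database.fasta"
    blast_path = out_dir / "hits.blast.tsv"
    go_map_path = out_dir / "go_map.tsv"
    taxon_map_path = out_dir / "taxon_map.tsv"
    peptides_path = out_dir / "peptides_1.tsv"
    with open(fasta_path, "w", encoding="utf-8") as fa, open(
        blast_path, "w", encoding="utf-8"
    ) as bl, open(go_map_path, "w", encoding="utf-8") as gm, open(
        taxon_map_path, "w", encoding="utf-8"
    ) as tm, open(peptides_path, "w", encoding="utf-8") as pl:
        pl.write("peptide\tcount\n")
        for i, (pep, count, go_terms, taxid) in enumerate(plan):
            pid, ref = f"prot{i:04d}", f"REF{i:04d}"
            fa.write(f">{pid}\n{pep}AAAG\n")  # N-terminal implant
            bl.write(f"{pid}\t{ref}\t100.0\t50\t0\t0\t1\t50\t1\t50\t1e-50\t200\n")
            gm.write(f"{ref}\t{go_terms}\n")
            tm.write(f"{ref}\t{taxid}\n")
            pl.write(f"{pep}\t{count}\n")

    expected = {
        "GO:0008150": 12217,               # aspect roots always hit the total
        "GO:0009987": 1712 + 2473 + 2560,
        "unknownprc": 200 + 5272,
        "GO:0003674": 12217,
        "GO:0005488": 1712 + 2473,
        "GO:0005524": 1712,
        "GO:0003824": 5272 + 2560,
        "unknownfun": 200,
        "GO:0005575": 12217,
        "GO:1990351": 200,
        "GO:0016020": 2560,
        "unknowncmp": 1712 + 2473 + 5272,
    }
    return FixtureManifest(
        paths={
            "fasta": fasta_path,
            "peptides_1": peptides_path,
            "blast": blast_path,
            "go_map": go_map_path,
            "taxon_map": taxon_map_path,
            "obo": obo_path,
            "nodes": nodes_path,
            "names": names_path,
            "merged": merged_path,
        },
        expected_peptide_protein_map={
            pep: frozenset({f"prot{i:04d}"}) for i, (pep, _, _, _) in enumerate(plan)
        },
        expected_protein_annotations={},
        expected_peptide_taxids={
            pep: frozenset({taxid}) for pep, _, _, taxid in plan
        },
        expected_go_counts_1=expected,
        expected_go_counts_2={},
        total_psms_1=12217,
        total_psms_2=0,
        planted_peptides=[],
    )
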
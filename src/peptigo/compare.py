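"""Two-experiment comparison of GO spectral-count proportions (step 3).

For every GO term seen in either experiment the per-term proportion of
spectra is compared between the two runs: a log2 fold change on
Laplace-corrected proportions (add-one pseudocount, so terms observed in
only one experiment still get a finite fold change), a two-tailed pooled
two-proportion z-test on the raw counts, and Bonferroni / Benjamini-Hochberg
multiple-testing correction over the union of terms.

The comparison DAG is "trimmed" for display by iteratively deleting every
leaf whose q-value exceeds the threshold (default 0.01); interior
non-significant terms survive when they have a surviving descendant, which
preserves the hierarchical context of the significant leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .go_quant import GoCountTable, GoOntology


def laplace_proportion(count, total):
    """Add-one-corrected proportion ``(count + 1) / (total + 1)``.

    Strictly positive even at ``count = 0``, which is what keeps log fold
    changes finite for terms observed in only one experiment.  Accepts
    scalars or arrays.
    """
    count = np.asarray(count)
    total = np.asarray(total)
    if np.any(total < 1):
        raise ValueError("total must be >= 1")
    if np.any(count < 0) or np.any(count > total):
        raise ValueError("count must satisfy 0 <= count <= total")
    result = (count + 1.0) / (total + 1.0)
    return result.item() if result.ndim == 0 else result


def log2_fold_change(count_1, total_1, count_2, total_2):
    """log2 of experiment-2 over experiment-1 Laplace-corrected proportions."""
    p1 = laplace_proportion(count_1, total_1)
    p2 = laplace_proportion(count_2, total_2)
    result = np.log2(np.asarray(p2) / np.asarray(p1))
    return result.item() if np.ndim(result) == 0 else result


def proportion_test(count_1, total_1, count_2, total_2):
    """Two-tailed pooled two-proportion z-test on the raw counts.

    Pooled proportion ``p = (c1 + c2) / (n1 + n2)``, standard error
    ``sqrt(p (1 - p) (1/n1 + 1/n2))``, no continuity correction.  A
    degenerate pooled proportion (0 or 1 — both samples all-zero or
    all-total) returns p-value 1.  Accepts scalars or arrays.
    """
    c1 = np.asarray(count_1, dtype=float)
    n1 = np.asarray(total_1, dtype=float)
    c2 = np.asarray(count_2, dtype=float)
    n2 = np.asarray(total_2, dtype=float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("totals must be >= 1")
    pooled = (c1 + c2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (c2 / n2 - c1 / n1) / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return p.item() if p.ndim == 0 else p


def adjust_pvalues(p_values: Sequence[float], method: str) -> np.ndarray:
    """Multiple-testing adjustment over ``m = len(p_values)`` tests.

    ``bonferroni``: ``min(p * m, 1)``.  ``bh``: Benjamini-Hochberg step-up
    q-values.  Results are returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


COMPARISON_COLUMNS = [
    "go_accession", "go_aspect", "go_name",
    "ratio_1", "ratio_2", "count_1", "count_2",
    "log2_fold_change", "p_value", "p_bonferroni", "q_value",
]


def compare_experiments(
    table_1: GoCountTable,
    table_2: GoCountTable,
    ontology: GoOntology | None = None,
    *,
    laplace_denominator: str = "psm",
) -> pd.DataFrame:
    """One comparison row per GO term in the union of the two experiments.

    A term absent from one experiment contributes count 0 there.  The number
    of tests for both corrections is the size of the union, unknown and root
    nodes included.  Rows are sorted by q-value then accession.

    ``laplace_denominator`` selects the pseudocount normalization for the
    fold change: ``"psm"`` (default) uses ``(c + 1) / (N + 1)``;
    ``"terms"`` uses ``(c + 1) / (N + m)`` with ``m`` the union size, i.e.
    one pseudo-observation per compared term.  The z-test always uses the
    raw counts.
    """
    if table_1.unknown_config != table_2.unknown_config:
        raise ValueError(
            "experiments were built with different unknown-node configs: "
            f"{table_1.unknown_config} vs {table_2.unknown_config}"
        )
    if (
        table_1.ontology_fingerprint is not None
        and table_2.ontology_fingerprint is not None
        and table_1.ontology_fingerprint != table_2.ontology_fingerprint
    ):
        raise ValueError("experiments were built against different ontologies")
    terms = sorted(set(table_1.counts) | set(table_2.counts))
    info = {**table_2.term_info, **table_1.term_info}
    c1 = np.array([table_1.counts.get(t, 0) for t in terms])
    c2 = np.array([table_2.counts.get(t, 0) for t in terms])
    n1, n2 = table_1.total_psms, table_2.total_psms
    if laplace_denominator == "psm":
        log2fc = log2_fold_change(c1, n1, c2, n2)
    elif laplace_denominator == "terms":
        m = len(terms)
        log2fc = np.log2(((c2 + 1.0) / (n2 + m)) / ((c1 + 1.0) / (n1 + m)))
    else:
        raise ValueError(f"unknown laplace_denominator mode {laplace_denominator!r}")
    p = proportion_test(c1, n1, c2, n2)
    frame = pd.DataFrame(
        {
            "go_accession": terms,
            "go_aspect": [info[t][0] for t in terms],
            "go_name": [info[t][1] for t in terms],
            "ratio_1": c1 / n1,
            "ratio_2": c2 / n2,
            "count_1": c1,
            "count_2": c2,
            "log2_fold_change": log2fc,
            "p_value": p,
            "p_bonferroni": adjust_pvalues(p, "bonferroni"),
            "q_value": adjust_pvalues(p, "bh"),
        },
        columns=COMPARISON_COLUMNS,
    )
    return frame.sort_values(
        ["q_value", "go_accession"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class TrimmedDag:
    """A comparison DAG with all non-significant leaves iteratively removed.

    ``nodes`` maps accession → (name, log2_fold_change, q_value, category);
    category is ``up`` (significant, positive fold change), ``down``
    (significant, negative or zero) or ``ns``.  ``edges`` are (child, parent)
    "is a" pairs restricted to retained nodes.
    """

    nodes: dict[str, tuple[str, float, float, str]]
    edges: frozenset[tuple[str, str]]
    q_threshold: float

    def to_dot(self, graph_name: str = "go_comparison") -> str:
        """Graphviz DOT: parallelogram/yellow for up, box/blue for down,
        grey for non-significant; deterministic node and edge order."""
        style = {
            "up": 'shape=parallelogram, style=filled, fillcolor="#ffe066"',
            "down": 'shape=box, style=filled, fillcolor="#9ecae1"',
            "ns": 'shape=box, style=filled, fillcolor="#d9d9d9"',
        }
        lines = [f"digraph {graph_name} {{"]
        for acc in sorted(self.nodes):
            name, lfc, q, category = self.nodes[acc]
            label = f"{name}\\n{acc}\\nlog2FC={lfc:.3g}\\nq={q:.3g}"
            lines.append(f'  "{acc}" [label="{label}", {style[category]}];')
        for child, parent in sorted(self.edges):
            lines.append(f'  "{child}" -> "{parent}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def _direct_parents(
    accession: str,
    aspect: str,
    retained: set[str],
    ontology: GoOntology,
) -> set[str]:
    if accession in ontology:
        return set(ontology.parents(accession)) & retained
    # synthetic unknown node: child of its aspect root
    root = ontology.roots.get(aspect)
    return {root} if root in retained else set()


def trim_dag(
    rows: pd.DataFrame,
    ontology: GoOntology,
    q_threshold: float = 0.01,
) -> TrimmedDag:
    """Iteratively delete every current leaf with ``q > q_threshold``.

    A leaf is a node with no retained children under the direct "is a" edges
    induced by the row set.  The fixed point has every leaf significant;
    interior non-significant nodes survive through their significant
    descendants.  The result may be empty.
    """
    q = dict(zip(rows["go_accession"], rows["q_value"]))
    retained = set(rows["go_accession"])
    meta = {
        acc: (name, lfc)
        for acc, name, lfc in zip(
            rows["go_accession"], rows["go_name"], rows["log2_fold_change"]
        )
    }
    aspect = dict(zip(rows["go_accession"], rows["go_aspect"]))
    # child -> parents (restricted); recompute children counts incrementally
    parents_of = {
        acc: _direct_parents(acc, aspect[acc], retained, ontology) for acc in retained
    }
    n_children = {acc: 0 for acc in retained}
    for child, parents in parents_of.items():
        for parent in parents:
            n_children[parent] += 1
    frontier = [acc for acc in retained if n_children[acc] == 0 and q[acc] > q_threshold]
    while frontier:
        acc = frontier.pop()
        retained.discard(acc)
        for parent in parents_of[acc]:
            n_children[parent] -= 1
            if (
                parent in retained
                and n_children[parent] == 0
                and q[parent] > q_threshold
            ):
                frontier.append(parent)
    nodes = {}
    for acc in retained:
        name, lfc = meta[acc]
        if q[acc] <= q_threshold:
            category = "up" if lfc > 0 else "down"
        else:
            category = "ns"
        nodes[acc] = (name, float(lfc), float(q[acc]), category)
    edges = frozenset(
        (child, parent)
        for child in retained
        for parent in parents_of[child]
        if parent in retained
    )
    return TrimmedDag(nodes=nodes, edges=edges, q_threshold=q_threshold)
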
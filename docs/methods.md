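# Methods

## Model and assumptions

`peptigo` treats a metaproteomics experiment as a bag of peptide-spectrum
matches (PSMs): a list of peptide sequences with non-negative integer
abundances (spectral counts, or any integer relative-abundance measure). The
quantities it estimates are *relative*: the proportion of all spectra in an
experiment attributable to a GO term, and within a GO term the proportion
attributable to a taxon. No absolute-abundance interpretation is attempted,
and no protein inference is performed — a peptide shared by many proteins
contributes the union of their annotations, exactly once per spectrum.

Assumptions baked into the matching step:

- **Tryptic digestion.** A peptide can only originate at a protein's
  N-terminus or immediately after a literal K or R. The C-terminal side is
  unconstrained by default because chromatographic/in-source fragments and
  ragged C-termini are common; `strict_tryptic` additionally demands the
  match end in K/R or at the protein C-terminus.
- **I/L equivalence.** Isoleucine and leucine are isobaric and
  indistinguishable by MS, so both strings are folded I→L before comparison.
  The *boundary* residue check is on the literal protein residue (K/R are
  unaffected by the fold anyway).
- **Ambiguity codes.** B, Z, X, U, O in database proteins never match any
  peptide residue, X included. This is deliberately conservative: a match
  through an ambiguous position would transfer annotations on no evidence.
- Peptide-list PSM filtering (e.g. at 1% peptide-level FDR) is assumed done
  upstream by the search pipeline.

## Step 1: GO quantification

Per peptide, the non-redundant GO graph is the union over matched proteins of
the ancestor closures (following **"is a" edges only**) of their direct GO
terms. Partonomy (`part_of`) is excluded by default because only subsumption
makes an ancestor's count readable as "spectra for this function or anything
more specific"; a load-time flag can include it. Obsolete direct annotations
are dropped with a warning rather than chased through `replaced_by`, and
`alt_id`s resolve to their primary terms.

Peptides with no annotation in an aspect feed a synthetic *unknown* node
(`unknownprc` / `unknownfun` / `unknowncmp` — the BP string is conventional,
the MF/CC strings are chosen by analogy and configurable) inserted as a child
of that aspect's root. The three aspect roots are always included in every
peptide graph, so each root's count equals the experiment total and every
ratio is a true proportion of uploaded spectra. Peptides matching *no*
protein are kept by default and routed to all three unknowns — dropping them
(`drop_unmatched`) changes the denominator, which is then the post-exclusion
total so that ratios remain proportions of retained spectra.

Invariants maintained (and asserted in tests): count(parent) ≥ count(child)
for every is_a edge; max count ≤ total; duplicating a protein changes
nothing; input order is irrelevant.

## Step 2: taxonomic attribution

The taxid set of a peptide is the union of taxa of its matched proteins'
retained homology hits (the *same* filtered hit set used for GO transfer).
Its lowest common ancestor is the deepest node on all lineages; the peptide's
count is added along the LCA's entire root lineage. A peptide whose matched
proteins carry no taxonomy is tallied as "unattributed" for that GO term and
touches no taxon — the tree is not polluted with a fake node.

The summed fraction of a GO term's count at one rank
(Σ<sub>taxa at rank</sub> count/GO-count) is reported for the seven canonical
ranks (superkingdom → species); non-canonical ranks ("no rank", "clade")
remain in lineages and tables but are excluded from the diagnostic. The sums
are non-increasing toward more specific ranks, provided every lineage
traverses all seven ranks (true of NCBI lineages for the canonical ranks and
of generated fixtures; a taxonomy that skips a rank entirely would show a dip
at the skipped rank).

## Homology-hit filtering

Hits arrive as NCBI BLAST tabular (`-outfmt 6`); running BLAST is out of
scope. Filtering: discard hits with E-value > cutoff (default 10⁻¹⁰,
comparison inclusive), then under `top_hit_only` (default) keep **all** hits
tied for the maximum surviving bit score — ties are never broken arbitrarily,
since an arbitrary winner would silently bias taxonomy. With the flag off,
all survivors are kept.

## Step 3: comparison statistics

- **Fold change:** log2 of Laplace-corrected proportions,
  (c+1)/(N+1), experiment 2 over experiment 1. The add-one pseudocount exists
  solely to keep the log finite when a term is absent from one run. Because
  per-term counts overlap (ancestor propagation), a shared
  "total-plus-number-of-terms" denominator is not well defined; the
  per-term (c+1)/(N+1) form is the default and an (c+1)/(N+m) variant (m =
  number of compared terms) is available as `laplace_denominator="terms"`.
- **Test:** two-tailed two-proportion z-test on the **raw** counts with
  pooled proportion p̂ = (c₁+c₂)/(N₁+N₂) and SE = √(p̂(1−p̂)(1/N₁+1/N₂)), no
  continuity correction (kept elementary and documented; checked against
  statsmodels' pooled implementation). Degenerate pooled proportions (0 or 1)
  return p = 1. The z approximation is poor for expected counts below ~5;
  with metaproteomics totals in the thousands this affects only the rarest
  terms, whose q-values are far from significance anyway.
- **Correction:** Bonferroni and Benjamini–Hochberg over m = |union of terms|,
  unknown and root nodes included (they are reportable results in their own
  right). Both are delegated to `statsmodels.stats.multitest`; the step-up
  definition is verified independently in the test suite.
- P-values of the many overlapping GO terms are strongly dependent
  (ancestors share counts with descendants); BH remains valid under the
  positive-dependence structure this induces, but q-values of nested terms
  should be read jointly, not as independent discoveries.

## DAG trimming

Starting from the sub-DAG induced by the compared terms (direct is_a edges
only; synthetic unknown nodes hang under their aspect roots), leaves with
q > 0.01 are deleted iteratively until every remaining leaf is significant.
Interior non-significant terms survive if they have a surviving descendant,
preserving the hierarchical context of each significant leaf. The result is a
fixed point (re-trimming changes nothing) and may be empty. Export is
Graphviz DOT: significant positive fold changes are yellow parallelograms,
significant negative ones blue boxes, the rest grey; labels carry name,
accession, log2FC and q.

## Synthetic data generator

`fixtures.generate_bundle` emits all seven input files plus a ground-truth
JSON, fully determined by a seed. Defaults (12 reference proteins, 6 GO terms
per aspect, a complete 7-rank taxonomy with branching 2, 20 peptides with
counts ~ 1 + Poisson(12), 2 bad-boundary decoys, 3 peptides planted at
4-fold abundance in experiment 2) are sized so every code path — shared
peptides, hit ties, sub-threshold hits, unannotated references, unknown-node
routing, merged taxids — occurs in one small bundle while the whole suite
stays fast. Ground truth is computed inside the generator with naive
independent logic (positional scans, repeated edge expansion), so
pipeline-equals-truth tests are genuine dual-route checks.

What the generator does **not** emulate: realistic sequence homology (hits
are constructed, not aligned), search-engine score distributions, realistic
GO/taxonomy scale (thousands of terms, tens of ranks), or modified peptides.
Passing tests therefore demonstrate algorithmic correctness on the defined
contracts, not end-to-end performance on real community samples.

A second, hand-shaped bundle (`reference_count_bundle`) plants exact counts —
total 12,217 PSMs with binding = 4185, ATP binding = 1712, unknown BP = 5472,
transporter complex = 200 — so the documented worked-example ratios (1, 0.34,
0.14, 0.45, 0.02 at two decimals) are reproduced by the full pipeline, not by
arithmetic alone.

## Numerical and formatting choices

- Ratios/statistics are kept at full double precision internally and in the
  JSON sidecars; display TSVs round to 6 significant/decimal digits so that
  report rounding can never propagate into comparisons.
- Report ordering is fixed (GO: aspect, count desc, accession; taxa: count
  desc, name asc; comparison: q asc, accession) purely for byte-reproducible
  outputs.
- Sidecars embed an ontology fingerprint, the unknown-node configuration and
  the behaviour flags; `compare` refuses sidecars that disagree on any of
  them.
- Exit codes: 0 success, 1 input error, 2 internal invariant violation.
  Warnings carry stable greppable codes (PEP01, ANN01/02, GOQ01, TAX01).

## Problem sizes in the checks

The repository's verification suite uses deliberately compact instances
chosen to exercise each property at high power: 200 random
(database, peptide) instances for the matcher oracle, 500 random tree/set
draws for the LCA oracle, 500 replicates of a 200-term / 5,000-PSM
multinomial null for z-test calibration (nominal 0.05 recovered within
±0.02), and a 50-term / 10,000-PSM comparison with five 4-fold planted terms
for rank recovery.

## Known limitations

- Pairwise comparisons only; no multi-group designs or replicate modelling
  (spectral counts from replicates must be summed or compared pairwise).
- Spectral counts are treated as exact integers; abundance uncertainty and
  run-to-run normalization beyond proportion scaling are out of scope.
- GO `part_of` (off by default) and `replaced_by` chasing are not traversed
  in the default configuration.
- Peptides mapping to proteins whose homology hits lack taxonomy are
  invisible to the taxonomic step (reported as unattributed).
- The matcher is O(peptides × proteins × length) via substring scans, ample
  for trimmed databases (the intended input) but not optimized for
  multi-gigabyte FASTA files.
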
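# peptigo

Peptide-centric functional and taxonomic quantification for metaproteomics.

Shotgun proteomics of a mixed microbial community identifies *peptides*, and
most peptides are shared by proteins from many organisms. Classical protein
inference is ill-posed in that setting, so `peptigo` avoids it entirely:
spectral counts are aggregated directly from peptides onto Gene Ontology (GO)
terms and, per GO term, onto unambiguous taxonomic units. Two experiments can
then be compared term-by-term with proper multiple-testing control. The
intended users are proteomics/microbiome researchers with a peptide list plus
spectral counts from any search engine, the FASTA database they searched, and
precomputed BLAST hits against an annotated reference such as UniProtKB.

## The method

**Step 1 — functional quantification.** Each peptide is matched to every
database protein that contains it at a tryptic position (N-terminal, or
immediately after K/R; I and L are interchangeable since they are isobaric).
Proteins inherit GO terms from their filtered homology hits (E-value cutoff
10⁻¹⁰ by default; "top hit" keeps all hits tied for the best bit score). For
a peptide *p* the non-redundant GO graph is

&nbsp;&nbsp;&nbsp;&nbsp;G(p) = ⋃<sub>proteins P ∋ p</sub> ⋃<sub>t ∈ GO(P)</sub> closure<sub>is_a</sub>(t),

and every term in G(p) gains the peptide's spectral count once, so a spectrum
never counts twice for the same annotation. Per aspect (BP/MF/CC), peptides
with no annotation feed a synthetic *unknown* node under the aspect root;
consequently each aspect root's count equals the experiment total N, and each
term's ratio is count/N.

**Step 2 — taxonomic attribution.** For each GO term, every contributing
peptide's matched-protein taxa are reduced to their lowest common ancestor
(LCA) — the most specific taxon the peptide supports unambiguously — and the
count is added along the LCA's full lineage. Summing each rank's share of the
term's count gives a monotone diagnostic (superkingdom ≥ … ≥ species) for
choosing the most specific usable rank.

**Step 3 — comparison.** For each term in the union of two experiments, the
log2 fold change uses add-one (Laplace) corrected proportions
(c+1)/(N+1) — finite even for terms seen in only one run — while the p-value
comes from a two-tailed pooled two-proportion z-test on the raw counts.
Bonferroni and Benjamini–Hochberg corrections are computed over the union.
For display, the comparison DAG is trimmed by iteratively deleting every leaf
with q > 0.01, leaving only significant leaves while preserving their
ancestry, and exported as Graphviz DOT.

## Worked example

Everything runs offline from generated inputs:

```bash
peptigo fixtures --seed 7 --out demo
peptigo quantify --fasta demo/database.fasta --peptides demo/peptides_1.tsv \
    --blast demo/hits.blast.tsv --go-map demo/go_map.tsv \
    --taxon-map demo/taxon_map.tsv --obo demo/ontology.obo \
    --nodes demo/nodes.dmp --names demo/names.dmp --merged demo/merged.dmp \
    --out-dir demo/run1
# wrote demo/run1/go_report.tsv (21 GO terms, 318 PSMs)
head -4 demo/run1/go_report.tsv
# go_accession  go_aspect          go_name                     spectral_count  ratio
# GO:0008150    biological_process biological process          318             1.000000
# GO:1000001    biological_process process term 0              146             0.459119
# unknownprc    biological_process unknown biological process  128             0.402516
```

The root count equals the 318 uploaded PSMs (unmatched peptides are routed to
the per-aspect unknown nodes), and each ratio is the fraction of all spectra
attributable to that term or anything more specific. Quantifying the second
peptide list the same way (`--peptides demo/peptides_2.tsv --out-dir
demo/run2`) and comparing:

```bash
peptigo compare demo/run1/go_counts.json demo/run2/go_counts.json \
    --obo demo/ontology.obo --out-dir demo/cmp
# wrote demo/cmp/comparison.tsv (21 terms; 2 significant at q<=0.01;
#  trimmed DAG has 11 node(s))
```

`comparison.tsv` holds, per term, both ratios and counts, the Laplace-based
log2 fold change, the raw and Bonferroni p-values and the BH q-value;
`comparison_trimmed.dot` is the trimmed graph (yellow parallelograms up,
blue boxes down, grey not significant). Per-term taxonomic tables come from
`peptigo taxa --terms all` and include the summed-fraction-by-rank
diagnostic as trailing comment lines.

The same operations are importable (`peptigo.run_quantify`,
`peptigo.compare_experiments`, `peptigo.go_term_taxon_table`, …) for use
from notebooks.

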
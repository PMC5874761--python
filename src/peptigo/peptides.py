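"""Peptide-to-protein matching under tryptic-boundary and I/L-equivalence rules.

Shotgun metaproteomics identifies peptides, not proteins.  This module maps
each observed peptide back to every protein in the searched FASTA database
that could have produced it under tryptic digestion: the match must start at
the protein N-terminus or immediately after a lysine (K) or arginine (R),
and isoleucine/leucine are treated as indistinguishable (their residue
masses are identical, so no mass spectrometer can tell them apart).

No protein inference is attempted: a peptide shared by many proteins is
deliberately mapped to all of them, and downstream quantification works on
the union of their annotations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger("peptigo")

#: the 20 standard amino acids
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: ambiguity / non-standard codes tolerated in database proteins but never
#: matched by any peptide residue
AMBIGUOUS_RESIDUES = frozenset("BZXUO")

# I and L are isobaric: fold both to L before comparison.  Ambiguity codes are
# folded to a sentinel that cannot occur in a validated peptide, so they can
# never produce a match.
_IL_FOLD = str.maketrans({"I": "L", "B": "\x00", "Z": "\x00", "X": "\x00",
                          "U": "\x00", "O": "\x00"})


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: the first whitespace-delimited header token and the
    uppercased amino-acid sequence."""

    protein_id: str
    sequence: str


@dataclass(frozen=True)
class PeptideObservation:
    """A peptide sequence with its integer relative abundance (spectral
    count, i.e. the number of PSMs supporting it)."""

    peptide: str
    abundance: int


def read_fasta(path: str | Path, *, allow_ambiguous: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased and input order is preserved.  Duplicate ids,
    empty sequences and residues outside the 20 standard amino acids (plus,
    when ``allow_ambiguous``, the codes B/Z/X/U/O) are hard errors.
    """
    allowed = STANDARD_RESIDUES | (AMBIGUOUS_RESIDUES if allow_ambiguous else frozenset())
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        protein_id = rec.id
        seq = str(rec.seq).upper()
        if protein_id in seen:
            raise ValueError(f"duplicate protein id {protein_id!r} in {path}")
        if not seq:
            raise ValueError(f"empty sequence for protein {protein_id!r} in {path}")
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"illegal residue {ch!r} at position {pos} of protein "
                    f"{protein_id!r} in {path}"
                )
        seen.add(protein_id)
        records.append(ProteinRecord(protein_id, seq))
    return records


_MOD_STRIP_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)|[^A-Za-z]")


def clean_peptide(peptide: str, *, strip_mods: bool = False) -> str:
    """Validate (and optionally de-modify) a peptide string.

    With ``strip_mods`` the bracketed mass tags ``[...]``/``(...)`` and any
    non-alphabetic characters are removed and the result uppercased before
    validation; otherwise any character outside the 20 standard residues is
    an error.
    """
    if strip_mods:
        peptide = _MOD_STRIP_RE.sub("", peptide).upper()
    if not peptide:
        raise ValueError("empty peptide sequence")
    bad = set(peptide) - STANDARD_RESIDUES
    if bad:
        raise ValueError(
            f"peptide {peptide!r} contains non-standard residue(s) "
            f"{''.join(sorted(bad))!r}; pass strip_mods=True to remove "
            "modification annotations"
        )
    return peptide


def read_peptide_list(path: str | Path, *, strip_mods: bool = False) -> list[PeptideObservation]:
    """Read a 2-column ``peptide<TAB>count`` text file.

    A single header line is auto-detected (skipped when its second column is
    not an integer).  Counts must be non-negative integers; duplicate
    peptides are an input error.
    """
    observations: list[PeptideObservation] = []
    seen: set[str] = set()
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
            pep_str, count_str = parts[0].strip(), parts[1].strip()
            try:
                count = int(count_str)
            except ValueError:
                numeric = True
                try:
                    float(count_str)
                except ValueError:
                    numeric = False
                if lineno == 1 and not observations and not numeric:
                    continue  # header row: column 2 not numeric at all
                raise ValueError(
                    f"{path}:{lineno}: abundance {count_str!r} is not an integer"
                ) from None
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative abundance {count}")
            peptide = clean_peptide(pep_str.upper(), strip_mods=strip_mods)
            if peptide in seen:
                raise ValueError(f"{path}:{lineno}: duplicate peptide {peptide!r}")
            seen.add(peptide)
            observations.append(PeptideObservation(peptide, count))
    return observations


def peptide_matches_protein(
    peptide: str, protein: ProteinRecord | str, *, strict_tryptic: bool = False
) -> bool:
    """True iff *peptide* occurs in *protein* at a valid tryptic start.

    The occurrence must begin at protein position 1 or immediately after a
    literal K or R (the preceding residue is never I/L-folded, though K and R
    are unaffected by the fold anyway).  I and L are interchangeable in the
    compared subsequence.  Ambiguity codes (B/Z/X/U/O) in the protein never
    match any peptide residue.  With ``strict_tryptic`` the match must also
    end in K/R or at the protein C-terminus.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    folded_pep = peptide.translate(_IL_FOLD)
    if "\x00" in folded_pep:  # ambiguity codes in a peptide match nothing
        return False
    folded_seq = seq.translate(_IL_FOLD)
    start = 0
    n = len(peptide)
    while True:
        pos = folded_seq.find(folded_pep, start)
        if pos == -1:
            return False
        if pos == 0 or seq[pos - 1] in "KR":
            end = pos + n
            if not strict_tryptic or end == len(seq) or seq[end - 1] in "KR":
                return True
        start = pos + 1


def build_peptide_protein_map(
    peptides: Iterable[PeptideObservation],
    proteins: Iterable[ProteinRecord],
    *,
    strict_tryptic: bool = False,
) -> dict[str, frozenset[str]]:
    """Map every peptide to the set of protein ids that contain it.

    Every input peptide appears as a key; peptides matching no protein keep
    an empty set (their counts are routed to the per-aspect "unknown" nodes
    downstream) and are reported in a warning with their total spectral
    count.
    """
    proteins = list(proteins)
    mapping: dict[str, frozenset[str]] = {}
    unmatched: list[PeptideObservation] = []
    for obs in peptides:
        hits = frozenset(
            p.protein_id
            for p in proteins
            if peptide_matches_protein(obs.peptide, p, strict_tryptic=strict_tryptic)
        )
        mapping[obs.peptide] = hits
        if not hits:
            unmatched.append(obs)
    if unmatched:
        logger.warning(
            "PEP01 %d peptide(s) matched no protein (total spectral count %d): %s",
            len(unmatched),
            sum(o.abundance for o in unmatched),
            ", ".join(o.peptide for o in unmatched[:10])
            + ("..." if len(unmatched) > 10 else ""),
        )
    return mapping
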
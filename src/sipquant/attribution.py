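"""Attribution of labeled peptides to metagenome-assembled genomes (MAGs)
via in-silico tryptic digestion and unique-peptide indexing.

A peptide observed in the metaproteome can only be ascribed to a genome bin
when every protein that could have produced it belongs to that single bin;
peptides shared across bins are informative about presence but carry no
taxonomic signal and are never counted toward any bin. Proteins follow the
two-unique-peptide identification rule common in metaproteomics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ProteinBin",
    "PeptideIndex",
    "PeptideHit",
    "tryptic_digest",
    "build_index",
    "attribute_labeled",
    "identify_proteins",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinBin:
    """A genome bin's protein complement: bin id plus (protein id, sequence)
    records with unique ids."""

    bin_id: str
    proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, seq in self.proteins.items():
            if not seq:
                raise ValueError(f"protein {pid!r} in {self.bin_id} has empty sequence")

    def add(self, protein_id: str, sequence: str) -> None:
        if protein_id in self.proteins:
            raise ValueError(f"duplicate protein id {protein_id!r} in {self.bin_id}")
        if not sequence:
            raise ValueError("empty protein sequence")
        self.proteins[protein_id] = sequence


@dataclass
class PeptideIndex:
    """Mapping peptide sequence → set of (bin id, protein id) sources.

    A peptide is unique to a bin iff all of its source proteins lie in that
    one bin (bin-level uniqueness; protein-level uniqueness is available via
    ``unique_protein_of``).
    """

    sources: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def unique_bin_of(self, peptide: str) -> str | None:
        src = self.sources.get(peptide)
        if not src:
            return None
        bins = {b for b, _ in src}
        return next(iter(bins)) if len(bins) == 1 else None

    def unique_protein_of(self, peptide: str) -> tuple[str, str] | None:
        src = self.sources.get(peptide)
        if src and len(src) == 1:
            return next(iter(src))
        return None


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 2,
    length_bounds: tuple[int, int] | None = (6, 50),
) -> list[str]:
    """In-silico tryptic peptides of a protein.

    Trypsin cleaves C-terminal to K or R except when the next residue is P.
    All products with at most ``missed_cleavages`` internal cleavage sites
    are enumerated (default 2, the reference search setting) and filtered to
    ``length_bounds`` (pass None to disable filtering). Returns a sorted,
    de-duplicated list.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    bad = set(sequence) - _AA
    if bad:
        raise ValueError(f"non-canonical residue(s) {sorted(bad)} in sequence")
    # indices after which cleavage occurs
    cut_after = [
        i
        for i, ch in enumerate(sequence[:-1])
        if ch in "KR" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    peptides: set[str] = set()
    n_frag = len(boundaries) - 1
    for start in range(n_frag):
        for end in range(start + 1, min(start + missed_cleavages + 2, n_frag + 1)):
            pep = sequence[boundaries[start] : boundaries[end]]
            if length_bounds is None or length_bounds[0] <= len(pep) <= length_bounds[1]:
                peptides.add(pep)
    return sorted(peptides)


def build_index(
    bins: list[ProteinBin],
    missed_cleavages: int = 2,
    length_bounds: tuple[int, int] | None = (6, 50),
    il_equivalent: bool = False,
) -> PeptideIndex:
    """Digest every protein of every bin into a peptide → sources index.

    With ``il_equivalent`` leucine and isoleucine are collapsed to a common
    symbol before indexing (off by default: database searches report
    sequence-level matches). Duplicate bin ids are rejected.
    """
    if not bins:
        raise ValueError("no bins provided")
    ids = [b.bin_id for b in bins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate bin ids")
    index = PeptideIndex()
    for pbin in sorted(bins, key=lambda b: b.bin_id):
        for pid in sorted(pbin.proteins):
            seq = pbin.proteins[pid]
            for pep in tryptic_digest(seq, missed_cleavages, length_bounds):
                if il_equivalent:
                    pep = pep.replace("I", "L")
                index.sources.setdefault(pep, set()).add((pbin.bin_id, pid))
    return index


def attribute_labeled(
    index: PeptideIndex,
    records: list,
    il_equivalent: bool = False,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Count uniquely attributable labeled peptides per bin.

    ``records`` may be LabeledPeptideRecord objects or plain peptide
    strings. Returns (per-bin table with columns bin_id and
    unique_labeled_peptides, shared peptides, unassigned peptides). Shared
    peptides map to proteins in more than one bin and are never counted
    toward any bin; unassigned peptides map to no indexed protein.
    """
    per_bin: dict[str, set[str]] = defaultdict(set)
    shared: list[str] = []
    unassigned: list[str] = []
    all_bins = sorted({b for src in index.sources.values() for b, _ in src})
    for rec in records:
        pep = rec if isinstance(rec, str) else rec.sequence
        if il_equivalent:
            pep = pep.replace("I", "L")
        if pep not in index.sources:
            unassigned.append(pep)
            continue
        owner = index.unique_bin_of(pep)
        if owner is None:
            shared.append(pep)
        else:
            per_bin[owner].add(pep)
    table = pd.DataFrame(
        {
            "bin_id": all_bins,
            "unique_labeled_peptides": [len(per_bin[b]) for b in all_bins],
        }
    )
    return table, sorted(set(shared)), sorted(set(unassigned))


@dataclass(frozen=True)
class PeptideHit:
    """One observed peptide ascribed to a protein, with its uniqueness
    status from the index."""

    peptide: str
    protein_id: str
    bin_id: str
    unique: bool


def identify_proteins(hits: list[PeptideHit], min_unique: int = 2) -> pd.DataFrame:
    """Apply the ≥2-unique-peptide protein identification rule.

    Returns a per-protein table (bin_id, protein_id, n_unique_peptides,
    identified) sorted for determinism; a protein counts as identified when
    at least ``min_unique`` distinct unique peptides were observed.
    """
    uniques: dict[tuple[str, str], set[str]] = defaultdict(set)
    seen: set[tuple[str, str]] = set()
    for hit in hits:
        key = (hit.bin_id, hit.protein_id)
        seen.add(key)
        if hit.unique:
            uniques[key].add(hit.peptide)
    rows = []
    for bin_id, protein_id in sorted(seen):
        n = len(uniques[(bin_id, protein_id)])
        rows.append(
            {
                "bin_id": bin_id,
                "protein_id": protein_id,
                "n_unique_peptides": n,
                "identified": n >= min_unique,
            }
        )
    return pd.DataFrame(rows, columns=["bin_id", "protein_id", "n_unique_peptides", "identified"])
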
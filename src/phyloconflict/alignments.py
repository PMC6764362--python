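"""Alignment containers, FASTA I/O, concatenation, column cleaning,
and protein-guided codon alignment (back-translation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AlignmentError",
    "Alignment",
    "PartitionTable",
    "read_fasta",
    "write_fasta",
    "concatenate",
    "clean_columns",
    "codon_align_from_protein",
]

MISSING_CHARS = frozenset("-?Nn")
#: NCBI translation table for plastid / bacterial genes
PLASTID_CODE = 11


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """A multiple sequence alignment: label -> gap-padded row."""

    sequences: dict[str, str]
    molecule: str = "nucleotide"  # or "amino_acid"

    def __post_init__(self):
        if not self.sequences:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment length must be >= 1")
        if self.molecule not in ("nucleotide", "amino_acid"):
            raise AlignmentError(f"unknown molecule type {self.molecule!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    def subset(self, taxa: Iterable[str]) -> "Alignment":
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self.sequences]
        if missing:
            raise AlignmentError(f"taxa not in alignment: {missing}")
        return Alignment({t: self.sequences[t] for t in taxa}, self.molecule)

    def columns(self, idx: Sequence[int]) -> "Alignment":
        return Alignment(
            {t: "".join(s[i] for i in idx) for t, s in self.sequences.items()},
            self.molecule,
        )


@dataclass
class PartitionTable:
    """Ordered, contiguous, 1-based inclusive gene coordinates."""

    partitions: list[tuple[str, int, int]]

    def __post_init__(self):
        pos = 1
        names = set()
        for name, start, end in self.partitions:
            if name in names:
                raise AlignmentError(f"duplicate partition name {name!r}")
            names.add(name)
            if start != pos or end < start:
                raise AlignmentError(
                    f"partition {name!r} ({start}-{end}) not contiguous at {pos}"
                )
            pos = end + 1

    @property
    def total_length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def to_raxml(self, datatype: str = "DNA") -> str:
        return "\n".join(
            f"{datatype}, {name} = {start}-{end}" for name, start, end in self.partitions
        ) + "\n"


# ----------------------------------------------------------------------


def read_fasta(path, molecule: str = "nucleotide") -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"empty or non-FASTA file: {path}")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise AlignmentError(f"duplicate label {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return Alignment(seqs, molecule)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label, seq in aln.sequences.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ----------------------------------------------------------------------


def concatenate(genes: Sequence[tuple[str, Alignment]]) -> tuple[Alignment, PartitionTable]:
    """Build a supermatrix and its partition table.

    Taxa absent from a gene are filled with ``?`` across that gene's
    span, distinguishing gene absence from within-alignment indels.
    """
    if not genes:
        raise AlignmentError("no genes to concatenate")
    names = [n for n, _ in genes]
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate gene names")
    molecules = {a.molecule for _, a in genes}
    if len(molecules) != 1:
        raise AlignmentError(f"mixed molecule types: {sorted(molecules)}")
    taxa = sorted({t for _, a in genes for t in a.taxa})
    parts: list[tuple[str, int, int]] = []
    rows = {t: [] for t in taxa}
    pos = 1
    for name, aln in genes:
        L = aln.length
        parts.append((name, pos, pos + L - 1))
        pos += L
        for t in taxa:
            rows[t].append(aln.sequences.get(t, "?" * L))
    supermatrix = Alignment({t: "".join(rows[t]) for t in taxa}, molecules.pop())
    return supermatrix, PartitionTable(parts)


def slice_partition(aln: Alignment, table: PartitionTable, name: str) -> Alignment:
    """Extract one gene's columns from a supermatrix (all taxa retained)."""
    for pname, start, end in table.partitions:
        if pname == name:
            return Alignment(
                {t: s[start - 1 : end] for t, s in aln.sequences.items()}, aln.molecule
            )
    raise AlignmentError(f"no partition named {name!r}")


def occupancy(aln: Alignment) -> list[float]:
    """Per-column fraction of non-missing characters (N/?/- are missing)."""
    n = aln.n_taxa
    counts = [0] * aln.length
    for seq in aln.sequences.values():
        for i, c in enumerate(seq):
            if c not in MISSING_CHARS:
                counts[i] += 1
    return [c / n for c in counts]


def clean_columns(aln: Alignment, min_occupancy: float) -> Alignment:
    """Keep columns whose occupancy is at least ``min_occupancy``."""
    if not (0 < min_occupancy <= 1):
        raise AlignmentError("min_occupancy must be in (0, 1]")
    occ = occupancy(aln)
    keep = [i for i, f in enumerate(occ) if f >= min_occupancy]
    if not keep:
        raise AlignmentError("empty alignment after cleaning")
    return aln.columns(keep)


# ----------------------------------------------------------------------


def translate_nt(seq: str, table: int = PLASTID_CODE) -> str:
    """Translate an ungapped nucleotide sequence (no trailing stop kept)."""
    seq = seq.replace("-", "").replace("?", "")
    if len(seq) % 3:
        raise AlignmentError(f"nucleotide length {len(seq)} not divisible by 3")
    aa = str(Seq(seq).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def codon_align_from_protein(
    nt: Mapping[str, str],
    aa: Alignment,
    mode: str = "strict",
) -> tuple[Alignment, list[str]]:
    """Expand an amino-acid alignment into a codon alignment.

    Each residue column becomes three nucleotide columns; an amino-acid
    gap becomes ``---``.  Every shared taxon's translated nucleotide
    sequence must equal its ungapped amino-acid row; mismatches either
    raise (``mode='strict'``) or drop the taxon (``mode='drop'``).

    Returns the codon alignment and the list of dropped taxa.
    """
    if aa.molecule != "amino_acid":
        raise AlignmentError("guide alignment must be amino_acid")
    if mode not in ("strict", "drop"):
        raise AlignmentError(f"unknown mode {mode!r}")
    out: dict[str, str] = {}
    dropped: list[str] = []
    for taxon, aa_row in aa.sequences.items():
        if taxon not in nt:
            dropped.append(taxon)
            continue
        raw = nt[taxon].replace("-", "").replace("?", "")
        aa_ungapped = aa_row.replace("-", "").replace("?", "")
        ok = len(raw) % 3 == 0
        if ok:
            trans = translate_nt(raw)
            ok = trans.upper() == aa_ungapped.upper() and len(trans) * 3 in (
                len(raw),
                len(raw) - 3,  # trailing stop codon allowed
            )
        if not ok:
            if mode == "strict":
                raise AlignmentError(
                    f"nucleotide sequence of {taxon!r} does not translate to its "
                    "amino acid row"
                )
            dropped.append(taxon)
            continue
        codons = [raw[i : i + 3] for i in range(0, len(aa_ungapped) * 3, 3)]
        row = []
        k = 0
        for c in aa_row:
            if c in "-?":
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        out[taxon] = "".join(row)
    if not out:
        raise AlignmentError("no taxa left after codon alignment")
    return Alignment(out, "nucleotide"), dropped
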
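"""Alignment container and multiple-sequence-alignment IO.

The :class:`Alignment` is an immutable taxa x columns character matrix over a
declared state alphabet. Parsing and serialization of FASTA, relaxed PHYLIP
and NEXUS go through Biopython (Bio.SeqIO / Bio.AlignIO); this module layers
validation (equal lengths, unique labels, alphabet membership) and
normalization (upper-casing, U->T for nucleotide data) on top.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DNA, Alphabet, get_alphabet
from .errors import (
    AlignmentShapeError,
    AmbiguousMappingError,
    CharacterError,
    DuplicateTaxonError,
)
from .partitions import PartitionScheme

_FORMATS = ("fasta", "phylip", "nexus")
_BIO_FORMAT = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


class Alignment:
    """Immutable character matrix with unique, ordered taxon labels.

    Parameters
    ----------
    taxa : ordered taxon labels, unique.
    sequences : one string per taxon, all of identical length >= 1.
    alphabet : declared state alphabet (default nucleotide with IUPAC codes).
    provenance : optional (source path, format) tag.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        sequences: Sequence[str],
        alphabet: Alphabet = DNA,
        provenance: Optional[tuple[str, str]] = None,
    ):
        alphabet = get_alphabet(alphabet)
        taxa = [str(t) for t in taxa]
        if len(taxa) != len(sequences):
            raise AlignmentShapeError(
                f"{len(taxa)} labels but {len(sequences)} sequences"
            )
        if not taxa:
            raise AlignmentShapeError("alignment has no taxa")
        seen = set()
        for t in taxa:
            if t in seen:
                raise DuplicateTaxonError(f"duplicate taxon label {t!r}")
            seen.add(t)
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths {sorted(lengths)}"
            )
        length = lengths.pop()
        if length < 1:
            raise AlignmentShapeError("alignment has zero columns")

        allowed = alphabet.allowed
        norm = [
            "".join(alphabet.normalize(ch) for ch in str(seq)) for seq in sequences
        ]
        for t, seq in zip(taxa, norm):
            for j, ch in enumerate(seq):
                if ch not in allowed:
                    raise CharacterError(t, j + 1, ch)

        self._taxa: tuple[str, ...] = tuple(taxa)
        self._matrix = np.array([list(s) for s in norm], dtype="<U1")
        self._matrix.setflags(write=False)
        self._alphabet = alphabet
        self.provenance = provenance

    # -- basic accessors ---------------------------------------------------
    @property
    def taxa(self) -> tuple[str, ...]:
        return self._taxa

    @property
    def n_taxa(self) -> int:
        return len(self._taxa)

    @property
    def length(self) -> int:
        return self._matrix.shape[1]

    @property
    def alphabet(self) -> Alphabet:
        return self._alphabet

    @property
    def matrix(self) -> np.ndarray:
        """Read-only (n_taxa, length) array of single characters."""
        return self._matrix

    def index(self, taxon: str) -> int:
        try:
            return self._taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def sequence(self, taxon: str) -> str:
        return "".join(self._matrix[self.index(taxon)])

    def row(self, taxon: str) -> np.ndarray:
        return self._matrix[self.index(taxon)]

    def column(self, col: int) -> dict[str, str]:
        """Taxon -> state at a 1-based column."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside [1, {self.length}]")
        return {t: self._matrix[i, col - 1] for i, t in enumerate(self._taxa)}

    # -- derived alignments ------------------------------------------------
    def take_columns(self, columns0: Sequence[int]) -> "Alignment":
        """New alignment restricted to the given 0-based columns, in order."""
        cols = np.asarray(columns0, dtype=int)
        if cols.size == 0:
            raise AlignmentShapeError("cannot take zero columns")
        sub = self._matrix[:, cols]
        return Alignment(
            self._taxa, ["".join(r) for r in sub], self._alphabet, self.provenance
        )

    def subset_taxa(self, taxa: Sequence[str]) -> "Alignment":
        rows = [self.index(t) for t in taxa]
        return Alignment(
            [self._taxa[i] for i in rows],
            ["".join(self._matrix[i]) for i in rows],
            self._alphabet,
            self.provenance,
        )

    # -- dunder ------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self._taxa == other._taxa
            and self._alphabet.name == other._alphabet.name
            and np.array_equal(self._matrix, other._matrix)
        )

    def __repr__(self) -> str:
        return (
            f"Alignment(n_taxa={self.n_taxa}, length={self.length}, "
            f"alphabet={self._alphabet.name!r})"
        )

    # -- Biopython bridge --------------------------------------------------
    def to_biopython(self) -> MultipleSeqAlignment:
        mol = "protein" if self._alphabet.name == "protein" else "DNA"
        records = [
            SeqRecord(
                Seq(self.sequence(t)),
                id=t,
                name=t,
                description="",
                annotations={"molecule_type": mol},
            )
            for t in self._taxa
        ]
        msa = MultipleSeqAlignment(records)
        msa.annotations["molecule_type"] = mol
        return msa


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    by_suffix = {
        ".fasta": "fasta", ".fa": "fasta", ".fna": "fasta", ".faa": "fasta",
        ".phy": "phylip", ".phylip": "phylip",
        ".nex": "nexus", ".nexus": "nexus", ".nxs": "nexus",
    }
    if suffix in by_suffix:
        return by_suffix[suffix]
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                return "fasta"
            if line.upper().startswith("#NEXUS"):
                return "nexus"
            fields = line.split()
            if len(fields) == 2 and all(f.isdigit() for f in fields):
                return "phylip"
            break
    raise AlignmentShapeError(f"cannot auto-detect alignment format of {path}")


def read_alignment(path, format: str = "auto", alphabet: Alphabet | str = DNA) -> Alignment:
    """Read an alignment from FASTA, relaxed PHYLIP or NEXUS.

    Ragged input, duplicate labels and symbols outside the alphabet are
    rejected with specific errors.
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentShapeError(f"no FASTA records in {path}")
    else:
        try:
            records = list(AlignIO.read(str(path), _BIO_FORMAT[format]))
        except ValueError as exc:
            msg = str(exc)
            if "length" in msg.lower():
                raise AlignmentShapeError(f"{path}: {msg}") from exc
            raise
    taxa = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return Alignment(taxa, seqs, alphabet, provenance=(str(path), format))


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment; re-reading yields identical taxa, order and matrix."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    AlignIO.write(aln.to_biopython(), str(path), _BIO_FORMAT[format])


def subset_concatenate(
    alignments: Sequence[Alignment],
    taxon_map: Mapping[str, str],
    block_names: Optional[Sequence[str]] = None,
) -> tuple[Alignment, PartitionScheme]:
    """Concatenate gene alignments into an OTU supermatrix.

    Each source taxon present in ``taxon_map`` is renamed to its OTU
    (operational taxonomic unit) label; unmapped taxa are dropped. Genes
    absent for an OTU are filled with the missing symbol '?'. The returned
    :class:`PartitionScheme` records each source block's 1-based coordinates.
    """
    if not alignments:
        raise AlignmentShapeError("no alignments to concatenate")
    alphabet = alignments[0].alphabet
    for a in alignments:
        if a.alphabet.name != alphabet.name:
            raise AlignmentShapeError("mixed alphabets in concatenation")
    if block_names is None:
        block_names = [f"gene{i + 1}" for i in range(len(alignments))]
    if len(block_names) != len(alignments):
        raise ValueError("block_names must match alignments in number")

    otu_order: list[str] = []
    per_gene_rows: list[dict[str, str]] = []
    for a in alignments:
        rows: dict[str, str] = {}
        for t in a.taxa:
            if t not in taxon_map:
                continue
            otu = taxon_map[t]
            if otu in rows:
                raise AmbiguousMappingError(
                    f"two taxa of one alignment map to OTU {otu!r}"
                )
            rows[otu] = a.sequence(t)
            if otu not in otu_order:
                otu_order.append(otu)
        per_gene_rows.append(rows)
    if not otu_order:
        raise AlignmentShapeError("taxon_map retains no taxa")

    pieces: dict[str, list[str]] = {otu: [] for otu in otu_order}
    ranges: dict[str, list[tuple[int, int]]] = {}
    offset = 0
    for name, a, rows in zip(block_names, alignments, per_gene_rows):
        fill = alphabet.missing * a.length
        for otu in otu_order:
            pieces[otu].append(rows.get(otu, fill))
        ranges[name] = [(offset + 1, offset + a.length)]
        offset += a.length
    concat = Alignment(
        otu_order, ["".join(pieces[otu]) for otu in otu_order], alphabet
    )
    scheme = PartitionScheme.from_ranges(ranges)
    return concat, scheme
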
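"""Character recoding and column masking.

RY coding collapses nucleotides to purines (R = A/G) and pyrimidines
(C/T = Y), removing within-class compositional signal; masking restricts an
alignment to the complement of named blocks and/or codon positions, the way
saturated third positions and ambiguously aligned regions are excluded when
building analysis matrices.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .alignment import Alignment
from .alphabet import RY
from .errors import AlphabetError, EmptyAlignmentError
from .partitions import PartitionScheme

#: nucleotide -> RY image. Ambiguity codes resolving wholly within one class
#: map to that class; codes spanning both classes become '?' (kept in place so
#: alignment length and coordinate maps stay valid). Gaps are preserved.
_RY_MAP = {
    "A": "R", "G": "R", "R": "R",
    "C": "Y", "T": "Y", "Y": "Y",
    "S": "?", "W": "?", "K": "?", "M": "?",
    "B": "?", "D": "?", "H": "?", "V": "?", "N": "?",
    "-": "-", "?": "?",
}


def recode_ry(aln: Alignment) -> Alignment:
    """Recode a nucleotide alignment over {R, Y, ?, -}.

    Idempotent: applying it to an already RY-coded alignment returns an equal
    alignment.
    """
    if aln.alphabet.name == "ry":
        return Alignment(aln.taxa, ["".join(r) for r in aln.matrix], RY, aln.provenance)
    if aln.alphabet.name != "dna":
        raise AlphabetError(
            f"RY recoding requires a nucleotide alphabet, got {aln.alphabet.name!r}"
        )
    recoded = [
        "".join(_RY_MAP[ch] for ch in row) for row in aln.matrix
    ]
    return Alignment(aln.taxa, recoded, RY, aln.provenance)


def mask_columns(
    aln: Alignment,
    scheme: Optional[PartitionScheme] = None,
    drop_blocks: Sequence[str] = (),
    drop_codon_pos: Sequence[int] = (),
    drop_columns: Sequence[int] = (),
) -> tuple[Alignment, tuple[int, ...]]:
    """Drop named blocks, per-block codon positions, and/or explicit columns.

    Codon positions are interpreted relative to each frame-annotated block of
    ``scheme`` (genes are concatenated at arbitrary offsets, so global
    coordinates would be meaningless). Returns the restricted alignment and a
    map from new to original 1-based coordinates.
    """
    if scheme is not None:
        scheme.validate(aln.length)
    drop: set[int] = set()
    for c in drop_columns:
        c = int(c)
        if not 1 <= c <= aln.length:
            raise IndexError(f"drop column {c} outside [1, {aln.length}]")
        drop.add(c)
    if drop_blocks:
        if scheme is None:
            raise ValueError("drop_blocks requires a PartitionScheme")
        for name in drop_blocks:
            drop.update(scheme.columns(name))
    if drop_codon_pos:
        if scheme is None:
            raise ValueError("drop_codon_pos requires a PartitionScheme")
        for pos in drop_codon_pos:
            for name in scheme.frames:
                drop.update(scheme.codon_position_columns(name, pos))
    keep = [c for c in range(1, aln.length + 1) if c not in drop]
    if not keep:
        raise EmptyAlignmentError("mask would remove every column")
    masked = aln.take_columns(np.asarray(keep, dtype=int) - 1)
    return masked, tuple(keep)
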
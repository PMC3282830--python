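"""Compositional-heterogeneity statistics.

Implements the relative composition frequency variability (RCFV) and its
taxon-specific decomposition, the legacy count-based RCV, per-state and
binned-class deviations, the four nucleotide skews (A-T, G-C, A-G, C-T) and a
codon-usage tabulator.

Notation: mu_Xi is the frequency of state X in taxon i over that taxon's
*counted* sites (unambiguous, non-gap, non-missing); mu~_X is the unweighted
mean of the per-taxon frequencies across the n taxa. Then

    RCFV = sum_i sum_X |mu_Xi - mu~_X| / n

and the i-th summand (divided by n) is the taxon-specific RCFV contribution.
The unweighted mean is deliberate: it differs from a pooled-count frequency
whenever sequence coverage varies between taxa, e.g. after OTU concatenation
with large missing blocks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .errors import AllMissingError, AlphabetError, ConfigurationError
from .partitions import PartitionScheme

#: binned-class schemes: class name -> symbols counted as an observation of
#: that class. IUPAC codes resolving wholly within one class count for it
#: (W = A/T is an AT observation; R = A/G is a purine observation).
CLASS_SCHEMES = {
    "AT_GC": {"AT": ("A", "T", "W"), "GC": ("G", "C", "S")},
    "R_Y": {"R": ("A", "G", "R"), "Y": ("C", "T", "Y")},
}

SKEW_PAIRS = (("A", "T"), ("G", "C"), ("A", "G"), ("C", "T"))


@dataclass
class CompositionProfile:
    """Per-taxon frequencies, deviations and RCFV decomposition."""

    frequencies: pd.DataFrame        # taxa x states, each row sums to 1
    mean_frequencies: pd.Series      # unweighted mean over taxa
    deviations: pd.DataFrame         # |mu_Xi - mu~_X|
    taxon_rcfv: pd.Series            # per-taxon contribution (row sum / n)
    total_rcfv: float                # sum of contributions, same order
    counted_sites: pd.Series         # counted sites per taxon

    def to_frame(self) -> pd.DataFrame:
        """One row per taxon plus a TOTAL row, as written by the CLI."""
        out = self.frequencies.add_prefix("freq_")
        out = out.join(self.deviations.add_prefix("dev_"))
        out["taxon_rcfv"] = self.taxon_rcfv
        out["counted_sites"] = self.counted_sites
        total = pd.Series({"taxon_rcfv": self.total_rcfv}, name="TOTAL")
        return pd.concat([out, total.to_frame().T])


def _resolve_columns(aln: Alignment, columns: Optional[Sequence[int]]) -> np.ndarray:
    """1-based user columns -> validated 0-based index array."""
    if columns is None:
        return np.arange(aln.length)
    cols = np.asarray(sorted(set(int(c) for c in columns)), dtype=int)
    if cols.size == 0:
        raise ValueError("empty column selection")
    if cols[0] < 1 or cols[-1] > aln.length:
        raise IndexError(
            f"column selection outside [1, {aln.length}]: "
            f"{cols[0]}..{cols[-1]}"
        )
    return cols - 1


def _count_matrix(aln: Alignment, columns0: np.ndarray) -> pd.DataFrame:
    """Counts of each counted state per taxon over the selected columns."""
    sub = aln.matrix[:, columns0]
    data = {s: (sub == s).sum(axis=1) for s in aln.alphabet.states}
    return pd.DataFrame(data, index=list(aln.taxa))


def state_frequencies(
    aln: Alignment, taxon: str, columns: Optional[Sequence[int]] = None
) -> pd.Series:
    """Frequencies of the counted states for one taxon.

    Gaps, '?' and ambiguity codes are excluded from both numerator and
    denominator: they are non-observations, not states.
    """
    cols0 = _resolve_columns(aln, columns)
    row = aln.row(taxon)[cols0]
    counts = pd.Series(
        {s: int((row == s).sum()) for s in aln.alphabet.states}, dtype=float
    )
    total = counts.sum()
    if total == 0:
        raise AllMissingError(
            f"taxon {taxon!r} has no counted sites in the selected columns"
        )
    return counts / total


def _frequency_table(aln: Alignment, columns0: np.ndarray) -> tuple[pd.DataFrame, pd.Series]:
    counts = _count_matrix(aln, columns0)
    totals = counts.sum(axis=1)
    empty = totals[totals == 0]
    if not empty.empty:
        raise AllMissingError(
            f"taxa with no counted sites in the selected columns: "
            f"{list(empty.index)} (drop them explicitly before computing)"
        )
    return counts.div(totals, axis=0), totals


def rcfv(aln: Alignment, columns: Optional[Sequence[int]] = None) -> CompositionProfile:
    """Relative composition frequency variability, total and per taxon.

    Works verbatim for any alphabet (nucleotide or amino acid); only the
    state set changes.
    """
    if aln.n_taxa < 2:
        raise ValueError("RCFV requires at least 2 taxa")
    cols0 = _resolve_columns(aln, columns)
    freqs, totals = _frequency_table(aln, cols0)
    mean = freqs.mean(axis=0)  # unweighted mean over taxa
    devs = (freqs - mean).abs()
    n = aln.n_taxa
    taxon_rcfv = devs.sum(axis=1) / n
    total = float(sum(taxon_rcfv))  # same summation order as the contributions
    return CompositionProfile(freqs, mean, devs, taxon_rcfv, total, totals)


def rcv(aln: Alignment, columns: Optional[Sequence[int]] = None) -> float:
    """Legacy relative composition variability from absolute counts.

    Same summation as RCFV but over per-taxon state *counts* c_Xi, normalized
    by n * Lbar where Lbar is the mean number of counted sites per taxon.
    Because it uses absolute counts, the value confounds compositional and
    sequence-length variability; it is provided for comparison only. On
    gap-free equal-length alignments rcv == rcfv exactly.
    """
    if aln.n_taxa < 2:
        raise ValueError("RCV requires at least 2 taxa")
    cols0 = _resolve_columns(aln, columns)
    counts = _count_matrix(aln, cols0).astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise AllMissingError(
            f"taxa with no counted sites: {list(totals[totals == 0].index)}"
        )
    mean_counts = counts.mean(axis=0)
    lbar = totals.mean()
    n = aln.n_taxa
    return float((counts - mean_counts).abs().to_numpy().sum() / (n * lbar))


def class_deviations(
    aln: Alignment,
    scheme: str = "AT_GC",
    columns: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Binned two-class frequencies and absolute deviations per taxon.

    scheme 'AT_GC' bins A+T vs G+C; 'R_Y' bins purines vs pyrimidines.
    Because only two classes remain, the two deviations are equal per taxon
    and a single value is reported.
    """
    if aln.alphabet.name not in ("dna", "ry"):
        raise AlphabetError("class deviations are defined for nucleotide data")
    if scheme not in CLASS_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(CLASS_SCHEMES)}")
    if aln.alphabet.name == "ry" and scheme != "R_Y":
        raise AlphabetError("an RY-recoded alignment only supports the R_Y scheme")
    cols0 = _resolve_columns(aln, columns)
    sub = aln.matrix[:, cols0]
    names = list(CLASS_SCHEMES[scheme])
    counts = pd.DataFrame(
        {
            name: np.isin(sub, list(symbols)).sum(axis=1)
            for name, symbols in CLASS_SCHEMES[scheme].items()
        },
        index=list(aln.taxa),
        dtype=float,
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise AllMissingError(
            f"taxa with no class observations: {list(totals[totals == 0].index)}"
        )
    freqs = counts.div(totals, axis=0)
    mean = freqs.mean(axis=0)
    devs = (freqs - mean).abs()
    out = freqs.add_prefix("freq_")
    # two-state closure: |dev| identical for both classes, report one value
    out["deviation"] = devs[names[0]]
    return out


def skews(
    aln: Alignment,
    taxon: Optional[str] = None,
    columns: Optional[Sequence[int]] = None,
) -> pd.DataFrame | pd.Series:
    """A-T, G-C, A-G and C-T skews: (mu_X - mu_Y) / (mu_X + mu_Y).

    A zero denominator yields NaN, the explicit "undefined" marker — never an
    exception and never a silent 0, since 0 is a meaningful (balanced) value.
    Returns a Series for one taxon or a DataFrame for all taxa.
    """
    if aln.alphabet.name != "dna":
        raise AlphabetError("skews are defined for nucleotide alphabets only")
    cols0 = _resolve_columns(aln, columns)
    target = aln.subset_taxa([taxon]) if taxon is not None else aln
    freqs, _ = _frequency_table(target, cols0)
    rows = {}
    for t in freqs.index:
        mu = freqs.loc[t]
        vals = {}
        for x, y in SKEW_PAIRS:
            denom = mu[x] + mu[y]
            vals[f"{x}-{y}"] = (mu[x] - mu[y]) / denom if denom > 0 else np.nan
        rows[t] = vals
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table.loc[taxon] if taxon else table


def codon_usage(aln: Alignment, scheme: PartitionScheme) -> pd.DataFrame:
    """Codon counts per taxon over the union of frame-annotated blocks.

    For each block, codons are read in consecutive triplets starting at the
    block's first codon-position-1 column; a trailing partial codon is
    dropped with a warning. Codons containing gaps, '?' or ambiguity codes
    are skipped. Returns a taxa x 64 count table.
    """
    if aln.alphabet.name != "dna":
        raise AlphabetError("codon usage is defined for nucleotide alphabets")
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    table = pd.DataFrame(
        0, index=list(aln.taxa), columns=codons, dtype=int
    )
    for name in scheme.blocks:
        frame = scheme.frame(name)
        if frame is None:
            raise ConfigurationError(
                f"block {name!r} lacks a codon-frame annotation"
            )
        scheme.validate(aln.length)
        cols = scheme.columns(name)
        offset = (1 - frame) % 3  # columns before the first complete codon
        usable = cols[offset:]
        trailing = len(usable) % 3
        if trailing:
            warnings.warn(
                f"block {name!r}: dropping trailing partial codon of "
                f"{trailing} column(s)",
                stacklevel=2,
            )
            usable = usable[: len(usable) - trailing]
        idx = np.asarray(usable, dtype=int) - 1
        sub = aln.matrix[:, idx]
        for i, taxon in enumerate(aln.taxa):
            row = sub[i]
            for k in range(0, len(row), 3):
                codon = row[k] + row[k + 1] + row[k + 2]
                if codon in table.columns:
                    table.loc[taxon, codon] += 1
    return table
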
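"""Split-support spectra.

Per-column support for directed bipartitions of the taxon set, graded into
three quality categories:

* ``binary`` — both sides monomorphic, with different states;
* ``noisy_outgroup`` — the ingroup monomorphic, the outgroup polymorphic but
  with an identifiable strict-majority state different from the ingroup's;
* ``noisy_both`` — both sides polymorphic with distinct strict-majority
  states.

"Ingroup" and "outgroup" here denote the two sides of one split (the
spectral-analysis sense, not rooting): each side is evaluated as an ingroup
separately, so a binary column supports both directions of its split.

Candidate ingroups are generated by a documented, testable rule. Without a
group mapping, a candidate must be *state-class-complete*: every state
occurring in the ingroup occurs nowhere in the outgroup, so candidates are
unions of whole state classes (monomorphic unions for the first two
categories, strict-majority polymorphic unions for the third). With a group
mapping active, category-3 candidates are instead unions of whole taxon
groups, which bounds the combinatorial space and matches how named clades
are read off a spectrum. Strict majority means > 50% of counted states on
that side; ties yield no majority and hence no support.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .errors import ConfigurationError
from .partitions import TaxonGroups

CATEGORIES = ("binary", "noisy_outgroup", "noisy_both")


@dataclass(frozen=True)
class DirectedSplit:
    """A bipartition with one side singled out as the ingroup under study."""

    ingroup: frozenset[str]
    outgroup: frozenset[str]

    def __post_init__(self):
        if self.ingroup & self.outgroup:
            raise ValueError("ingroup and outgroup overlap")

    @property
    def key(self) -> tuple[str, ...]:
        """Canonical identity of the directed split: sorted ingroup labels."""
        return tuple(sorted(self.ingroup))


@dataclass
class SplitSupport:
    """Aggregated support for one directed split across columns."""

    split: DirectedSplit
    counts: dict[str, int]
    columns: tuple[int, ...]  # supporting columns, 1-based original coords
    label: Optional[str] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _strict_majority(counter: Counter) -> Optional[str]:
    """The state holding > 50% of observations, or None on a tie/minority."""
    total = sum(counter.values())
    state, count = counter.most_common(1)[0]
    return state if 2 * count > total else None


def _classify(
    in_states: Counter, out_states: Counter, exclusive: bool
) -> Optional[str]:
    """Category of a directed (ingroup, outgroup) state profile, or None."""
    if len(in_states) == 1:
        (s,) = in_states
        if len(out_states) == 1:
            (t,) = out_states
            return "binary" if t != s else None
        t = _strict_majority(out_states)
        if t is None or t == s:
            return None
        if exclusive and s in out_states:
            return None
        return "noisy_outgroup"
    s = _strict_majority(in_states)
    if s is None or len(out_states) < 2:
        return None
    t = _strict_majority(out_states)
    if t is None or t == s:
        return None
    if exclusive and s in out_states:
        return None
    return "noisy_both"


def column_support(
    column: Mapping[str, str],
    min_side: int = 2,
    groups: Optional[TaxonGroups] = None,
    exclusive: bool = False,
    counted_states: Sequence[str] = ("A", "C", "G", "T"),
) -> list[tuple[DirectedSplit, str]]:
    """Supported directed splits at one column.

    ``column`` maps taxon -> state; taxa whose symbol is not a counted state
    (gap, '?', ambiguity) are removed before evaluation. Fewer than
    2 * min_side counted taxa yield an empty result, not an error.
    """
    counted_set = set(counted_states)
    counted = {t: s for t, s in column.items() if s in counted_set}
    if len(counted) < 2 * min_side:
        return []
    by_state: dict[str, frozenset[str]] = {}
    for t, s in counted.items():
        by_state.setdefault(s, frozenset())
        by_state[s] = by_state[s] | {t}
    all_counted = frozenset(counted)

    results: dict[frozenset[str], tuple[DirectedSplit, str]] = {}

    def consider(ingroup: frozenset[str]) -> None:
        outgroup = all_counted - ingroup
        if len(ingroup) < min_side or len(outgroup) < min_side:
            return
        cat = _classify(
            Counter(counted[t] for t in ingroup),
            Counter(counted[t] for t in outgroup),
            exclusive,
        )
        if cat is not None:
            results[ingroup] = (DirectedSplit(ingroup, outgroup), cat)

    # categories 1-2: each state class as a monomorphic candidate ingroup
    for members in by_state.values():
        consider(members)

    # category 3: polymorphic candidates
    if groups is not None and groups.groups:
        names = sorted(groups.groups)
        for k in range(1, len(names)):
            for combo in combinations(names, k):
                ingroup = frozenset().union(
                    *(groups.groups[g] & all_counted for g in combo)
                )
                if ingroup and len(set(counted[t] for t in ingroup)) > 1:
                    consider(ingroup)
    else:
        states = sorted(by_state)
        for s in states:
            others = [u for u in states if u != s]
            for k in range(1, len(others) + 1):
                for combo in combinations(others, k):
                    ingroup = by_state[s].union(*(by_state[u] for u in combo))
                    # s must be the strict-majority state of the candidate
                    if 2 * len(by_state[s]) > len(ingroup):
                        consider(ingroup)
    return list(results.values())


def spectrum(
    aln: Alignment,
    min_side: int = 2,
    groups: Optional[TaxonGroups] = None,
    exclusive: bool = False,
) -> list[SplitSupport]:
    """Aggregate column support over all columns, keyed by directed split.

    Sorted by total support descending, ties broken by the canonical split
    key. Identical columns are evaluated once and their results multiplied
    out, which keeps long simulated alignments fast.
    """
    taxa = aln.taxa
    counted_states = aln.alphabet.states
    patterns, inverse = np.unique(aln.matrix.T, axis=0, return_inverse=True)
    inverse = np.asarray(inverse).ravel()
    agg: dict[tuple[str, ...], dict] = {}
    for u, pattern in enumerate(patterns):
        column = dict(zip(taxa, pattern))
        supports = column_support(
            column, min_side=min_side, groups=groups,
            exclusive=exclusive, counted_states=counted_states,
        )
        if not supports:
            continue
        cols = (np.nonzero(inverse == u)[0] + 1).tolist()
        for split, cat in supports:
            entry = agg.setdefault(
                split.key,
                {
                    "ingroup": split.ingroup,
                    "counts": {c: 0 for c in CATEGORIES},
                    "columns": [],
                },
            )
            entry["counts"][cat] += len(cols)
            entry["columns"].extend(cols)
    full = frozenset(taxa)
    out = [
        SplitSupport(
            DirectedSplit(e["ingroup"], full - e["ingroup"]),
            e["counts"],
            tuple(sorted(e["columns"])),
        )
        for e in agg.values()
    ]
    out.sort(key=lambda s: (-s.total, s.split.key))
    return out


def filter_focal(
    spec: Sequence[SplitSupport], groups: TaxonGroups
) -> list[SplitSupport]:
    """Retain splits relevant to the focal taxon set and label them.

    A split is retained when its ingroup is a subset of the focal set with
    2 <= |ingroup| <= |focal| - 1. When a group mapping is supplied, the
    ingroup must additionally be a union of complete groups — it counts for
    e.g. "Al+Am+Tr" only if it contains every member of each named group and
    no non-members — and is labelled with the sorted group names.
    """
    focal = groups.focal
    if len(focal) < 3:
        raise ConfigurationError("focal set must contain at least 3 taxa")
    out: list[SplitSupport] = []
    for s in spec:
        ing = s.split.ingroup
        if not (ing <= focal and 2 <= len(ing) <= len(focal) - 1):
            continue
        if groups.groups:
            touched = sorted(
                g for g, members in groups.groups.items() if members & ing
            )
            union = frozenset().union(*(groups.groups[g] for g in touched)) if touched else frozenset()
            if union != ing:
                continue
            out.append(replace(s, label="+".join(touched)))
        else:
            out.append(replace(s, label=None))
    return out


def label_hypotheses(
    spec: Sequence[SplitSupport], groups: TaxonGroups
) -> pd.DataFrame:
    """Per-hypothesis support-category counts (the bar-chart decomposition).

    Each hypothesis resolves to the taxon set of its member groups; the row
    reports the category counts of the split whose ingroup equals that set
    exactly (zeros when the spectrum contains no such split).
    """
    by_key = {s.split.key: s for s in spec}
    rows = {}
    for name in groups.hypotheses:
        taxa = groups.hypothesis_taxa(name)
        s = by_key.get(tuple(sorted(taxa)))
        counts = s.counts if s is not None else {c: 0 for c in CATEGORIES}
        rows[name] = {c: counts.get(c, 0) for c in CATEGORIES}
        rows[name]["total"] = sum(rows[name].values())
    return pd.DataFrame.from_dict(rows, orient="index").astype(int)


def spectrum_frame(spec: Sequence[SplitSupport]) -> pd.DataFrame:
    """Tabular view of a spectrum (one row per directed split)."""
    rows = []
    for s in spec:
        row = {"split": ",".join(s.split.key)}
        row.update({c: s.counts.get(c, 0) for c in CATEGORIES})
        row["total"] = s.total
        row["label"] = s.label if s.label is not None else ""
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["split", *CATEGORIES, "total", "label"]
    )
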
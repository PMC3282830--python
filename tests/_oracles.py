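"""Independent brute-force oracles used by the test suite.

Each function restates a definition naively (literal formulas, per-character
tallies, exhaustive subset enumeration) without sharing code with the
package implementation it checks.
"""
from __future__ import annotations

from collections import Counter
from itertools import combinations


def literal_rcfv(seqs: dict[str, str], states: tuple[str, ...]):
    """Literal transcription of the RCFV formula via per-character loops.

    Returns (total, per-taxon contribution dict, per-taxon frequency dict).
    """
    taxa = list(seqs)
    n = len(taxa)
    mu: dict[str, dict[str, float]] = {}
    for t in taxa:
        counts = {s: 0 for s in states}
        total = 0
        for ch in seqs[t]:
            if ch in counts:
                counts[ch] += 1
                total += 1
        mu[t] = {s: counts[s] / total for s in states}
    mu_bar = {s: sum(mu[t][s] for t in taxa) / n for s in states}
    contrib = {
        t: sum(abs(mu[t][s] - mu_bar[s]) for s in states) / n for t in taxa
    }
    return sum(contrib[t] for t in taxa), contrib, mu


def tally_frequencies(seq: str, states: tuple[str, ...]) -> dict[str, float]:
    counts = Counter(ch for ch in seq if ch in states)
    total = sum(counts.values())
    return {s: counts[s] / total for s in states}


def _strict_majority(counter: Counter):
    total = sum(counter.values())
    state, count = counter.most_common(1)[0]
    return state if 2 * count > total else None


def classify_subset(ingroup, outgroup, column, groups=None, exclusive=False):
    """Category of one candidate directed bipartition, or None.

    Restates the documented support rule: monomorphic ingroups must be
    complete state classes; polymorphic ingroups must be state-class-complete
    (no mapping) or unions of whole taxon groups (mapping active), with
    strict-majority states differing between the sides.
    """
    in_states = Counter(column[t] for t in ingroup)
    out_states = Counter(column[t] for t in outgroup)
    if len(in_states) == 1:
        (s,) = in_states
        if s in out_states:  # not the full state class
            return None
        if len(out_states) == 1:
            return "binary"
        t = _strict_majority(out_states)
        return "noisy_outgroup" if t is not None and t != s else None
    # polymorphic ingroup
    if groups is not None and groups.groups:
        counted = set(ingroup) | set(outgroup)
        touched = [g for g, mem in groups.groups.items() if mem & set(ingroup)]
        union = set()
        for g in touched:
            union |= groups.groups[g] & counted
        if union != set(ingroup):
            return None
    else:
        if any(s in out_states for s in in_states):
            return None
    s = _strict_majority(in_states)
    if s is None or len(out_states) < 2:
        return None
    t = _strict_majority(out_states)
    if t is None or t == s:
        return None
    if exclusive and s in out_states:
        return None
    return "noisy_both"


def brute_spectrum(aln, min_side=2, groups=None, exclusive=False):
    """Exhaustive split spectrum: every subset of counted taxa, every column.

    Returns {sorted-ingroup-tuple: {"counts": {...}, "columns": [...]}}.
    """
    states_ok = set(aln.alphabet.states)
    agg: dict[tuple, dict] = {}
    for col in range(1, aln.length + 1):
        column = aln.column(col)
        counted = {t for t, s in column.items() if s in states_ok}
        names = sorted(counted)
        if len(names) < 2 * min_side:
            continue
        for r in range(min_side, len(names) - min_side + 1):
            for combo in combinations(names, r):
                ingroup = set(combo)
                outgroup = counted - ingroup
                cat = classify_subset(ingroup, outgroup, column, groups, exclusive)
                if cat is None:
                    continue
                key = tuple(sorted(ingroup))
                entry = agg.setdefault(
                    key,
                    {"counts": {"binary": 0, "noisy_outgroup": 0, "noisy_both": 0},
                     "columns": []},
                )
                entry["counts"][cat] += 1
                entry["columns"].append(col)
    return agg


def codon_counts_sliding(seq: str, frame: int) -> Counter:
    """Sliding-window-by-3 codon tally over one in-frame sequence."""
    offset = (1 - frame) % 3
    usable = seq[offset:]
    usable = usable[: len(usable) - (len(usable) % 3)]
    out: Counter = Counter()
    for k in range(0, len(usable), 3):
        codon = usable[k : k + 3]
        if all(c in "ACGT" for c in codon):
            out[codon] += 1
    return out


def hky_transition_matrix(pi, kappa, t):
    """Closed-form HKY85 transition probabilities (A,C,G,T order), with the
    rate matrix scaled to one expected substitution per unit time at pi."""
    import numpy as np

    pi = np.asarray(pi, dtype=float)
    a, c, g, tt = pi
    pi_r, pi_y = a + g, c + tt
    beta = 1.0 / (
        2 * (a * c + a * tt + c * g + g * tt) + 2 * kappa * (a * g + c * tt)
    )
    cls = {0: pi_r, 1: pi_y, 2: pi_r, 3: pi_y}
    transition_partner = {0: 2, 2: 0, 1: 3, 3: 1}
    P = np.zeros((4, 4))
    e1 = np.exp(-beta * t)
    for i in range(4):
        for j in range(4):
            pj, Pj = pi[j], cls[j]
            e2 = np.exp(-t * beta * (1 + Pj * (kappa - 1)))
            if i == j:
                P[i, j] = pj + pj * (1 / Pj - 1) * e1 + ((Pj - pj) / Pj) * e2
            elif transition_partner[i] == j:
                P[i, j] = pj + pj * (1 / Pj - 1) * e1 - (pj / Pj) * e2
            else:
                P[i, j] = pj * (1 - e1)
    return P
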
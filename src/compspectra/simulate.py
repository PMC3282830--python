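"""Forward simulation of non-stationary sequence evolution.

Each branch of a tree carries its own substitution model — an HKY-style (or
GTR) exchangeability structure together with a branch-specific equilibrium
composition vector pi_b — so base composition can drift along chosen
lineages. This is the minimal generative realization of "different
compositional vectors along branches": the root sequence is drawn i.i.d.
from a root composition, and each branch applies the transition probabilities
exp(Q_b * l_b) of its scaled rate matrix, sites independent.

Rate matrices are scaled so the expected rate is 1 at the branch's own
stationary vector; branch lengths therefore keep their expected
substitutions-per-site meaning during composition shifts (an approximation,
since the process on a branch generally starts away from that branch's
equilibrium).

A preset "symplesiomorphy trap" scenario builds a 5-clade ingroup topology
(P,(T,(Tr,(Am,Al)))) and applies opposite pyrimidine shifts of magnitude
delta to the Am and Al stems and subtrees, providing ground truth for the
compositional diagnostics and split spectra.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .alignment import Alignment
from .alphabet import DNA
from .errors import ConfigurationError
from .partitions import TaxonGroups

_NUC = np.array(["A", "C", "G", "T"])
_NUC_INDEX = {s: i for i, s in enumerate(_NUC)}
#: transition pairs under the A,C,G,T ordering
_TRANSITIONS = ((0, 2), (1, 3))


def _validate_pi(pi) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,):
        raise ConfigurationError("composition vector must have 4 entries (A,C,G,T)")
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ConfigurationError(
            f"composition vector must be non-negative and sum to 1, got {pi}"
        )
    return pi / pi.sum()


@dataclass
class BranchModel:
    """Substitution model attached to one branch.

    Parameters
    ----------
    pi : target composition vector over (A, C, G, T); the stationary
        distribution of the branch's rate matrix.
    kappa : transition/transversion rate ratio (HKY); ignored when ``rates``
        is given.
    rates : optional 6 symmetric GTR exchangeabilities in the order
        AC, AG, AT, CG, CT, GT.
    """

    pi: Sequence[float]
    kappa: float = 2.0
    rates: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.pi = _validate_pi(self.pi)
        if self.kappa < 0:
            raise ConfigurationError("kappa must be non-negative")
        if self.rates is not None:
            self.rates = np.asarray(self.rates, dtype=float)
            if self.rates.shape != (6,) or (self.rates < 0).any():
                raise ConfigurationError("rates must be 6 non-negative values")

    def exchangeabilities(self) -> np.ndarray:
        """Symmetric 4x4 exchangeability matrix (zero diagonal)."""
        r = np.zeros((4, 4))
        if self.rates is not None:
            pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
            for (i, j), v in zip(pairs, self.rates):
                r[i, j] = r[j, i] = v
        else:
            r[:] = 1.0
            np.fill_diagonal(r, 0.0)
            for i, j in _TRANSITIONS:
                r[i, j] = r[j, i] = self.kappa
        return r

    def rate_matrix(self) -> np.ndarray:
        """Rate matrix q_ij = r_ij * pi_j, rows summing to 0, scaled so the
        expected rate is 1 at the model's own stationary vector pi."""
        r = self.exchangeabilities()
        q = r * self.pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -float(np.dot(self.pi, np.diag(q)))
        if mean_rate <= 0:
            raise ConfigurationError("degenerate rate matrix (zero mean rate)")
        return q / mean_rate

    def transition_matrix(self, length: float) -> np.ndarray:
        """P(l) = exp(Q l) for a branch of the given expected length."""
        if length < 0:
            raise ConfigurationError("branch length must be >= 0")
        if length == 0:
            return np.eye(4)
        return expm(self.rate_matrix() * length)


def _branch_stream(seed: int, key: str) -> np.random.Generator:
    """Deterministic per-branch RNG stream.

    Keyed by the branch's descendant tip labels, so adding a taxon elsewhere
    in the tree does not reshuffle the draws of existing branches.
    """
    digest = zlib.crc32(key.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def _clade_key(node) -> str:
    tips = sorted(
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
    )
    return ",".join(tips)


def _lookup_model(models: Mapping[str, BranchModel], node) -> BranchModel:
    if node.is_leaf() and node.taxon is not None:
        label = node.taxon.label
    else:
        label = node.label
    if label is not None and label in models:
        return models[label]
    if "default" in models:
        return models["default"]
    raise ConfigurationError(
        f"no branch model for node {label!r} and no 'default' model given"
    )


def simulate(
    tree: "dendropy.Tree | str",
    models: Mapping[str, BranchModel],
    n_sites: int,
    seed: int,
    root_pi: Sequence[float],
) -> Alignment:
    """Simulate an alignment down a tree under branch-specific models.

    ``tree`` is a dendropy Tree or a Newick string with branch lengths;
    ``models`` maps node labels (tip labels or internal-node labels) to
    :class:`BranchModel`, with an optional ``"default"`` fallback. The root
    sequence is drawn i.i.d. from ``root_pi``. Identical inputs give
    byte-identical alignments.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    leaves = [l for l in tree.leaf_node_iter() if l.taxon is not None]
    if not leaves:
        raise ConfigurationError("tree has no labelled leaves")
    root_pi = _validate_pi(root_pi)

    root = tree.seed_node
    rng_root = _branch_stream(seed, "__root__")
    states: dict[int, np.ndarray] = {
        id(root): rng_root.choice(4, size=n_sites, p=root_pi)
    }
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_states = states[id(node.parent_node)]
        model = _lookup_model(models, node)
        length = node.edge.length
        if length is None:
            raise ConfigurationError(
                f"branch above {node.taxon.label if node.taxon else node.label!r} "
                "has no length"
            )
        p = model.transition_matrix(float(length))
        rng = _branch_stream(seed, _clade_key(node))
        child = np.empty(n_sites, dtype=np.int64)
        cum = np.cumsum(p, axis=1)
        cum[:, -1] = 1.0  # guard against float round-off at the top bin
        for i in range(4):
            mask = parent_states == i
            k = int(mask.sum())
            if k:
                u = rng.random(k)
                child[mask] = np.searchsorted(cum[i], u, side="right")
        states[id(node)] = child

    taxa = [l.taxon.label for l in leaves]
    seqs = ["".join(_NUC[states[id(l)]]) for l in leaves]
    return Alignment(taxa, seqs, DNA)


# ---------------------------------------------------------------------------
# trap scenario preset
# ---------------------------------------------------------------------------

#: clade labels of the preset topology (P,(T,(Tr,(Am,Al)))): an outgroup
#: analogue P and the four-clade ingroup with Am and Al as sisters.
CLADES = ("P", "T", "Tr", "Am", "Al")


@dataclass
class ScenarioConfig:
    """Parameters of the symplesiomorphy-trap scenario.

    delta is the magnitude of the pyrimidine shift: the Am stem and subtree
    move +delta toward thymine and -delta away from cytosine, the Al lineage
    the opposite way. All other branches evolve at the baseline composition
    pi0. Branch lengths are expected substitutions per site; the biased
    lineages are given longer branches so their compositions actually drift,
    eroding ancestral signal the way the trap requires, while the unbiased
    lineages stay conservative.
    """

    n_sites: int = 50_000
    seed: int = 0
    delta: float = 0.15
    pi0: tuple[float, float, float, float] = (0.30, 0.24, 0.16, 0.30)
    kappa: float = 3.0
    tips_per_clade: int = 2
    backbone_length: float = 0.02
    tip_length: float = 0.02
    biased_length: float = 0.2

    def __post_init__(self):
        pi0 = _validate_pi(self.pi0)
        c, t = pi0[1], pi0[3]
        if not (0 < c - self.delta and 0 < t - self.delta
                and c + self.delta < 1 and t + self.delta < 1):
            raise ConfigurationError(
                f"delta={self.delta} pushes shifted frequencies out of (0, 1)"
            )
        if self.tips_per_clade < 2:
            raise ConfigurationError("each clade needs at least 2 tips")


@dataclass
class TrapScenario:
    """Everything a trap run produces: inputs, ground truth and data."""

    tree: str  # newick with labelled internal nodes
    models: dict[str, BranchModel]
    groups: TaxonGroups
    alignment: Alignment
    truth: dict = field(default_factory=dict)


def _shifted(pi0: np.ndarray, delta: float, toward_t: bool) -> np.ndarray:
    shift = np.array([0.0, -delta, 0.0, +delta])
    return _validate_pi(pi0 + (shift if toward_t else -shift))


def trap_scenario(config: ScenarioConfig) -> TrapScenario:
    """Build and simulate the preset trap scenario.

    Returns the tree, branch models, taxon groups (focal set = all tips;
    hypotheses TriAA = {Tr, Am, Al}, TriTer = {Tr, T}, TerAA = {T, Am, Al})
    and the simulated alignment. With delta = 0 the scenario degenerates to a
    stationary simulation.
    """
    pi0 = _validate_pi(config.pi0)
    pi_am = _shifted(pi0, config.delta, toward_t=True)
    pi_al = _shifted(pi0, config.delta, toward_t=False)

    k = config.tips_per_clade
    tips = {c: [f"{c}{i}" for i in range(1, k + 1)] for c in CLADES}

    def clade_newick(c: str, tip_len: float, stem_len: float) -> str:
        inner = ",".join(f"{t}:{tip_len}" for t in tips[c])
        return f"({inner}){c}:{stem_len}"

    bb, tl, bl = config.backbone_length, config.tip_length, config.biased_length
    newick = (
        "("
        + clade_newick("P", tl, bb)
        + ",("
        + clade_newick("T", tl, bb)
        + ",("
        + clade_newick("Tr", tl, bb)
        + ",("
        + clade_newick("Am", bl, bl)
        + ","
        + clade_newick("Al", bl, bl)
        + f")AmAl:{bb}"
        + f")TrAmAl:{bb}"
        + f")TTrAmAl:{bb}"
        + ");"
    )

    models: dict[str, BranchModel] = {
        "default": BranchModel(pi0, kappa=config.kappa)
    }
    for label in ("Am", *tips["Am"]):
        models[label] = BranchModel(pi_am, kappa=config.kappa)
    for label in ("Al", *tips["Al"]):
        models[label] = BranchModel(pi_al, kappa=config.kappa)

    aln = simulate(newick, models, config.n_sites, config.seed, root_pi=pi0)

    groups = TaxonGroups(
        groups={c: frozenset(tips[c]) for c in CLADES},
        focal=frozenset(t for c in CLADES for t in tips[c]),
        hypotheses={
            "TriAA": ("Tr", "Am", "Al"),
            "TriTer": ("Tr", "T"),
            "TerAA": ("T", "Am", "Al"),
        },
    )
    truth = {
        "newick": newick,
        "pi0": pi0.tolist(),
        "pi_Am": pi_am.tolist(),
        "pi_Al": pi_al.tolist(),
        "delta": config.delta,
        "kappa": config.kappa,
        "n_sites": config.n_sites,
        "seed": config.seed,
        "true_clade_hypothesis": "TriAA",
        "branch_lengths": {
            "backbone": bb, "tip": tl, "biased": bl,
        },
    }
    return TrapScenario(newick, models, groups, aln, truth)
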
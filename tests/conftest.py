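import numpy as np
import pytest

from compspectra import DNA, Alignment


def make_random_alignment(
    rng: np.random.Generator,
    n_taxa: int,
    length: int,
    gap_frac: float = 0.0,
    missing_frac: float = 0.0,
    ambig_frac: float = 0.0,
) -> Alignment:
    """Random nucleotide alignment, optionally salted with gaps/?/IUPAC codes."""
    symbols = list("ACGT")
    weights = [(1 - gap_frac - missing_frac - ambig_frac) / 4] * 4
    if gap_frac or missing_frac or ambig_frac:
        symbols += ["-", "?", "R", "Y", "N"]
        weights += [gap_frac, missing_frac, ambig_frac / 3, ambig_frac / 3, ambig_frac / 3]
    weights = np.asarray(weights) / np.sum(weights)
    mat = rng.choice(symbols, size=(n_taxa, length), p=weights)
    taxa = [f"t{i}" for i in range(n_taxa)]
    return Alignment(taxa, ["".join(row) for row in mat], DNA)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def random_alignment(rng) -> Alignment:
    return make_random_alignment(rng, 6, 40, gap_frac=0.05, missing_frac=0.05, ambig_frac=0.06)
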
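import numpy as np
import pytest

import mrmquant as mq

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(sequence: str, enzyme: str) -> list[str]:
    """Independent site-scanner oracle: walk the chain, cut where the rule fires."""
    frags, start = [], 0
    for i in range(1, len(sequence)):
        prev, nxt = sequence[i - 1], sequence[i]
        tryptic = prev in "KR" and nxt != "P"
        lysc = prev == "K"
        cut = {"trypsin": tryptic, "lysc": lysc, "lysc_then_trypsin": tryptic or lysc}[enzyme]
        if cut:
            frags.append(sequence[start:i])
            start = i
    frags.append(sequence[start:])
    return frags


def random_kr_peptides(n: int, rng: np.random.Generator, length=(7, 15)) -> list[mq.Peptide]:
    """Peptides with no internal cleavage site and a K/R C-terminus."""
    interior = np.array(list(set(RESIDUES) - {"K", "R"}))
    out = []
    seen = set()
    while len(out) < n:
        L = int(rng.integers(length[0], length[1] + 1))
        seq = "".join(rng.choice(interior, size=L - 1)) + rng.choice(["K", "R"])
        if seq[0] == "P" or seq in seen:  # keep junctions trivially cleavable
            continue
        seen.add(seq)
        out.append(mq.Peptide(seq))
    return out


@pytest.fixture(scope="session")
def toy_proteome() -> dict[str, str]:
    return mq.synthetic_proteome(30, seed=1)


@pytest.fixture(scope="session")
def toy_selection(toy_proteome):
    return mq.select_proteotypic(toy_proteome, list(toy_proteome))


@pytest.fixture(scope="session")
def small_assay(toy_selection):
    """Scheduled transitions for ten peptides plus the matching ground truth."""
    rng = np.random.default_rng(0)
    transitions = []
    for pep in toy_selection.peptides[:10]:
        transitions += mq.build_transitions(pep, predicted_rt=float(rng.uniform(5, 55)))
    return transitions
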
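import numpy as np
import pytest

from duphic import build_layout, simulate_contacts
from duphic.motifs import BASES, CTCF_PFM_TEXT, MotifModel


@pytest.fixture(scope="session")
def default_layout():
    return build_layout()


@pytest.fixture(scope="session")
def small_sim(default_layout):
    """A modest default-layout read set shared across tests."""
    reads, truth = simulate_contacts(default_layout, n_reads=20_000, seed=11)
    return reads, truth


@pytest.fixture(scope="session")
def ctcf_model():
    rows = [line.split("\t") for line in CTCF_PFM_TEXT.strip().splitlines()]
    lab = {r[0]: [float(x) for x in r[1:]] for r in rows}
    counts = np.array([lab[b] for b in BASES]).T
    return MotifModel.from_counts(counts, threshold=8.0)


def naive_one_sweep_posteriors(reads, uni_dense, prior, w, pseudocount):
    """Independent direct evaluation of the single-sweep posterior
    formula with explicit loops (oracle for the vectorised path)."""
    n = uni_dense.shape[0]
    out = {}
    for r in reads:
        if not r.is_multi:
            out[r.read_id] = [1.0]
            continue
        weights = []
        for (i, j) in r.candidates:
            local = 0.0
            for a in range(max(0, i - w), min(n, i + w + 1)):
                for b in range(max(0, j - w), min(n, j + w + 1)):
                    local += uni_dense[a, b]
            weights.append(prior.evaluate(j - i) * (local + pseudocount))
        total = sum(weights)
        if total <= 0:
            weights = [prior.evaluate(j - i) for (i, j) in r.candidates]
            total = sum(weights)
        out[r.read_id] = [x / total for x in weights]
    return out
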
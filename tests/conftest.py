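import numpy as np
import pandas as pd
import pytest

from tregpipe.deg import CountMatrix
from tregpipe.repertoire import CloneRecord, Repertoire, _with_frequencies


def make_repertoire(counts, sample_id="S1", tissue="NI", subset="Treg", keys=None):
    """Build a small repertoire from a count list (keys auto-generated)."""
    if keys is None:
        keys = [("TRBV1", "TRBJ1-1", f"CDR{i:03d}") for i in range(len(counts))]
    clones = _with_frequencies(
        [CloneRecord(v, j, c, count=n) for (v, j, c), n in zip(keys, counts)]
    )
    return Repertoire(sample_id=sample_id, patient_id="P1", tissue=tissue, subset=subset, clones=clones)


def random_repertoire(rng, max_clones=50, sample_id="R", subset="Treg", key_pool=None):
    """A random small repertoire for brute-force oracle comparisons."""
    n = int(rng.integers(1, max_clones + 1))
    if key_pool is None:
        keys = [(f"TRBV{rng.integers(1, 6)}", f"TRBJ1-{rng.integers(1, 4)}", f"C{i}_{rng.integers(0, 1000)}") for i in range(n)]
    else:
        idx = rng.choice(len(key_pool), size=min(n, len(key_pool)), replace=False)
        keys = [key_pool[i] for i in idx]
    keys = list(dict.fromkeys(keys))
    counts = [int(c) for c in rng.integers(1, 100, size=len(keys))]
    return make_repertoire(counts, sample_id=sample_id, subset=subset, keys=keys)


@pytest.fixture
def toy_counts():
    """4 Treg + 4 Tconv samples, 4 hand-set genes, one tissue."""
    samples = [f"NI_Treg_{i}" for i in range(1, 5)] + [f"NI_Tconv_{i}" for i in range(1, 5)]
    counts = pd.DataFrame(
        np.array(
            [
                [100, 100, 100, 100, 25, 25, 25, 25],   # up in Treg
                [30, 30, 30, 30, 30, 30, 30, 30],       # flat
                [5, 5, 5, 5, 5, 5, 5, 5],               # below flag threshold
                [0, 0, 0, 0, 0, 0, 0, 0],               # all zero
            ]
        ),
        index=["G_UP", "G_FLAT", "G_LOW", "G_ZERO"],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "patient": [f"P{i}" for i in range(1, 5)] * 2,
            "tissue": "NI",
            "subset": ["Treg"] * 4 + ["Tconv"] * 4,
        },
        index=samples,
    )
    return CountMatrix(counts=counts, metadata=meta)
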
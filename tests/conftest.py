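import numpy as np
import pytest

from paddymix.panel import AccessionRecord, GenotypePanel, SNPMarker


def build_panel(calls, chroms=None, positions=None, acc_ids=None, marker_ids=None):
    """Small-panel factory for hand-constructed fixtures."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    if chroms is None:
        chroms = [1] * L
    if positions is None:
        positions = []
        counter = {}
        for c in chroms:
            counter[c] = counter.get(c, 0) + 1
            positions.append(counter[c] * 100)
    if acc_ids is None:
        acc_ids = [f"acc{i + 1}" for i in range(n)]
    if marker_ids is None:
        marker_ids = [f"snp{j + 1}" for j in range(L)]
    markers = [
        SNPMarker(id=m, chrom=int(c), pos_bp=int(p))
        for m, c, p in zip(marker_ids, chroms, positions)
    ]
    return GenotypePanel(
        markers=markers,
        accessions=[AccessionRecord(id=a) for a in acc_ids],
        calls=calls,
    )


@pytest.fixture
def panel_factory():
    return build_panel


def random_panel(rng, n=None, L=None, missing_rate=0.1, n_chrom=2):
    """Random valid panel for round-trip and property tests."""
    n = n or int(rng.integers(2, 8))
    L = L or int(rng.integers(2, 12))
    calls = rng.integers(0, 2, size=(n, L)).astype(np.int8)
    mask = rng.random((n, L)) < missing_rate
    calls[mask] = -1
    chroms = np.sort(rng.integers(1, n_chrom + 1, size=L))
    pos = np.zeros(L, dtype=int)
    for c in np.unique(chroms):
        k = int((chroms == c).sum())
        pos[chroms == c] = np.sort(
            rng.choice(np.arange(1, 10_000), size=k, replace=False)
        )
    return build_panel(calls, chroms=chroms.tolist(), positions=pos.tolist())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
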
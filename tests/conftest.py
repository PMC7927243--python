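import itertools

import numpy as np
import pytest

from sortnoise.sortseq_core import BinManifest


def deterministic_barcodes(n: int) -> tuple[str, ...]:
    """First n distinct 9-mers in lexicographic order (test plumbing)."""
    bases = "ACGT"
    out = []
    for combo in itertools.product(bases, repeat=5):
        out.append("ACGT" + "".join(combo))
        if len(out) == n:
            return tuple(out)
    raise ValueError("too many barcodes requested")


def make_manifest(
    n_bins: int = 20,
    lo: float = 1.0,
    hi: float = 1e5,
    cells_sorted=None,
    spacing: str = "log",
) -> BinManifest:
    if spacing == "log":
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    if cells_sorted is None:
        cells_sorted = np.full(n_bins, 1000.0)
    return BinManifest(
        lower=edges[:-1],
        upper=edges[1:],
        barcodes=deterministic_barcodes(n_bins),
        cells_sorted=np.asarray(cells_sorted, dtype=float),
        spacing=spacing,
    )


@pytest.fixture
def manifest20() -> BinManifest:
    return make_manifest(20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
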
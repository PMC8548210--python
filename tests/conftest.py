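import numpy as np
import pytest

from hervlink.core import GenomeLayout, GenomicInterval


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 10_000, "chr2": 8_000})


def random_intervals(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    max_len: int = 500,
    prefix: str = "iv",
) -> list[GenomicInterval]:
    """Uniform random intervals on a layout, for randomized oracle tests."""
    chroms = list(layout.chromosomes)
    out = []
    for k in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = int(rng.integers(1, max_len + 1))
        clen = layout.chromosomes[chrom]
        L = min(L, clen)
        start = int(rng.integers(0, clen - L + 1))
        out.append(GenomicInterval(chrom, start, start + L, id=f"{prefix}_{k}"))
    return out
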
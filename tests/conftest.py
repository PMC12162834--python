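import numpy as np
import pytest

from stiffprime.genomeio import GenomicInterval
from stiffprime.synthdata import SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced synthetic bundle shared across tests (1 Mb, 300 regions)."""
    cfg = SimConfig(
        seed=7, n_chroms=1, chrom_length=1_000_000, n_genes=120, n_regions=300
    )
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate(cfg, outdir)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=300):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                str(rng.choice(list(chroms))), start, start + length, f"iv{i}"
            )
        )
    return out


def mask_union(intervals, chroms, size):
    """Per-base boolean-mask oracle for interval union."""
    masks = {c: np.zeros(size, dtype=bool) for c in chroms}
    for iv in intervals:
        masks[iv.chrom][iv.start : min(iv.end, size)] = True
    return masks
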
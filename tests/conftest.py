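import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bidiprom.pair_catalog import TranscriptModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_tx(tx_id, strand, tss, length=2000, chrom="chr1", gene=None):
    """Transcript with a given TSS; span derived from strand and length."""
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length + 1, tss + 1
    return TranscriptModel(tx_id, gene or tx_id, chrom, strand, start, end)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_transcripts(rng, n, chroms=("chr1", "chr2"), span=50_000, n_genes=None):
    """Random transcript set with clustered TSSs so pairs actually occur."""
    out = []
    n_genes = n_genes or max(1, n // 2)
    for i in range(n):
        gene = f"g{rng.integers(n_genes)}"
        out.append(
            make_tx(
                f"t{i}",
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(3000, span)),
                length=int(rng.integers(500, 3000)),
                chrom=str(rng.choice(list(chroms))),
                gene=gene,
            )
        )
    return out
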
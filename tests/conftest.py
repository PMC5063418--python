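import numpy as np
import pytest

from smnsplice.genomic_model import GenomicInterval


@pytest.fixture
def toy_genome():
    """8-base palindrome-friendly chromosome plus a longer random one."""
    rng = np.random.default_rng(42)
    chr2 = "".join(rng.choice(list("ACGT"), size=5000))
    return {"chr1": "ACGTACGT", "chr2": chr2}


@pytest.fixture
def interval():
    return GenomicInterval("chr1", 0, 4, "+")


def make_gtf(path, lines):
    path.write_text("".join(line + "\n" for line in lines))
    return str(path)
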
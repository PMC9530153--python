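import numpy as np
import pytest

from scramblekit.refmodel import (LOXPSYM_SITE, build_reference,
                                  random_reference)


@pytest.fixture(scope="session")
def small_ref():
    """12-segment linear chromosome (~20 kb), the workhorse fixture."""
    return random_reference(n_segments=12, mean_segment_len=1600, seed=2)


@pytest.fixture(scope="session")
def ring_ref():
    """10-segment circular chromosome."""
    return random_reference(n_segments=10, mean_segment_len=1500,
                            topology="circular", seed=4)


@pytest.fixture(scope="session")
def uniform_ref():
    """4 equal 1000-bp segments (exact retention arithmetic)."""
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    segs = ["".join(rng.choice(bases, 1000)) for _ in range(4)]
    site = LOXPSYM_SITE
    seq = site.join(segs)
    site_iv = []
    pos = 0
    for s in segs[:-1]:
        pos += len(s)
        site_iv.append((pos, pos + len(site)))
        pos += len(site)
    cen = (1500, 1620)      # inside segment 2
    return build_reference("uniform4", seq, site_iv, [], cen, "linear")
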
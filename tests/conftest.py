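import numpy as np
import pytest

import maremap as m
from maremap import landscape as lsc


@pytest.fixture(scope="session")
def element_998():
    return m.gen_element(998, seed=11, element_id="el998")


@pytest.fixture(scope="session")
def library_998(element_998):
    return m.design_fragments(element_998)


@pytest.fixture(scope="session")
def two_site_run():
    """Default synthetic benchmark: 998-bp element, two planted sites."""
    return m.default_two_site_run(seed=5)


def run_landscape(intensities, library, replicate, seed=17,
                  min_enrichment=2.0):
    """Full single-replicate landscape pipeline: bin, interpolate,
    classify, call peaks."""
    land = lsc.bin_signals(intensities, library, library.element_id,
                           "TF", replicate)
    lsc.interpolate_landscape(land)
    cls = lsc.classify_positions(land, seed=seed)
    peaks = lsc.call_peaks(land, cls, min_enrichment=min_enrichment)
    return land, cls, peaks


def kmeans_oracle(values):
    """Exhaustive 1-D 2-means: try every threshold split of the sorted data
    and return the (lower, upper) centers of the minimum-SSE partition."""
    v = np.sort(np.asarray(values, float))
    best = None
    for k in range(1, len(v)):
        lo, hi = v[:k], v[k:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0]:
            best = (sse, lo.mean(), hi.mean())
    return best[1], best[2]
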
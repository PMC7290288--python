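import numpy as np
import pandas as pd
import pytest

import meipop as m


@pytest.fixture(scope="session")
def structured_cohort():
    """Default seven-group structured cohort, shared across tests."""
    cfg = m.SimConfig(seed=11)
    calls, panel, anc, truth = m.simulate_cohort(cfg)
    return {"cfg": cfg, "calls": calls, "panel": panel, "anc": anc, "truth": truth}


@pytest.fixture
def tiny_panel():
    frame = pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "population": ["p1", "p1", "p2", "p2"],
            "group": ["Africa", "Africa", "East Asia", "East Asia"],
            "lat": [0.0, 1.0, 35.0, 36.0],
            "lon": [20.0, 21.0, 110.0, 111.0],
        }
    )
    return m.SamplePanel(frame)


def make_callset(genotypes, samples=None, me_class="ALU", chrom="1", start=1000):
    """Build a small call set from a dosage matrix (-1 = missing)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_loci, n_samples = genotypes.shape
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    loci = [
        m.MEILocus(chrom=chrom, pos=start + 100 * i, me_class=me_class, assess=5)
        for i in range(n_loci)
    ]
    return m.MEICallSet(loci=loci, samples=list(samples), genotypes=genotypes)


@pytest.fixture
def make_calls():
    return make_callset
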
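import numpy as np
import pandas as pd
import pytest

import musadmix as mx
from musadmix.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A fast single-chromosome cohort with the default panel design."""
    spec = mx.DemographicSpec(
        seed=7,
        n_chromosomes=1,
        chrom_length=2_000_000,
        panel_sizes={"KAZ": 5, "SPR": 7, "KOR": 9, "IND": 2, "FOCAL": 6},
    )
    return mx.simulate_cohort(spec)


def make_geno(freq_rows, panel_sizes, seed=0, positions=None, chrom="chr1"):
    """Build a GenotypeMatrix whose per-panel frequencies are exact.

    ``freq_rows`` is a list of dicts {panel: frequency}; each panel's
    dosages at a site are chosen deterministically so that the panel
    frequency equals the requested value exactly (2*n*freq must be an
    integer).
    """
    panels = []
    samples = []
    for p, n in panel_sizes.items():
        for i in range(n):
            samples.append(f"{p}_{i}")
            panels.append(p)
    dosage = np.zeros((len(freq_rows), len(samples)), dtype=np.int8)
    for si, row in enumerate(freq_rows):
        col = 0
        for p, n in panel_sizes.items():
            f = row[p]
            alt = f * 2 * n
            assert abs(alt - round(alt)) < 1e-9, (p, f, n)
            alt = int(round(alt))
            geno_row = []
            # fill with 2s then a possible 1 then 0s
            n2, rem = divmod(alt, 2)
            geno_row = [2] * n2 + ([1] if rem else []) + [0] * (n - n2 - rem)
            dosage[si, col : col + n] = geno_row
            col += n
    pos = positions if positions is not None else np.arange(1, len(freq_rows) + 1)
    return GenotypeMatrix(
        chrom=np.full(len(freq_rows), chrom, dtype=object),
        pos=np.asarray(pos),
        dosage=dosage,
        samples=samples,
        panels=pd.Series(panels, index=samples),
    )
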
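import numpy as np
import pytest

from refugia import simulate as sim
from refugia.datatypes import AlignedSequenceSet, BinaryMarkerMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_alignment():
    """Four sequences, two variant columns, padded to length 100."""
    pad = "A" * 98
    seqs = [pad + "AA", pad + "AA", pad + "AA", pad + "TT"]
    ids = [f"s{i}" for i in range(1, 5)]
    return AlignedSequenceSet(
        sample_ids=ids, sequences=seqs,
        population_of={i: "p1" for i in ids},
    )


@pytest.fixture
def env8(rng):
    return sim.simulate_env(sim.EnvSimConfig(), rng)


@pytest.fixture
def markers_small(env8, rng):
    markers, _ = sim.simulate_aflp(
        sim.AflpSimConfig(n_loci=120, background_fst=0.15), env8, rng)
    return markers


def plant_high_fst_locus(markers: BinaryMarkerMatrix, rng, fst=0.6,
                         p_bar=0.5, locus_index=0) -> BinaryMarkerMatrix:
    """Replace one locus with a Balding–Nichols locus at elevated FST."""
    pops = markers.populations
    m = {p: len(ix) for p, ix in markers.population_indices().items()}
    f = sim.balding_nichols_freqs(np.array(p_bar), fst, (len(pops),), rng)
    band_prob = 1.0 - (1.0 - f) ** 2
    col = np.concatenate([
        (rng.random(m[p]) < band_prob[j]).astype(float)
        for j, p in enumerate(pops)
    ])
    calls = markers.calls.copy()
    calls[:, locus_index] = col
    return BinaryMarkerMatrix(markers.individual_ids, markers.locus_ids,
                              calls, markers.population_of)
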
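import numpy as np
import pytest

from tumap.pipeline import RunConfig, run
from tumap.synthetic import SimConfig, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A compact seeded chromosome with planted truth, shared across tests."""
    cfg = SimConfig(
        genome_length=80_000,
        n_tus_per_class={"high": 6, "medium": 6, "low": 6},
        n_convergent_pairs=2,
        n_srna=1,
        seed=3,
    )
    genome, truth = generate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def desk_run():
    """One full desk-profile pipeline run at default noise (seed 1)."""
    return run(RunConfig(outdir=None, seed=1, profile="desk", write_outputs=False))


def match_truth_tu(truth_tu, tus, min_frac=0.5):
    """The assembled TU covering most of a truth TU on the same strand."""
    lo, hi = truth_tu.span
    best = None
    for tu in tus:
        if tu.strand != truth_tu.strand:
            continue
        lo2, hi2 = tu.span
        ov = min(hi, hi2) - max(lo, lo2) + 1
        if ov > min_frac * (hi - lo + 1) and (best is None or ov > best[0]):
            best = (ov, tu)
    return None if best is None else best[1]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
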
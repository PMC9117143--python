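import numpy as np
import pytest

from btmbkit.io import VariantCall
from btmbkit.panel import default_panel
from btmbkit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (records + variants), fixed seed."""
    return simulate_cohort(SimulationConfig(), seed=11)


def make_variant(sample_id="S1", gene="TP53", position=7577120, ref="C",
                 alt="T", variant_class="SNV", allele_frequency=0.05,
                 in_population_db=False, is_known_driver=False,
                 germline_flag="unknown"):
    return VariantCall(sample_id, gene, position, ref, alt, variant_class,
                       allele_frequency, in_population_db, is_known_driver,
                       germline_flag)


def random_variant_list(rng: np.random.Generator, sample_id="S1",
                        n_max=40) -> list:
    """Randomized variant fixture spanning the scoring rules' edge cases."""
    n = int(rng.integers(0, n_max))
    calls = []
    for j in range(n):
        vclass = rng.choice(["SNV", "SNV", "SNV", "insertion", "deletion"])
        af = float(rng.choice([
            rng.uniform(0, 0.005), rng.uniform(0.005, 0.2),
            rng.uniform(0.2, 0.46), rng.uniform(0.45, 0.55),
            rng.uniform(0.95, 1.0)]))
        ref = "A" if vclass != "deletion" else "AT"
        alt = ("G" if vclass == "SNV" else
               "ATT" if vclass == "insertion" else "A")
        calls.append(VariantCall(
            sample_id=sample_id, gene="TP53", position=1000 + j,
            ref=ref, alt=alt, variant_class=vclass, allele_frequency=af,
            in_population_db=bool(rng.uniform() < 0.2),
            is_known_driver=bool(rng.uniform() < 0.15)))
    return calls
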
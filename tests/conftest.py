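import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from chipcomp.models import GeneModel, GenomeModel  # noqa: E402


@pytest.fixture
def linear_genome() -> GenomeModel:
    """Small linear genome with a divergent gene pair and a lone + gene."""
    return GenomeModel(
        name="chrT",
        length=20_000,
        circular=False,
        genes=[
            GeneModel("plus_lone", 10_000, 11_000, "+"),     # tss 10000
            GeneModel("div_minus", 8_500, 9_801, "-"),       # tss 9800
            GeneModel("early_plus", 200, 900, "+"),          # tss 200, clipped window
        ],
    )


@pytest.fixture
def random_genome_factory():
    """Random non-overlapping gene layouts for oracle comparisons."""

    def build(rng: np.random.Generator, length: int = 50_000,
              n_genes: int = 60, circular: bool = False) -> GenomeModel:
        lengths = rng.integers(100, 400, size=n_genes)
        spare = length - int(lengths.sum())
        offsets = np.sort(rng.choice(spare, size=n_genes, replace=False))
        starts = offsets + np.concatenate(([0], np.cumsum(lengths)[:-1]))
        strands = rng.choice(np.array(["+", "-"]), size=n_genes)
        genes = [
            GeneModel(f"g{i}", int(starts[i]), int(starts[i] + lengths[i]),
                      str(strands[i]))
            for i in range(n_genes)
        ]
        return GenomeModel(name="chrR", length=length, circular=circular,
                           genes=genes)

    return build
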
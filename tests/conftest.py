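import numpy as np
import pytest

from mtmarker.genome_io import AnnotationSet, CircularGenome, Feature
from mtmarker.synthetic_data import SimConfig, generate_reference, generate_strains


@pytest.fixture(scope="session")
def default_truth():
    """One full-size simulated panel, shared across tests (seed 7)."""
    cfg = SimConfig(seed=7)
    reference, ann = generate_reference(cfg)
    return generate_strains(reference, ann, cfg)


@pytest.fixture
def toy_genome():
    return CircularGenome(id="toy", sequence="ACGTACGTAC")


@pytest.fixture
def toy_annotation():
    feats = [
        Feature("geneA", "PCG", 1, 40, "+", "g"),
        Feature("geneB", "PCG", 61, 100, "+", "g"),
    ]
    return AnnotationSet(genome_id="g", features=feats)


def random_annotation(rng: np.random.Generator, genome_len: int, n_features: int) -> AnnotationSet:
    """Arbitrary (possibly overlapping, possibly wrapping) features."""
    feats = []
    for i in range(n_features):
        start = int(rng.integers(1, genome_len + 1))
        span = int(rng.integers(1, genome_len))
        end = (start - 1 + span - 1) % genome_len + 1
        strand = "+" if rng.random() < 0.5 else "-"
        cat = ["PCG", "tRNA", "rRNA", "orf"][int(rng.integers(0, 4))]
        feats.append(Feature(f"f{i}", cat, start, end, strand, "g"))
    return AnnotationSet(genome_id="g", features=feats)
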
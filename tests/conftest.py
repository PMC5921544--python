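import numpy as np
import pytest

from paintphylo.characters import Character, CharacterMatrix
from paintphylo.homology import HomologyMap, SignalBlock


def random_binary_matrix(
    rng: np.random.Generator, n_taxa: int, n_chars: int, missing: float = 0.0
) -> CharacterMatrix:
    states = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.int8)
    if missing:
        states[rng.random((n_taxa, n_chars)) < missing] = -1
    return CharacterMatrix(
        [f"t{i}" for i in range(n_taxa)],
        [Character(f"c{j}", "association") for j in range(n_chars)],
        states,
    )


def toy_map(probe: str, target: str, chrom_signals: dict[str, list[str]]) -> HomologyMap:
    """Build a map from {target_chromosome: [probe labels]} ('.' = unpainted)."""
    hmap = HomologyMap(probe_species=probe, target_species=target)
    for chrom, labels in chrom_signals.items():
        hmap.signals[chrom] = [
            SignalBlock(
                probe_chromosome="" if lab == "." else lab,
                position_index=i,
                painted=lab != ".",
            )
            for i, lab in enumerate(labels)
        ]
    hmap.validate()
    return hmap


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
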
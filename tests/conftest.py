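import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from genedecay.simulate import (
    FIXTURE_SEED,
    fixture_configs,
    simulate,
    whale_tree_and_manifest,
)


@pytest.fixture(scope="session")
def whale_tree_manifest():
    return whale_tree_and_manifest(genes=["G1"])


@pytest.fixture(scope="session")
def stem_loss_sim():
    """The canned stem-loss simulation: (alignment, truth, config)."""
    cfg = fixture_configs()["stem_loss"]
    aln, truth = simulate(cfg)
    return aln, truth, cfg


@pytest.fixture(scope="session")
def micro_sim():
    """3-taxon, 3-codon simulation small enough for exhaustive oracles."""
    cfg = fixture_configs()["micro"]
    aln, truth = simulate(cfg)
    return aln, truth, cfg


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The canned on-disk fixture suite written by the simulator."""
    out = tmp_path_factory.mktemp("fixtures")
    from genedecay.simulate import make_fixture_suite

    return make_fixture_suite(out, seed=FIXTURE_SEED)


@pytest.fixture
def toy_alignment():
    """4 species x 30 columns, reference ungapped, with planted events.

    Mouse is the intact reference.  SpA carries a 1-bp deletion at reference
    position 7; SpB carries a premature stop (TGA) at reference codon 4
    (positions 10-12); SpC matches the reference.
    """
    from genedecay.core import CodonAlignment

    mouse = "ATGGCCAAATTTGGGCCCAAAGAGTTTTAA"
    spa = mouse[:6] + "-" + mouse[7:]
    spb = mouse[:9] + "TGA" + mouse[12:]
    return CodonAlignment(
        records=[("Mouse", mouse), ("SpA", spa), ("SpB", spb), ("SpC", mouse)],
        reference_id="Mouse",
    )
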
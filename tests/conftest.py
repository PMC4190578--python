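import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cottondge import simulate as sim
from cottondge.tags import TagLibrary, build_tag_database


@pytest.fixture(scope="session")
def small_reference():
    """100 transcripts, some tagless, some paralogous."""
    return sim.generate_reference(
        100, (100, 500), no_catg_fraction=0.05, paralog_fraction=0.2, seed=11
    )


@pytest.fixture(scope="session")
def small_db(small_reference):
    return build_tag_database(small_reference)


@pytest.fixture(scope="session")
def design():
    return sim.generate_design()


@pytest.fixture(scope="session")
def two_line_design():
    return sim.generate_design(["TM-1", "CSIL-A"], ["05DPA"], "TM-1")


def library_from_counts(library_id: str, counts: dict[str, int]) -> TagLibrary:
    """Gene-count-level TagLibrary for tests that bypass tag sequencing."""
    total = sum(counts.values())
    return TagLibrary(
        library_id=library_id,
        raw_total=total,
        clean={},
        clean_total=total,
        mapped_unambiguous=dict(counts),
    )


def multinomial_library(
    library_id: str,
    abundance: np.ndarray,
    genes: list[str],
    depth: int,
    rng: np.random.Generator,
) -> TagLibrary:
    """Draw gene counts directly from true abundances (no sequencing noise)."""
    counts = rng.multinomial(depth, abundance / abundance.sum())
    return library_from_counts(
        library_id, {g: int(c) for g, c in zip(genes, counts) if c > 0}
    )
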
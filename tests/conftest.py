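import numpy as np
import pytest

from phfold.constants import DEFAULT_MODEL_PKA, TITRATABLE_CLASSES
from phfold.structures import TitratableSite
from phfold.synthetic import build_toy_protein, planted_sites, random_fixture
from phfold.titration import PhGrid


def make_site(
    site_class: str,
    resnum: int = 2,
    intrinsic_pka: float | None = None,
    model_pka: float | None = None,
    center=(0.0, 0.0, 0.0),
    chain: str = "A",
) -> TitratableSite:
    polarity = TITRATABLE_CLASSES[site_class][0]
    model = DEFAULT_MODEL_PKA[site_class] if model_pka is None else model_pka
    return TitratableSite(
        chain=chain,
        resnum=resnum,
        resname=site_class,
        site_class=site_class,
        polarity=polarity,
        center=tuple(float(x) for x in center),
        model_pka=model,
        intrinsic_pka=model if intrinsic_pka is None else intrinsic_pka,
    )


@pytest.fixture
def grid() -> PhGrid:
    return PhGrid(4.0, 8.0, 0.1)


@pytest.fixture
def fine_grid() -> PhGrid:
    return PhGrid(4.0, 8.0, 0.01)


def oracle_fixture(seed: int):
    """Random ≤12-site fixture with planted intrinsic pKas and geometry."""
    spec = random_fixture(seed)
    structure, truth = build_toy_protein(spec)
    return planted_sites(structure, truth)


@pytest.fixture
def twelve_site_sites():
    # seed chosen so the fixture has the full 12 sites
    for seed in range(100):
        sites = oracle_fixture(seed)
        if len(sites) == 12:
            return sites
    raise AssertionError("no 12-site fixture found")
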
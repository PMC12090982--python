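import pytest
from hypothesis import settings

from glycominion import GlycanComposition

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def comp(**counts) -> GlycanComposition:
    """Shorthand composition constructor for tests."""
    return GlycanComposition(counts)


@pytest.fixture
def grid_compositions():
    """Every composition with Hex<=12, HexNAc<=12, dHex<=4, NeuAc<=4."""
    comps = []
    for h in range(13):
        for n in range(13):
            for f in range(5):
                for s in range(5):
                    if h + n + f + s:
                        comps.append(GlycanComposition(
                            {"Hex": h, "HexNAc": n, "dHex": f, "NeuAc": s}))
    return comps
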
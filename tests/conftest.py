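import itertools
import math

import numpy as np
import pytest

from sirmkit.isotopes import ISOTOPE_SHIFTS, ElementalFormula, load_fragment_library


def enumerate_natural_pattern(formula: ElementalFormula, K: int) -> np.ndarray:
    """Independent oracle: exhaustive enumeration over per-atom isotope choices.

    Tractable for fragments with <= ~12 atoms.
    """
    atoms: list[str] = []
    for el, n in formula.counts.items():
        atoms.extend([el] * n)
    out = np.zeros(K + 1)
    options = [list(ISOTOPE_SHIFTS[el].items()) for el in atoms]
    for combo in itertools.product(*options):
        shift = sum(s for s, _ in combo)
        if shift <= K:
            out[shift] += math.prod(a for _, a in combo)
    return out


@pytest.fixture(scope="session")
def fragment_library():
    return load_fragment_library()
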
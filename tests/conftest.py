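import numpy as np
import pytest

from perfusim.circuit import (
    FixedResistor,
    FluidicNetwork,
    NetworkElement,
    WATER_20C,
    parallel_total,
    series_total,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20220820)


def random_ladder(rng, n_branches=None):
    """Random series–parallel ladder between ``inlet`` and ``outlet``.

    Series entry resistor → parallel branches (each a series chain of 1–3
    resistors) → series exit resistor. Returns (network, reduced resistance
    computed independently through the series/parallel laws).
    """
    if n_branches is None:
        n_branches = int(rng.integers(2, 7))
    elements = []
    r_in = float(rng.uniform(1e8, 1e10))
    r_out = float(rng.uniform(1e8, 1e10))
    elements.append(NetworkElement("r_in", FixedResistor(r_in), "inlet", "top"))
    branch_totals = []
    for b in range(n_branches):
        chain = [float(rng.uniform(1e9, 1e12)) for _ in range(int(rng.integers(1, 4)))]
        prev = "top"
        for j, r in enumerate(chain):
            node = f"b{b}_{j}" if j < len(chain) - 1 else "bottom"
            elements.append(NetworkElement(f"b{b}_r{j}", FixedResistor(r), prev, node))
            prev = node
        branch_totals.append(series_total(chain))
    elements.append(NetworkElement("r_out", FixedResistor(r_out), "bottom", "outlet"))
    reduced = series_total([r_in, parallel_total(branch_totals), r_out])
    net = FluidicNetwork(elements, {"inlet": 0.0, "outlet": 0.0}, WATER_20C)
    return net, reduced
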
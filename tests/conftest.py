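import pytest

from elastnet import VentricleParams, build_default_tree, simulate


@pytest.fixture(scope="session")
def reference_simulation():
    """Reference subject (default ventricle, unscaled tree) at steady state."""
    return simulate(VentricleParams(), build_default_tree())


@pytest.fixture(scope="session")
def ees_sweep_simulations():
    """Paired simulations varying only E_es over {1.5, 2.0, 2.5, 3.0}."""
    tree = build_default_tree()
    out = {}
    for ees in (1.5, 2.0, 2.5, 3.0):
        out[ees] = simulate(VentricleParams(E_es=ees), tree)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort shared by bookkeeping tests."""
    from elastnet import generate_cohort

    return generate_cohort(40, seed=123)


@pytest.fixture(scope="session")
def medium_cohort():
    """A cohort large enough for population-statistics checks."""
    from elastnet import generate_cohort

    return generate_cohort(300, seed=99)


@pytest.fixture(scope="session")
def toy_dataset():
    """500 toy pulses with smooth-function labels, split and normalized."""
    from elastnet import (
        fit_channel_scalers,
        generate_toy_fixtures,
        make_channels,
        split_60_20_20,
    )

    wm, labels = generate_toy_fixtures(500, seed=7)
    split = split_60_20_20(wm.n, seed=8)
    scalers = fit_channel_scalers(wm, split.train, "two_channel")
    X = make_channels(wm, "two_channel", scalers)
    return {"wm": wm, "labels": labels, "split": split, "scalers": scalers, "X": X}
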
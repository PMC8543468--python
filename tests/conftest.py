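import numpy as np
import pytest

from margeflux import (
    ExchangeConstraint,
    ExchangeConstraintSet,
    MargeParams,
    MetabolicModel,
    extend_model,
    max_uptake_rate,
)
from margeflux.exo import SECRETION, UPTAKE, measurements_from_frame
from margeflux.synthetic import ToyScenario, make_toy_model, simulate_condition_pair


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def toy_ext(toy_model):
    return extend_model(toy_model)


@pytest.fixture()
def noiseless_data():
    return simulate_condition_pair(
        ToyScenario(seed=0, expression_sigma=0.0, abundance_sigma=0.0)
    )


def measurements(data):
    return measurements_from_frame(data.exomet)


def make_variant(seed: int) -> MetabolicModel:
    """Structural variant of the toy network: different energy yields,
    exchange bounds, isozyme counts and reversibility."""
    rng = np.random.default_rng(seed)
    d = make_toy_model().to_dict()
    for r in d["reactions"]:
        if r["id"] == "OXPHOS":
            r["stoichiometry"]["nrg"] = int(rng.integers(10, 21))
        elif r["id"] == "GLYC":
            r["stoichiometry"]["nrg"] = int(rng.integers(1, 4))
        elif r["id"] == "EX_glc":
            r["lb"] = -float(rng.uniform(5.0, 15.0))
        elif r["id"] == "LDH" and rng.random() < 0.5:
            r["lb"] = 0.0  # irreversible variant
    if rng.random() < 0.5:
        d["gpr_rules"]["HEX"] = "gHK1 or gHK2 or gHK3"
    return MetabolicModel.from_dict(d)


def random_scenario(seed: int):
    """A feasible randomized MARGE instance on a network variant.

    Direction calls follow the network's natural operating mode (glucose
    and glutamine uptake, lactate secretion) so the floors and wide ratio
    intervals are always jointly satisfiable.
    """
    model = make_variant(seed)
    ext = extend_model(model)
    rng = np.random.default_rng(seed + 10_000)
    cset = ExchangeConstraintSet(tau=0.5, phi=0.01)
    for ex, met, direction in (
        ("EX_glc", "glc", UPTAKE),
        ("EX_lac", "lac", SECRETION),
        ("EX_gln", "gln", UPTAKE),
    ):
        vmax = max_uptake_rate(ext, ex)
        con = ExchangeConstraint(ex, met, direction, direction, 0.01 * vmax, 0.01 * vmax)
        if rng.random() < 0.6:
            fc = float(rng.uniform(0.7, 1.6))
            con.ratio_interval = (0.5 * fc, 1.5 * fc)
        cset.constraints[ex] = con
    ratios = {
        key: float(2.0 ** rng.normal(0.0, 0.7))
        for key in ext.usage_groups
        if rng.random() < 0.75
    }
    growth = None if rng.random() < 0.5 else float(rng.uniform(0.2, 0.6))
    params = MargeParams(growth_frac_a=growth, growth_frac_b=growth)
    return model, ext, ratios, cset, params
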
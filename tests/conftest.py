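from __future__ import annotations

import pytest
from hypothesis import settings

from debrisdose.records import BirdRecord, Cohort, DebrisItem
from debrisdose.simulate import default_config, generate_cohort
from debrisdose.synthetic_reference import published_marginals_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_bird(
    bird_id="b1",
    cod="KND",
    n_items=0,
    item_type="hard_plastic",
    species="SP1",
    weight=500.0,
    **kw,
):
    items = tuple(DebrisItem(item_type) for _ in range(n_items))
    if cod == "KD":
        kw.setdefault("lethal_item_type", item_type)
    return BirdRecord(
        bird_id=bird_id,
        species=species,
        family="Procellariidae",
        age_class=kw.pop("age_class", "adult"),
        species_weight=weight,
        cod=cod,
        items=items,
        **kw,
    )


@pytest.fixture
def tiny_cohort():
    """One bird per COD category."""
    return Cohort(
        [
            make_bird("a", cod="KND", n_items=0),
            make_bird("b", cod="Ind", n_items=2),
            make_bird("c", cod="KD", n_items=3),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config synthetic cohort (1733 birds)."""
    cohort, truth = generate_cohort(default_config(seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def marginals_cohort():
    """Synthetic reconstruction of the published marginal totals."""
    return published_marginals_cohort()
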
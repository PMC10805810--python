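import numpy as np
import pytest

from kgsdl.campaign import CampaignConfig, default_config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_config(*, allowance=6, seed=0, labs=("cambridge", "singapore"),
                noise=0.0, control=False, faults=(), unreachable_goals=True,
                n_init=4, nsga_pop=24, nsga_gen=20, n_spectral=120,
                **extra) -> CampaignConfig:
    """Small, fast campaign configuration for tests.

    Defaults: noise off, control gate off, unreachable goal thresholds (so the
    campaign always spends its full allowance), and a lightweight optimiser.
    """
    cfg = default_config()
    gr = cfg.goal_request.model_copy(update={
        "cycle_allowance": allowance,
        "labs": list(labs),
    })
    if unreachable_goals:
        gr = gr.model_copy(update={"objectives": [
            {"objective": "yield", "direction": "maximise", "threshold": 101.0},
            {"objective": "run_material_cost", "direction": "minimise",
             "threshold": 0.0}]})
    lab_cfgs = []
    for lab in cfg.labs:
        if lab.name not in labs:
            continue
        hplc = lab.hplc.model_copy(update={"area_noise_sigma": noise})
        lab_cfgs.append(lab.model_copy(update={"hplc": hplc}))
    update = {
        "goal_request": gr,
        "labs": lab_cfgs,
        "seed": seed,
        "control": cfg.control.model_copy(update={"enabled": control}),
        "faults": list(faults),
        "optimiser": cfg.optimiser.model_copy(update={
            "n_init": n_init, "nsga_pop": nsga_pop, "nsga_gen": nsga_gen,
            "n_spectral": n_spectral}),
    }
    update.update(extra)
    return CampaignConfig.model_validate(
        cfg.model_copy(update=update).model_dump())


@pytest.fixture
def small_config():
    return make_config()
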
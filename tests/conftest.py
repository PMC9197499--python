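import numpy as np
import pytest

from catlab.irt import ItemBank, ItemParams, Model
from catlab.synth import SynthSpec, generate_bank, generate_thetas, simulate_responses


@pytest.fixture(scope="session")
def sas_c3():
    """A published 5-category graded item: a=1.26, thresholds from the bank table."""
    return ItemParams(
        "SAS_C3", "SASC", Model.GRM, 5, 1.26, (-2.111, -0.191, 1.250, 3.602)
    )


@pytest.fixture(scope="session")
def dichotomous_grm():
    return ItemParams("d1", "X", Model.GRM, 2, 1.0, (0.0,))


@pytest.fixture(scope="session")
def gpcm_item():
    return ItemParams("g1", "X", Model.GPCM, 4, 1.5, (-1.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def small_bank():
    """10-item mixed-category GRM bank used across engine/calibration tests."""
    spec = SynthSpec(scale_layout=(("A", 6, 5), ("B", 4, 4)), seed=42, n_respondents=0)
    return generate_bank(spec)


@pytest.fixture(scope="session")
def bank89():
    """89-item synthetic GRM bank mirroring the screened pool's envelope."""
    spec = SynthSpec(seed=11)
    bank = generate_bank(spec)
    return ItemBank(bank.items[:89], provenance="synthetic 89-item bank")


@pytest.fixture(scope="session")
def cohort89(bank89):
    """200-respondent cohort answering the 89-item bank (complete data)."""
    spec = SynthSpec(seed=11)
    thetas = generate_thetas(200, spec, seed=21)
    X = simulate_responses(bank89, thetas, seed=22)
    return X, thetas


@pytest.fixture(scope="session")
def recovery_data(small_bank):
    """n=1000 responses from the known 10-item bank, for parameter recovery."""
    spec = SynthSpec(seed=42)
    thetas = generate_thetas(1000, spec, seed=101)
    X = simulate_responses(small_bank, thetas, seed=102)
    return X, thetas


@pytest.fixture(scope="session")
def recovery_harness():
    """Parameter-recovery sweep: 5 replicate 10-item GRM banks, n=1000 each.

    Pools estimation errors across replicates (a single draw's RMSE is
    dominated by the handful of responses behind each extreme threshold).
    """
    from catlab.calibration import CalibrationSettings, fit_mml_em

    errs_a, errs_b, biases = [], [], []
    first_result = None
    for rep in range(5):
        bank = generate_bank(
            SynthSpec(scale_layout=(("A", 6, 5), ("B", 4, 4)), seed=40 + rep)
        )
        thetas = generate_thetas(1000, SynthSpec(seed=0), seed=101 + rep)
        X = simulate_responses(bank, thetas, seed=201 + rep)
        res = fit_mml_em(X, CalibrationSettings())
        if first_result is None:
            first_result = res
        ea = [res.bank[it.item_id].a - it.a for it in bank]
        for it in bank:
            errs_b.extend(
                np.asarray(res.bank[it.item_id].thresholds) - np.asarray(it.thresholds)
            )
        errs_a.extend(ea)
        biases.append(np.mean(ea))
    return {
        "rmse_a": float(np.sqrt(np.mean(np.square(errs_a)))),
        "rmse_b": float(np.sqrt(np.mean(np.square(errs_b)))),
        "mean_bias_a": float(np.mean(biases)),
        "first_result": first_result,
    }
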
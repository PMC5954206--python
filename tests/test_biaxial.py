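"""Biaxial datasets and GOH fitting: residuals, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

from reappose import (BiaxialDataError, BiaxialDataset, BiaxialProtocolSpec,
                      biaxial_cauchy_stress, fit_goh, generate_biaxial_dataset,
                      residual_sse)


@pytest.fixture()
def noise_free_mid3(flap_params):
    return generate_biaxial_dataset(flap_params["mid_3"],
                                    BiaxialProtocolSpec(cv=0.0, seed=1))


def test_sse_zero_on_generating_parameters(flap_params, noise_free_mid3):
    assert residual_sse(flap_params["mid_3"], noise_free_mid3) == pytest.approx(
        0.0, abs=1e-10)


def test_sse_arithmetic_single_record(flap_params):
    """One record offset by (+10, -10) Pa must give SSE = 200 Pa^2."""
    p = flap_params["mid_1"]
    scc, saa = biaxial_cauchy_stress(p, 1.1, 1.05)
    df = pd.DataFrame([
        dict(protocol="a", lambda_c=1.1, lambda_a=1.05,
             sigma_cc_pa=scc + 10.0, sigma_aa_pa=saa - 10.0),
        dict(protocol="b", lambda_c=1.0, lambda_a=1.0,
             sigma_cc_pa=0.0, sigma_aa_pa=0.0),
    ])
    ds = BiaxialDataset(df)
    assert residual_sse(p, ds) == pytest.approx(200.0, rel=1e-12)


def test_sse_cross_parameter_direct_evaluation(flap_params):
    """SSE of pig #2 distal parameters against pig #4 distal data equals the
    independently summed squared stress differences."""
    p2, p4 = flap_params["distal_2"], flap_params["distal_4"]
    ds = generate_biaxial_dataset(p4, BiaxialProtocolSpec(cv=0.0, seed=2))
    df = ds.records
    scc, saa = biaxial_cauchy_stress(p2, df["lambda_c"].to_numpy(),
                                     df["lambda_a"].to_numpy())
    expected = float(np.sum((scc - df["sigma_cc_pa"].to_numpy()) ** 2
                            + (saa - df["sigma_aa_pa"].to_numpy()) ** 2))
    got = residual_sse(p2, ds)
    assert got > 0.0
    assert got == pytest.approx(expected, rel=1e-12)


def test_sse_invariant_to_record_order(flap_params, noise_free_mid3):
    df = noise_free_mid3.records
    shuffled = BiaxialDataset(df.sample(frac=1.0, random_state=5)
                              .reset_index(drop=True))
    p = flap_params["mid_2"]
    assert residual_sse(p, noise_free_mid3) == pytest.approx(
        residual_sse(p, shuffled), rel=1e-12)


def test_dataset_validation():
    with pytest.raises(BiaxialDataError, match="empty"):
        BiaxialDataset(pd.DataFrame(columns=["protocol", "lambda_c", "lambda_a",
                                             "sigma_cc_pa", "sigma_aa_pa"]))
    bad = pd.DataFrame([dict(protocol="a", lambda_c=0.5, lambda_a=1.0,
                             sigma_cc_pa=0.0, sigma_aa_pa=0.0)])
    with pytest.raises(BiaxialDataError, match="stretch"):
        BiaxialDataset(bad)


def test_fit_requires_enough_data(flap_params):
    p = flap_params["mid_1"]
    ds = generate_biaxial_dataset(p, BiaxialProtocolSpec(
        ratios=((1.0, 1.0),), points=5, cv=0.0, seed=0))
    with pytest.raises(BiaxialDataError, match="protocols"):
        fit_goh(ds)


def test_fit_round_trip_stress_recovery(flap_params, noise_free_mid3):
    """Noise-free data generated from pig #3 mid flap: the fitted model must
    reproduce the generating stresses essentially exactly (SSE/record < 1)."""
    fr = fit_goh(noise_free_mid3, n_restarts=8, seed=0)
    assert fr.converged
    assert fr.sse / len(noise_free_mid3) < 1.0
    # best-objective trace is monotone non-increasing across restarts
    assert all(b <= a + 1e-12 for a, b in zip(fr.trace, fr.trace[1:]))


def test_fit_deterministic_given_seed(flap_params, noise_free_mid3):
    f1 = fit_goh(noise_free_mid3, n_restarts=3, seed=7, max_iter=400,
                 n_polish=1)
    f2 = fit_goh(noise_free_mid3, n_restarts=3, seed=7, max_iter=400,
                 n_polish=1)
    assert f1.sse == f2.sse
    assert f1.params.c10 == f2.params.c10


def test_fit_kappa_third_alpha_degenerate(flap_params):
    """Data generated at kappa = 1/3: the fit's predictions must be invariant
    to the (unidentifiable) fiber angle."""
    gen = flap_params["mid_1"].replace(kappa=1.0 / 3.0, label="iso")
    ds = generate_biaxial_dataset(gen, BiaxialProtocolSpec(cv=0.0, seed=4))
    fr = fit_goh(ds, n_restarts=6, seed=1)
    fitted = fr.params
    lc, la = 1.22, 1.1
    ref = biaxial_cauchy_stress(fitted, lc, la)
    rotated = fitted.replace(alpha_deg=min(90.0, fitted.alpha_deg + 41.0))
    # prediction shift from rotating alpha must be tiny relative to stress
    if abs(fitted.kappa - 1.0 / 3.0) < 0.02:
        alt = biaxial_cauchy_stress(rotated, lc, la)
        assert alt[0] == pytest.approx(ref[0], rel=0.02)
    # stress-space recovery regardless of parameter identifiability
    assert fr.sse / len(ds) < 1.0
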
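"""Synthetic biaxial data and material-variant generators."""

import numpy as np
import pytest

from reappose import (BiaxialProtocolSpec, biaxial_cauchy_stress,
                      generate_biaxial_dataset, generate_material_variants,
                      residual_sse)


def test_noise_free_round_trip(flap_params):
    p = flap_params["mid_1"]
    ds = generate_biaxial_dataset(p, BiaxialProtocolSpec(cv=0.0, seed=9))
    assert residual_sse(p, ds) == pytest.approx(0.0, abs=1e-10)
    assert len(ds) == 45 and ds.n_protocols == 3


def test_same_seed_identical(flap_params):
    p = flap_params["distal_1"]
    spec = BiaxialProtocolSpec(cv=0.05, seed=17)
    d1 = generate_biaxial_dataset(p, spec)
    d2 = generate_biaxial_dataset(p, spec)
    assert d1.records.equals(d2.records)
    d3 = generate_biaxial_dataset(p, BiaxialProtocolSpec(cv=0.05, seed=18))
    assert not d1.records.equals(d3.records)


def test_noise_has_declared_coefficient_of_variation(flap_params):
    """Empirical CV of (noisy/true - 1) within 3-sigma of the nominal 0.02."""
    p = flap_params["mid_1"]
    cv = 0.02
    ds = generate_biaxial_dataset(p, BiaxialProtocolSpec(cv=cv, seed=17))
    df = ds.records
    scc, saa = biaxial_cauchy_stress(p, df["lambda_c"].to_numpy(),
                                     df["lambda_a"].to_numpy())
    ratios = np.concatenate([
        df["sigma_cc_pa"].to_numpy() / np.where(np.abs(scc) > 1e-9, scc, np.nan),
        df["sigma_aa_pa"].to_numpy() / np.where(np.abs(saa) > 1e-9, saa, np.nan),
    ]) - 1.0
    ratios = ratios[np.isfinite(ratios)]
    n = len(ratios)
    # sd of the sample std is ~ cv/sqrt(2n)
    assert np.std(ratios) == pytest.approx(cv, abs=3 * cv / np.sqrt(2 * n))
    assert np.mean(ratios) == pytest.approx(0.0, abs=3 * cv / np.sqrt(n))


def test_protocol_spec_validation():
    with pytest.raises(ValueError):
        BiaxialProtocolSpec(max_stretch=0.9)
    with pytest.raises(ValueError):
        BiaxialProtocolSpec(points=2)
    with pytest.raises(ValueError):
        BiaxialProtocolSpec(cv=-0.1)


def test_variants_n1_is_base(flap_params):
    base = flap_params["mid_1"]
    assert generate_material_variants(base, {"c10": 0.2}, 1) == [base]


def test_variants_zero_ranges_copies(flap_params):
    base = flap_params["mid_2"]
    vs = generate_material_variants(base, {}, 5, seed=1)
    assert all(v.c10 == base.c10 and v.k1 == base.k1 for v in vs)


def test_variants_within_ranges_and_centered(flap_params):
    base = flap_params["mid_3"]
    vs = generate_material_variants(base, {"c10": 0.2, "k1": 0.2}, 100, seed=3)
    c10 = np.array([v.c10 for v in vs[1:]])
    k1 = np.array([v.k1 for v in vs[1:]])
    assert c10.min() >= 0.8 * base.c10 and c10.max() <= 1.2 * base.c10
    assert k1.min() >= 0.8 * base.k1 and k1.max() <= 1.2 * base.k1
    assert c10.mean() == pytest.approx(base.c10, rel=0.02)
    assert k1.mean() == pytest.approx(base.k1, rel=0.02)


def test_variants_reject_bound_violation(flap_params):
    base = flap_params["mid_1"]  # kappa = 0.33, near the 1/3 bound
    with pytest.raises(Exception):
        generate_material_variants(base, {"kappa": 0.2}, 5)
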
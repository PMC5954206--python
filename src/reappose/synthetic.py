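"""Synthetic inputs: biaxial test emulation and material-variant sampling.

The planar-biaxial generator emulates a displacement-controlled two-axis test:
each protocol ramps the circumferential/axial stretches along a fixed
increment ratio (defaults 1:1, 1:0.75, 0.75:1, typical for planar biaxial
testing of arterial tissue) up to a moderate maximum stretch, and stresses
are GOH model stresses corrupted by seeded multiplicative Gaussian noise,
``sigma_meas = sigma_model * (1 + cv * z)``.  Multiplicative noise is used
because biaxial stress magnitudes span orders of magnitude over a stretch
ramp.  ``cv = 0`` returns exact model stresses.

:func:`generate_material_variants` draws seeded uniform perturbations of a
base parameter set for sensitivity studies, with the base returned unchanged
as variant 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biaxial import BiaxialDataset
from .constitutive import GOHParameters, biaxial_cauchy_stress

DEFAULT_RATIOS = ((1.0, 1.0), (1.0, 0.75), (0.75, 1.0))


@dataclass(frozen=True)
class BiaxialProtocolSpec:
    """Stretch-ramp protocols for the synthetic biaxial test.

    ``ratios`` are (circumferential, axial) stretch-increment ratios, one
    protocol per pair; each protocol holds ``points`` levels up to
    ``1 + ratio * (max_stretch - 1)`` per axis.  ``cv`` is the coefficient of
    variation of the multiplicative Gaussian noise.
    """

    ratios: tuple = DEFAULT_RATIOS
    max_stretch: float = 1.30
    points: int = 15
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.max_stretch <= 1.0:
            raise ValueError("max_stretch must be > 1")
        if self.points < 3:
            raise ValueError("points must be >= 3")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if len(self.ratios) == 0:
            raise ValueError("need at least one protocol ratio")


def generate_biaxial_dataset(params: GOHParameters, spec: BiaxialProtocolSpec) -> BiaxialDataset:
    """Seeded synthetic biaxial dataset from known GOH parameters."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for ip, (rc, ra) in enumerate(spec.ratios):
        s = np.linspace(0.0, 1.0, spec.points + 1)[1:]
        lc = 1.0 + s * rc * (spec.max_stretch - 1.0)
        la = 1.0 + s * ra * (spec.max_stretch - 1.0)
        scc, saa = biaxial_cauchy_stress(params, lc, la)
        scc = np.atleast_1d(scc) * (1.0 + spec.cv * rng.standard_normal(spec.points))
        saa = np.atleast_1d(saa) * (1.0 + spec.cv * rng.standard_normal(spec.points))
        for j in range(spec.points):
            rows.append(dict(protocol=f"p{ip}_{rc:g}:{ra:g}", lambda_c=lc[j],
                             lambda_a=la[j], sigma_cc_pa=scc[j], sigma_aa_pa=saa[j]))
    return BiaxialDataset(pd.DataFrame(rows), specimen=params.label)


_VARIANT_FIELDS = ("c10", "k1", "k2", "alpha_deg", "kappa", "thickness_mm")


def generate_material_variants(
    base: GOHParameters, relative_ranges: dict, n: int, seed: int = 0
) -> list[GOHParameters]:
    """``n`` seeded parameter sets uniform within +/- relative ranges of ``base``.

    ``relative_ranges`` maps field names (subset of c10, k1, k2, alpha_deg,
    kappa, thickness_mm) to relative half-widths, e.g. ``{"c10": 0.2}`` for
    +/-20 %.  Variant 0 is the unperturbed base.  Raises if a range can push a
    parameter outside its physical bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = set(relative_ranges) - set(_VARIANT_FIELDS)
    if unknown:
        raise ValueError(f"unknown parameter fields {sorted(unknown)}")
    # pre-check that extreme corners remain valid
    extremes = {f: base.__getattribute__(f) * (1.0 + relative_ranges.get(f, 0.0))
                for f in _VARIANT_FIELDS}
    GOHParameters(**extremes, label=base.label)  # raises on bound violation
    extremes = {f: base.__getattribute__(f) * (1.0 - relative_ranges.get(f, 0.0))
                for f in _VARIANT_FIELDS}
    GOHParameters(**extremes, label=base.label)

    rng = np.random.default_rng(seed)
    out = [base]
    for i in range(1, n):
        kw = {}
        for f in _VARIANT_FIELDS:
            r = relative_ranges.get(f, 0.0)
            kw[f] = base.__getattribute__(f) * (1.0 + r * rng.uniform(-1.0, 1.0))
        out.append(GOHParameters(**kw, label=f"{base.label}_var{i}"))
    return out
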
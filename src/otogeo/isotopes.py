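"""Stable-isotope standardization and aragonite fractionation equations.

Delta values are handled in permil throughout.  Carbonate measurements are
standardized against NBS-19 (nominal 1.95 permil VPDB for d13C, -2.20 permil
for d18O) by chaining the sample/standard delta with the standard's nominal
VPDB delta, both taken in fractional form inside the product.  Seawater d18O
reported on the SMOW scale converts to VPDB through the printed affine map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: nominal NBS-19 delta values relative to VPDB, permil
NBS19_D13C_VPDB = 1.95
NBS19_D18O_VPDB = -2.20
NOMINAL_VPDB = {"13C": NBS19_D13C_VPDB, "18O": NBS19_D18O_VPDB}


def delta_sample_ref(R_sample: float, R_reference: float) -> float:
    """Sample-vs-reference delta (permil): 1000 * (1 - R_sample/R_reference)."""
    if R_sample <= 0 or R_reference <= 0:
        raise ValueError("isotopic ratios must be positive")
    return 1000.0 * (1.0 - R_sample / R_reference)


def delta_vpdb(R_sample: float, R_reference: float, nominal_ref_vpdb: float) -> float:
    """Standardize a measured ratio to the VPDB scale (permil).

    delta_VPDB = (delta_sample/ref + 1) * (delta_ref/VPDB + 1) - 1 with all
    deltas in fractional (permil/1000) form; the result is returned in permil.
    A sample measuring exactly the reference ratio returns the reference's
    nominal VPDB delta.
    """
    d_sr = delta_sample_ref(R_sample, R_reference) / 1000.0
    d_ref = nominal_ref_vpdb / 1000.0
    return 1000.0 * ((d_sr + 1.0) * (d_ref + 1.0) - 1.0)


def smow_to_vpdb(d18o_smow):
    """Convert d18O from the SMOW to the VPDB scale (permil, affine map)."""
    return 0.97006 * np.asarray(d18o_smow, dtype=float) - 29.94


def vpdb_to_smow(d18o_vpdb):
    """Inverse of :func:`smow_to_vpdb` (permil)."""
    return (np.asarray(d18o_vpdb, dtype=float) + 29.94) / 0.97006


@dataclass(frozen=True)
class FractionationEquation:
    """Linear aragonite-water fractionation: d18O_oto = a + b*T + c*d18O_water.

    ``residual_sd`` (permil) is the unexplained fractionation scatter used in
    Monte-Carlo error propagation.
    """

    name: str
    intercept: float  # permil
    temp_slope: float  # permil per degC
    water_coefficient: float = 1.0
    residual_sd: float = 0.2  # permil (assumed; not published)

    def __call__(self, temperature, d18o_water):
        return predict_oto(self, temperature, d18o_water)


#: the equation used for geo-location in this pipeline (biogenic aragonite)
THORROLD = FractionationEquation(name="thorrold", intercept=4.64, temp_slope=-0.21)


def predict_oto(eq: FractionationEquation, temperature, d18o_water):
    """Expected otolith d18O (permil VPDB) at a temperature and water d18O."""
    t = np.asarray(temperature, dtype=float)
    w = np.asarray(d18o_water, dtype=float)
    out = eq.intercept + eq.temp_slope * t + eq.water_coefficient * w
    return float(out) if out.ndim == 0 else out
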
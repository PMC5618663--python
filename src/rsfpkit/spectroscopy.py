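"""Spectroscopic property calculations for GFP-family photoswitchers.

Covers the standard characterization quantities: the pKa from a sigmoidal
(Henderson–Hasselbalch) fit to a pH titration of the anionic absorbance
peak, extinction coefficients by Ward's denatured-chromophore ratio method,
the Henderson–Hasselbalch extrapolation of the pH 7.4 extinction coefficient
to the fully deprotonated chromophore, fluorescence quantum yields relative
to EGFP, and molecular brightness scaled to a reference construct.

Reported percents and scaled brightness values are rounded
half-away-from-zero to integers, the convention used in characterization
tables of this kind; brightness percent changes are computed on the
integer-scaled values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SpectroscopicProfile",
    "TitrationFit",
    "fit_pka",
    "extrapolate_eon",
    "extinction_wards",
    "relative_quantum_yield",
    "molecular_brightness",
    "percent_change",
    "round_half_away",
    "profile_table",
]


def round_half_away(x: float | np.ndarray) -> int | np.ndarray:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3), unlike banker's rounding."""
    out = np.copysign(np.floor(np.abs(x) + 0.5), x)
    return int(out) if np.isscalar(x) or np.ndim(x) == 0 else out.astype(int)


@dataclass(frozen=True)
class SpectroscopicProfile:
    """One construct's spectroscopic characterization row.

    Extinction coefficients are carried in L mol^-1 cm^-1 (report renderers
    divide by 10^3).  ``brightness_scaled`` is the molecular brightness
    (eps7.4 * phi) scaled to 100 for the reference construct, filled by
    :func:`molecular_brightness`.
    """

    name: str
    lambda_ex: float | None = None
    lambda_em: float | None = None
    pKa: float | None = None
    phi: float | None = None
    eps74: float | None = None
    eps_on: float | None = None
    brightness_scaled: int | None = None

    def __post_init__(self) -> None:
        if self.phi is not None and not 0 <= self.phi <= 1:
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.eps74 is not None and self.eps74 <= 0:
            raise ValueError("eps7.4 must be positive")
        if self.eps_on is not None and self.eps74 is not None and self.eps_on < self.eps74:
            raise ValueError("eps_on must be >= eps7.4 (deprotonation can only increase absorption)")


@dataclass
class TitrationFit:
    """Sigmoidal pH-titration fit; pKa is the inflection point."""

    pKa: float
    hill: float
    A_max: float
    A_min: float
    residual_norm: float
    success: bool
    message: str = ""

    def predict(self, pH: np.ndarray) -> np.ndarray:
        return _sigmoid_titration(np.asarray(pH, dtype=float), self.pKa, self.hill, self.A_min, self.A_max)


def _sigmoid_titration(pH, pKa, hill, A_min, A_max):
    return A_min + (A_max - A_min) / (1.0 + 10.0 ** (hill * (pKa - pH)))


def fit_pka(pH: np.ndarray, absorbance: np.ndarray) -> TitrationFit:
    """Fit A(pH) = A_min + (A_max - A_min)/(1 + 10^(hill (pKa - pH))).

    The pKa is reported as the inflection point of the fitted sigmoid.  The
    Hill coefficient is a free parameter initialized at 1.  Degenerate data
    (absorbance already saturated at every pH, or a fitted midpoint outside
    the sampled range) yields ``success=False`` — no silent extrapolation.
    """
    pH = np.asarray(pH, dtype=float)
    A = np.asarray(absorbance, dtype=float)
    if len(pH) != len(A):
        raise ValueError("pH and absorbance must have equal length")
    if len(pH) < 5:
        raise ValueError("need at least 5 titration points")

    span = A.max() - A.min()
    if span < 0.05 * max(abs(A.max()), 1e-12):
        return TitrationFit(
            pKa=float("nan"), hill=float("nan"), A_max=float(A.max()), A_min=float(A.min()),
            residual_norm=0.0, success=False,
            message="absorbance nearly constant over the pH range: no transition to fit",
        )

    # midpoint crossing as pKa initializer
    half = A.min() + span / 2
    order = np.argsort(pH)
    pka0 = float(np.interp(half, A[order], pH[order]))
    p0 = [pka0, 1.0, float(A.min()), float(A.max())]
    try:
        popt, _ = optimize.curve_fit(
            lambda x, pka, hill, amin, amax: _sigmoid_titration(x, pka, hill, amin, amax),
            pH, A, p0=p0, maxfev=20000,
        )
    except RuntimeError as err:
        return TitrationFit(
            pKa=float("nan"), hill=float("nan"), A_max=float(A.max()), A_min=float(A.min()),
            residual_norm=float("nan"), success=False, message=f"fit failed: {err}",
        )
    pka, hill, amin, amax = map(float, popt)
    resid = _sigmoid_titration(pH, *popt) - A
    in_range = pH.min() <= pka <= pH.max()
    return TitrationFit(
        pKa=pka, hill=hill, A_max=amax, A_min=amin,
        residual_norm=float(np.linalg.norm(resid)),
        success=in_range,
        message="" if in_range else "fitted inflection point lies outside the sampled pH range",
    )


def extrapolate_eon(eps74: float, pKa: float, pH: float = 7.4) -> float:
    """Henderson–Hasselbalch extrapolation to the deprotonated-state extinction.

    The coefficient measured at the stated pH is divided by the anionic
    occupancy there: eps_on = eps7.4 * (1 + 10^(pKa - pH)).
    """
    if eps74 <= 0:
        raise ValueError("eps7.4 must be positive")
    return eps74 * (1.0 + 10.0 ** (pKa - pH))


def extinction_wards(A_native: float, A_denatured: float, eps_reference: float) -> float:
    """Ward's method: extinction via the alkali-denatured chromophore.

    Denaturation converts every chromophore to a common species of known
    extinction ``eps_reference``, so the concentration cancels and
    eps = eps_reference * A_native / A_denatured.
    """
    if A_denatured <= 0:
        raise ValueError("denatured absorbance must be positive")
    if A_native <= 0:
        raise ValueError("native absorbance must be positive")
    if eps_reference <= 0:
        raise ValueError("reference extinction must be positive")
    return eps_reference * A_native / A_denatured


def relative_quantum_yield(
    emission_sample: float,
    emission_reference: float,
    absorbance_sample: float,
    absorbance_reference: float,
    phi_reference: float = 0.60,
) -> float:
    """Fluorescence quantum yield relative to a reference (default EGFP, 0.60).

    Phi = Phi_ref * (I_sample / I_ref) * (A_ref / A_sample).  Absorbances
    should be optically thin (< 0.1); larger values trigger a warning, and a
    result above 1 is flagged as physically invalid.
    """
    if emission_reference <= 0 or absorbance_reference <= 0:
        raise ValueError("reference emission and absorbance must be positive")
    if absorbance_sample <= 0:
        raise ValueError("sample absorbance must be positive")
    import warnings

    if absorbance_sample > 0.1 or absorbance_reference > 0.1:
        warnings.warn(
            "absorbance above 0.1: inner-filter effects may bias the relative quantum yield"
        )
    phi = phi_reference * (emission_sample / emission_reference) * (
        absorbance_reference / absorbance_sample
    )
    if phi > 1:
        warnings.warn(f"computed quantum yield {phi:.3f} > 1 is physically invalid")
    return phi


def molecular_brightness(
    profiles: Iterable[SpectroscopicProfile], reference: str
) -> dict[str, int]:
    """Molecular brightness eps7.4 * phi, scaled to 100 for the reference.

    Returns integer values rounded half away from zero, keyed by construct
    name.
    """
    plist = list(profiles)
    by_name = {p.name: p for p in plist}
    if reference not in by_name:
        raise ValueError(f"reference {reference!r} not among the profiles")
    ref = by_name[reference]
    if ref.eps74 is None or ref.phi is None:
        raise ValueError("reference profile must have eps7.4 and phi")
    ref_b = ref.eps74 * ref.phi
    if ref_b == 0:
        raise ValueError("reference brightness is zero")
    out = {}
    for p in plist:
        if p.eps74 is None or p.phi is None:
            continue
        out[p.name] = round_half_away(100.0 * p.eps74 * p.phi / ref_b)
    return out


def percent_change(reference: float, new: float) -> int:
    """Signed integer percent change of ``new`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    if reference < 0:
        raise ValueError("reference value must be positive")
    return round_half_away(100.0 * (new - reference) / reference)


def profile_table(
    profiles: Iterable[SpectroscopicProfile], reference: str, pH: float = 7.4
) -> pd.DataFrame:
    """Derive the full characterization table from measured inputs.

    From each profile's (pKa, phi, eps7.4), computes eps_on by
    Henderson–Hasselbalch extrapolation (rounded to the nearest 10^3 for
    reporting, matching the convention of characterization tables) and the
    molecular brightness scaled to the reference construct.
    """
    plist = list(profiles)
    brightness = molecular_brightness(plist, reference)
    rows = []
    for p in plist:
        eon = extrapolate_eon(p.eps74, p.pKa, pH=pH) if p.eps74 and p.pKa is not None else None
        rows.append(
            {
                "name": p.name,
                "lambda_ex_nm": p.lambda_ex,
                "lambda_em_nm": p.lambda_em,
                "pKa": p.pKa,
                "phi": p.phi,
                "eps74_e3": round_half_away(p.eps74 / 1e3) if p.eps74 else None,
                "eps_on_e3": round_half_away(eon / 1e3) if eon else None,
                "brightness": brightness.get(p.name),
            }
        )
    return pd.DataFrame(rows)
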
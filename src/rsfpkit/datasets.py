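"""Published characterization inputs for the rsGreen series and EGFP.

Measured quantities for EGFP, rsGreen1, rsGreenF and their Enhancer-nanobody
fusions, as published for these constructs: peak wavelengths, pKa,
fluorescence quantum yield, and the apparent extinction coefficient at
pH 7.4.  These are the *inputs* of the characterization pipeline — the
derived quantities (deprotonated-state extinction, scaled molecular
brightness, percent changes) are computed from them by
:mod:`rsfpkit.spectroscopy`.

In-situ brightness values (average colony / transfected-cell fluorescence,
scaled to 100 for rsGreen1) are measured endpoints of the imaging assays and
feed the percent-change comparisons only.
"""

from __future__ import annotations

from .spectroscopy import SpectroscopicProfile

__all__ = [
    "published_profiles",
    "published_insitu_brightness",
    "REFERENCE_CONSTRUCT",
]

REFERENCE_CONSTRUCT = "rsGreen1"

_ROWS = [
    # name, lambda_ex, lambda_em, pKa, phi, eps74 (L/mol/cm)
    ("EGFP", 489.0, 509.0, 5.9, 0.60, 52e3),
    ("rsGreen1", 487.0, 508.0, 6.2, 0.46, 65e3),
    ("rsGreen1-Enhancer", 486.0, 505.0, 4.4, 0.47, 78e3),
    ("rsGreenF", 488.0, 510.0, 6.8, 0.42, 52e3),
    ("rsGreenF-Enhancer", 485.0, 506.0, 5.6, 0.37, 71e3),
]

# average brightness in situ, scaled to 100 for rsGreen1 (EGFP not determined)
_INSITU = {
    "colony_37C": {"rsGreen1": 100.0, "rsGreen1-Enhancer": 57.0, "rsGreenF": 82.0, "rsGreenF-Enhancer": 50.0},
    "hela": {"rsGreen1": 100.0, "rsGreen1-Enhancer": 69.0, "rsGreenF": 80.0, "rsGreenF-Enhancer": 51.0},
}


def published_profiles() -> list[SpectroscopicProfile]:
    """Measured spectroscopic inputs, one profile per construct."""
    return [
        SpectroscopicProfile(
            name=name, lambda_ex=lex, lambda_em=lem, pKa=pka, phi=phi, eps74=eps
        )
        for name, lex, lem, pka, phi, eps in _ROWS
    ]


def published_insitu_brightness(assay: str) -> dict[str, float]:
    """In-situ brightness by construct; ``assay`` is 'colony_37C' or 'hela'."""
    if assay not in _INSITU:
        raise ValueError(f"unknown assay {assay!r}; choose from {sorted(_INSITU)}")
    return dict(_INSITU[assay])
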
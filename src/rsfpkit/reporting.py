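"""Characterization-table reports and free-vs-fusion percent comparisons."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .spectroscopy import (
    SpectroscopicProfile,
    extrapolate_eon,
    molecular_brightness,
    percent_change,
    profile_table,
    round_half_away,
)

__all__ = [
    "read_profiles_csv",
    "characterization_report",
    "enhancer_comparison",
    "render_text_report",
]


def read_profiles_csv(path: str | Path) -> list[SpectroscopicProfile]:
    """Load measured profiles from a CSV with columns
    name, lambda_ex, lambda_em, pKa, phi, eps74."""
    table = pd.read_csv(path)
    required = {"name", "pKa", "phi", "eps74"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"profiles CSV is missing columns: {sorted(missing)}")
    profiles = []
    for _, row in table.iterrows():
        profiles.append(
            SpectroscopicProfile(
                name=str(row["name"]),
                lambda_ex=row.get("lambda_ex"),
                lambda_em=row.get("lambda_em"),
                pKa=float(row["pKa"]),
                phi=float(row["phi"]),
                eps74=float(row["eps74"]),
            )
        )
    return profiles


def characterization_report(
    profiles: Iterable[SpectroscopicProfile], reference: str
) -> pd.DataFrame:
    """Full derived characterization table (eps_on, scaled brightness)."""
    return profile_table(profiles, reference)


def enhancer_comparison(
    profiles: Iterable[SpectroscopicProfile],
    pairs: Sequence[tuple[str, str]],
    insitu: dict[str, dict[str, float]] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Percent changes of a fusion construct over its free protein.

    For each (free, fusion) pair: the increase of the deprotonated-state
    extinction coefficient (computed from eps7.4 and pKa, compared on the
    values rounded to 10^3 as reported), the increase of scaled molecular
    brightness (compared on the integer-scaled values), and — when in-situ
    assay tables are supplied — the change in measured cellular brightness.
    """
    plist = list(profiles)
    by_name = {p.name: p for p in plist}
    reference = reference or pairs[0][0]
    brightness = molecular_brightness(plist, reference)
    rows = []
    for free, fusion in pairs:
        pf, pu = by_name[free], by_name[fusion]
        eon_f = round_half_away(extrapolate_eon(pf.eps74, pf.pKa) / 1e3)
        eon_u = round_half_away(extrapolate_eon(pu.eps74, pu.pKa) / 1e3)
        row = {
            "free": free,
            "fusion": fusion,
            "eps_on_change_pct": percent_change(eon_f, eon_u),
            "brightness_change_pct": percent_change(brightness[free], brightness[fusion]),
        }
        if insitu:
            for assay, values in insitu.items():
                if free in values and fusion in values:
                    row[f"{assay}_change_pct"] = percent_change(values[free], values[fusion])
        rows.append(row)
    return pd.DataFrame(rows)


def render_text_report(table: pd.DataFrame, comparison: pd.DataFrame | None = None) -> str:
    """Human-readable characterization report."""
    lines = ["Spectroscopic characterization", "=" * 30, table.to_string(index=False)]
    if comparison is not None:
        lines += ["", "Fusion vs free protein", "-" * 30, comparison.to_string(index=False)]
    return "\n".join(lines) + "\n"
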
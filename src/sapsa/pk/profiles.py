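"""Concentration-time profiles and below-LLOQ preprocessing."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PKProfile", "preprocess_blq", "read_profiles_csv", "profiles_to_csv"]

SITES = ("systemic", "portal", "jugular")
ROUTES = ("iv_bolus", "oral")


@dataclass
class PKProfile:
    """One subject/site/route concentration-time series.

    ``concentrations`` keep the raw assay values; anything below ``lloq``
    is treated as censored by :func:`preprocess_blq`.  ``conc_unit`` is
    either ``nM`` or ``ng/mL``; converting between the two requires the
    molecular weight and is never guessed.
    """

    subject_id: str
    site: str
    route: str
    dose: float  # mg/kg
    times: np.ndarray  # h
    concentrations: np.ndarray
    lloq: float = 0.0
    conc_unit: str = "ng/mL"
    molecular_weight: float | None = None  # g/mol
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if len(self.times) and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.dose is None or self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.conc_unit not in ("nM", "ng/mL"):
            raise ValueError("conc_unit must be 'nM' or 'ng/mL'")

    @property
    def n_points(self) -> int:
        return len(self.times)

    def conc_as_ng_per_ml(self) -> np.ndarray:
        if self.conc_unit == "ng/mL":
            return self.concentrations
        if self.molecular_weight is None:
            raise ValueError("unit conversion nM -> ng/mL requires molecular_weight")
        return self.concentrations * self.molecular_weight / 1000.0


def preprocess_blq(profile: PKProfile, rule: str = "default") -> PKProfile:
    """Apply the below-LLOQ handling rule.

    ``default``: BLQ values before the first quantifiable point are set to
    0 (pre-absorption samples); embedded and trailing BLQ values are dropped
    with a note.  ``drop_all``: every BLQ point is dropped.  ``zero_all``:
    every BLQ value is set to 0 (useful for plotting, not for NCA).
    """
    blq = profile.concentrations < profile.lloq
    if blq.all():
        raise ValueError(f"profile {profile.subject_id}: all points below LLOQ")
    if not blq.any():
        return profile

    notes = list(profile.notes)
    if rule == "default":
        first_q = int(np.argmax(~blq))
        keep = np.ones(profile.n_points, dtype=bool)
        conc = profile.concentrations.copy()
        for k in np.flatnonzero(blq):
            if k < first_q:
                conc[k] = 0.0
                notes.append(f"t={profile.times[k]} h: leading BLQ set to 0")
            else:
                keep[k] = False
                notes.append(f"t={profile.times[k]} h: BLQ dropped")
        return replace(
            profile,
            times=profile.times[keep],
            concentrations=conc[keep],
            notes=notes,
        )
    if rule == "drop_all":
        keep = ~blq
        notes.append(f"dropped {int(blq.sum())} BLQ points")
        return replace(
            profile,
            times=profile.times[keep],
            concentrations=profile.concentrations[keep],
            notes=notes,
        )
    if rule == "zero_all":
        conc = profile.concentrations.copy()
        conc[blq] = 0.0
        notes.append(f"zeroed {int(blq.sum())} BLQ points")
        return replace(profile, concentrations=conc, notes=notes)
    raise ValueError(f"unknown BLQ rule {rule!r}")


CSV_COLUMNS = [
    "subject_id",
    "site",
    "route",
    "dose_mg_per_kg",
    "time_h",
    "conc",
    "conc_unit",
    "lloq",
]


def read_profiles_csv(path: str | Path) -> list[PKProfile]:
    """Read the tabular profile dialect (one row per sample).

    Columns: subject_id, site, route, dose_mg_per_kg, time_h, conc,
    conc_unit, lloq, and optionally molecular_weight.  One profile per
    (subject_id, site, route) group, rows sorted by time.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns: {missing}")
    profiles = []
    for (subject, site, route), group in df.groupby(
        ["subject_id", "site", "route"], sort=False
    ):
        group = group.sort_values("time_h")
        mw = None
        if "molecular_weight" in group.columns and group["molecular_weight"].notna().any():
            mw = float(group["molecular_weight"].iloc[0])
        profiles.append(
            PKProfile(
                subject_id=str(subject),
                site=str(site),
                route=str(route),
                dose=float(group["dose_mg_per_kg"].iloc[0]),
                times=group["time_h"].to_numpy(),
                concentrations=group["conc"].to_numpy(),
                lloq=float(group["lloq"].iloc[0]),
                conc_unit=str(group["conc_unit"].iloc[0]),
                molecular_weight=mw,
            )
        )
    return profiles


def profiles_to_csv(profiles: list[PKProfile], path: str | Path) -> None:
    """Write profiles in the same dialect :func:`read_profiles_csv` reads."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "site": p.site,
                    "route": p.route,
                    "dose_mg_per_kg": p.dose,
                    "time_h": t,
                    "conc": c,
                    "conc_unit": p.conc_unit,
                    "lloq": p.lloq,
                    "molecular_weight": p.molecular_weight,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS + ["molecular_weight"]).to_csv(
        path, index=False
    )
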
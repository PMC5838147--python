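"""Synthetic pharmacokinetic profiles for parameter-recovery testing.

Closed-form one-compartment kinetics with first-order absorption and a
hepatic extraction ratio ``EH``:

* i.v. bolus:   ``C(t) = (dose/V) * exp(-k t)`` with ``k = CL/V``.
* oral, systemic (jugular): the standard one-compartment oral solution
  with bioavailability ``F = f_abs * (1 - EH)``.
* oral, portal: systemic concentration plus the absorption flux divided by
  portal blood flow, ``C_p = C_sys + ka * f_abs * dose * exp(-ka t) / Q_pv``
  — the well-stirred-consistent additive-flux approximation.  This is a
  test harness, not a physiological claim.

Analytic identities used by the tests:
``AUC_inf(jugular) = f_abs * (1-EH) * dose / CL`` and
``AUC_inf(portal) - AUC_inf(jugular) = f_abs * dose / Q_pv``.  When
elimination is purely hepatic and portal flow equals hepatic flow
(``CL = EH * Q_pv``, the default), the portal/jugular AUC ratio identifies
EH exactly: ``1 - AUC_j/AUC_p = EH``.

Noise is multiplicative log-normal at a given CV; values censored by the
LLOQ are reported as 0 (the assay's "below LLOQ").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import PKProfile

__all__ = ["PKSimConfig", "simulate_iv", "simulate_oral_paired", "ORAL_SCHEDULE", "IV_SCHEDULE"]

#: Rodent sampling schedules (hours): 0.08 h is the i.v.-only first sample.
IV_SCHEDULE = (0.08, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 24.0)
ORAL_SCHEDULE = (0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 24.0)

#: Reference portal/hepatic blood flow, mL/min/kg (rodent-scale).
Q_PV_DEFAULT = 90.0


@dataclass
class PKSimConfig:
    """One-compartment simulation settings (doses mg/kg, flows mL/min/kg).

    Defaults describe a high-extraction compound: EH = 0.77 with purely
    hepatic elimination, so CL = EH * Q_pv = 69.3 mL/min/kg; V = 2.8 L/kg;
    ka = 1.0 /h (first-order absorption of a suspension dose); complete
    absorption (f_abs = 1); 3 mg/kg dose on the 0.25-24 h oral schedule.
    """

    dose: float = 3.0
    V: float = 2.8  # L/kg
    CL: float | None = None  # mL/min/kg; default EH * Q_pv (hepatic-only)
    ka: float = 1.0  # 1/h
    f_abs: float = 1.0
    EH: float = 0.77
    Q_pv: float = Q_PV_DEFAULT  # mL/min/kg
    schedule: tuple[float, ...] = ORAL_SCHEDULE
    noise_cv: float = 0.0
    lloq: float = 0.4  # ng/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.CL is None:
            self.CL = self.EH * self.Q_pv
        for name in ("dose", "V", "CL", "ka", "Q_pv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("f_abs", "EH"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def k_elim(self) -> float:
        """Elimination rate constant, 1/h."""
        return self.cl_L_per_h / self.V

    @property
    def cl_L_per_h(self) -> float:
        return self.CL * 60.0 / 1000.0

    @property
    def q_pv_L_per_h(self) -> float:
        return self.Q_pv * 60.0 / 1000.0


def _to_ng_per_ml(c_mg_per_L: np.ndarray) -> np.ndarray:
    return c_mg_per_L * 1000.0


def _apply_noise_and_lloq(
    conc_ng: np.ndarray, config: PKSimConfig, rng: np.random.Generator
) -> np.ndarray:
    c = conc_ng.copy()
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + config.noise_cv**2))
        c = c * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=c.shape)
    c[c < config.lloq] = 0.0
    return c


def simulate_iv(config: PKSimConfig, subject_id: str = "sim-iv") -> PKProfile:
    """Mono-exponential i.v. bolus profile in ng/mL on ``config.schedule``."""
    t = np.asarray(config.schedule, dtype=float)
    c_mg_L = config.dose / config.V * np.exp(-config.k_elim * t)
    rng = np.random.default_rng(config.seed)
    conc = _apply_noise_and_lloq(_to_ng_per_ml(c_mg_L), config, rng)
    return PKProfile(
        subject_id=subject_id,
        site="systemic",
        route="iv_bolus",
        dose=config.dose,
        times=t,
        concentrations=conc,
        lloq=config.lloq,
        conc_unit="ng/mL",
    )


def _oral_systemic_mg_L(t: np.ndarray, config: PKSimConfig) -> np.ndarray:
    F = config.f_abs * (1.0 - config.EH)
    ka, k, V = config.ka, config.k_elim, config.V
    if abs(ka - k) < 1e-9:  # flip-flop degenerate limit
        return F * config.dose * ka / V * t * np.exp(-ka * t)
    return (
        F * config.dose * ka / (V * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))
    )


def simulate_oral_paired(
    config: PKSimConfig, subject_id: str = "sim-oral"
) -> tuple[PKProfile, PKProfile]:
    """(portal, jugular) oral profiles with simultaneous sampling.

    Shared noise seed but independent draws per site; both sites share the
    schedule, dose and LLOQ, mirroring a dual-cannulation experiment.
    """
    t = np.asarray(config.schedule, dtype=float)
    sys_mg_L = _oral_systemic_mg_L(t, config)
    flux_mg_L = (
        config.ka * config.f_abs * config.dose * np.exp(-config.ka * t)
        / config.q_pv_L_per_h
    )
    rng = np.random.default_rng(config.seed)
    portal = _apply_noise_and_lloq(_to_ng_per_ml(sys_mg_L + flux_mg_L), config, rng)
    jugular = _apply_noise_and_lloq(_to_ng_per_ml(sys_mg_L), config, rng)

    common = dict(
        route="oral",
        dose=config.dose,
        times=t,
        lloq=config.lloq,
        conc_unit="ng/mL",
        subject_id=subject_id,
    )
    return (
        PKProfile(site="portal", concentrations=portal, **common),
        PKProfile(site="jugular", concentrations=jugular, **common),
    )
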
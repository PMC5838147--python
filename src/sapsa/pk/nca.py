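"""Non-compartmental pharmacokinetic analysis.

Model-free PK parameters from a concentration-time profile: AUC by
trapezoidal integration (linear or linear-up/log-down), terminal slope
``lambda_z`` by log-linear regression over the best terminal window, and
the derived quantities C_max, T_max, AUC_inf, t_1/2, MRT, and — for an
i.v. bolus — CL and V_ss.  The hepatic first-pass analysis compares AUCs
sampled simultaneously in the portal and jugular veins after an oral dose:
``first_pass_% = 100 * (1 - AUC_jugular / AUC_portal)``.

Usage follows the model/results convention::

    result = NCA(profile).fit()
    print(result.summary())
    fp = FirstPass(portal_profile, jugular_profile).fit()
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .profiles import PKProfile, preprocess_blq

__all__ = [
    "auc",
    "aumc",
    "fit_lambda_z",
    "LambdaZFit",
    "NCA",
    "NCAResult",
    "nca",
    "oral_bioavailability",
    "FirstPass",
    "FirstPassResult",
    "first_pass",
    "first_pass_from_aucs",
]

#: Reference hepatic blood flow used to contextualize hepatic extraction
#: (mouse/rat-scale default, mL/min/kg).
HEPATIC_BLOOD_FLOW = 90.0


def _segments(times: np.ndarray, conc: np.ndarray, method: str):
    if len(times) < 2:
        raise ValueError("AUC needs at least 2 quantifiable points")
    if method not in ("linear", "linear_up_log_down"):
        raise ValueError(f"unknown AUC method {method!r}")
    for k in range(len(times) - 1):
        yield times[k], times[k + 1], conc[k], conc[k + 1]


def auc(times: np.ndarray, conc: np.ndarray, method: str = "linear_up_log_down") -> float:
    """Trapezoidal AUC.  With ``linear_up_log_down``, declining segments with
    both concentrations positive use the log-trapezoid
    ``(C1 - C2) / ln(C1 / C2) * dt`` (exact for exponential decay)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    total = 0.0
    for t1, t2, c1, c2 in _segments(times, conc, method):
        dt = t2 - t1
        if method == "linear_up_log_down" and c1 > c2 > 0:
            total += (c1 - c2) / np.log(c1 / c2) * dt
        else:
            total += 0.5 * (c1 + c2) * dt
    return float(total)


def aumc(times: np.ndarray, conc: np.ndarray, method: str = "linear_up_log_down") -> float:
    """First-moment area (integral of t*C), matching the AUC segment rule."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    total = 0.0
    for t1, t2, c1, c2 in _segments(times, conc, method):
        dt = t2 - t1
        if method == "linear_up_log_down" and c1 > c2 > 0:
            k = np.log(c1 / c2) / dt
            total += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
        else:
            total += 0.5 * (t1 * c1 + t2 * c2) * dt
    return float(total)


@dataclass
class LambdaZFit:
    """Terminal log-linear regression result (lambda_z in 1/h)."""

    lambda_z: float
    n_points: int
    r_squared: float
    adj_r_squared: float
    reliable: bool


def fit_lambda_z(profile: PKProfile, min_points: int = 3) -> LambdaZFit:
    """Terminal slope by log-linear least squares.

    Candidate windows run from each start index to the last quantifiable
    point; the observed T_max point is excluded.  The window with the best
    adjusted r-squared wins (ties go to the longer window).  A flat or
    rising tail yields ``lambda_z <= 0`` flagged unreliable rather than an
    error.
    """
    t = profile.times
    c = profile.concentrations
    positive = c > 0
    if positive.sum() < min_points:
        raise ValueError(f"need at least {min_points} positive terminal points")
    i_max = int(np.argmax(c))

    candidates = []
    idx_all = np.flatnonzero(positive)
    idx_all = idx_all[idx_all > i_max]  # strictly after tmax
    for start_pos in range(len(idx_all) - min_points + 1):
        idx = idx_all[start_pos:]
        n = len(idx)
        x, y = t[idx], np.log(c[idx])
        if np.ptp(y) == 0.0:  # flat window: slope 0, r^2 undefined
            candidates.append(LambdaZFit(0.0, n, float("nan"), -np.inf, False))
            continue
        fit = stats.linregress(x, y)
        r2 = fit.rvalue**2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        lam = -fit.slope
        candidates.append(
            LambdaZFit(float(lam), n, float(r2), float(adj), bool(lam > 0 and r2 >= 0.8))
        )
    if not candidates:
        raise ValueError("not enough terminal points after T_max for lambda_z")
    best = max(candidates, key=lambda f: (f.adj_r_squared, f.n_points))
    return best


@dataclass
class NCAResult:
    """Non-compartmental parameters for one profile.

    AUCs are in ``conc_unit * h``; CL in mL/min/kg and V_ss in L/kg are
    reported for i.v. bolus profiles only.  ``auc_dose_normalized`` divides
    AUC_inf by the dose in mg/kg.
    """

    subject_id: str
    route: str
    dose: float
    conc_unit: str
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    auc_dose_normalized: float
    lambda_z: float
    t_half: float
    mrt: float
    cl: float | None
    vss: float | None
    n_lambda_points: int
    r_squared: float
    lambda_z_reliable: bool
    notes: tuple[str, ...] = ()

    def summary(self) -> str:
        def fmt(v, unit=""):
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                return "      --"
            return f"{v:8.3g} {unit}"

        lines = [
            f"Non-compartmental analysis — subject {self.subject_id} ({self.route})",
            "=" * 58,
            f"  dose                 : {self.dose:g} mg/kg",
            f"  Cmax                 : {fmt(self.cmax, self.conc_unit)}",
            f"  Tmax                 : {fmt(self.tmax, 'h')}",
            f"  AUC_last             : {fmt(self.auc_last, self.conc_unit + '·h')}",
            f"  AUC_inf              : {fmt(self.auc_inf, self.conc_unit + '·h')}",
            f"  AUC_inf (d.n.)       : {fmt(self.auc_dose_normalized)}",
            f"  lambda_z             : {fmt(self.lambda_z, '1/h')}"
            + ("" if self.lambda_z_reliable else "  [unreliable]"),
            f"  t_1/2 (terminal)     : {fmt(self.t_half, 'h')}",
            f"  MRT                  : {fmt(self.mrt, 'h')}",
        ]
        if self.route == "iv_bolus":
            lines.append(f"  CL                   : {fmt(self.cl, 'mL/min/kg')}")
            lines.append(f"  Vss                  : {fmt(self.vss, 'L/kg')}")
        for note in self.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)


class NCA:
    """Non-compartmental model for one :class:`PKProfile`.

    Parameters
    ----------
    profile : the concentration-time series (raw; BLQ handling is applied).
    method : AUC rule, ``linear_up_log_down`` (default) or ``linear``.
    blq_rule : rule passed to :func:`preprocess_blq`.
    min_lambda_points : minimum points in the terminal regression window.
    """

    def __init__(
        self,
        profile: PKProfile,
        method: str = "linear_up_log_down",
        blq_rule: str = "default",
        min_lambda_points: int = 3,
    ):
        self.raw_profile = profile
        self.method = method
        self.blq_rule = blq_rule
        self.min_lambda_points = min_lambda_points

    def _prepared(self) -> tuple[PKProfile, list[str]]:
        """BLQ handling plus the time-zero anchor.

        Oral profiles get C(0) = 0 at the dose time; i.v. bolus profiles get
        a back-extrapolated C(0) from the log-linear line through the first
        two positive points (standard bolus handling).
        """
        profile = preprocess_blq(self.raw_profile, self.blq_rule)
        notes = list(profile.notes)
        t, c = profile.times, profile.concentrations
        if len(t) and t[0] > 0:
            if profile.route == "oral":
                t = np.concatenate([[0.0], t])
                c = np.concatenate([[0.0], c])
            else:  # iv bolus back-extrapolation
                pos = np.flatnonzero(c > 0)
                if len(pos) >= 2 and c[pos[0]] > c[pos[1]]:
                    i1, i2 = pos[0], pos[1]
                    slope = (np.log(c[i2]) - np.log(c[i1])) / (t[i2] - t[i1])
                    c0 = float(np.exp(np.log(c[i1]) - slope * t[i1]))
                else:
                    c0 = float(c[pos[0]]) if len(pos) else 0.0
                notes.append(f"C0 back-extrapolated to {c0:.4g} {profile.conc_unit}")
                t = np.concatenate([[0.0], t])
                c = np.concatenate([[c0], c])
            profile = replace(profile, times=t, concentrations=c, notes=notes)
        return profile, notes

    def fit(self) -> NCAResult:
        profile, notes = self._prepared()
        t, c = profile.times, profile.concentrations
        if (c > 0).sum() < 2:
            raise ValueError("NCA needs at least 2 quantifiable points")

        i_max = int(np.argmax(c))
        cmax, tmax = float(c[i_max]), float(t[i_max])
        auc_last = auc(t, c, self.method)
        aumc_last = aumc(t, c, self.method)

        lam = fit_lambda_z(profile, self.min_lambda_points)
        c_last = float(c[c > 0][-1])
        t_last = float(t[c > 0][-1])
        if lam.reliable and lam.lambda_z > 0:
            auc_inf = auc_last + c_last / lam.lambda_z
            aumc_inf = aumc_last + c_last * t_last / lam.lambda_z + c_last / lam.lambda_z**2
            t_half = float(np.log(2.0) / lam.lambda_z)
        else:
            auc_inf, aumc_inf, t_half = float("nan"), float("nan"), float("nan")
            notes.append("terminal slope unreliable; AUC_inf not extrapolated")

        mrt = aumc_inf / auc_inf if np.isfinite(auc_inf) and auc_inf > 0 else float("nan")

        cl = vss = None
        if profile.route == "iv_bolus" and np.isfinite(auc_inf) and auc_inf > 0:
            if profile.conc_unit == "ng/mL":
                auc_mass = auc_inf  # ng/mL·h == ug/L·h
            else:  # nM·h -> ng/mL·h needs MW
                if profile.molecular_weight is None:
                    raise ValueError(
                        "CL in mL/min/kg from molar concentrations requires molecular_weight"
                    )
                auc_mass = auc_inf * profile.molecular_weight / 1000.0
            # dose mg/kg = 1e6 ng/kg; CL = dose/AUC in mL/h/kg, then per minute
            cl = float(profile.dose * 1e6 / auc_mass / 60.0)
            vss = float(cl * 60.0 / 1000.0 * mrt)  # L/kg

        return NCAResult(
            subject_id=profile.subject_id,
            route=profile.route,
            dose=profile.dose,
            conc_unit=profile.conc_unit,
            cmax=cmax,
            tmax=tmax,
            auc_last=float(auc_last),
            auc_inf=float(auc_inf),
            auc_dose_normalized=float(auc_inf / profile.dose),
            lambda_z=lam.lambda_z,
            t_half=t_half,
            mrt=float(mrt),
            cl=cl,
            vss=vss,
            n_lambda_points=lam.n_points,
            r_squared=lam.r_squared,
            lambda_z_reliable=lam.reliable,
            notes=tuple(notes),
        )


def nca(profile: PKProfile, **kwargs) -> NCAResult:
    """Convenience wrapper: ``NCA(profile, **kwargs).fit()``."""
    return NCA(profile, **kwargs).fit()


def oral_bioavailability(oral, iv) -> float:
    """Absolute oral bioavailability in percent.

    ``100 * AUC_dn(oral) / AUC_dn(iv)`` from dose-normalized AUCs.  Accepts
    :class:`NCAResult` objects or bare dose-normalized AUC numbers, so
    published mean AUC values can be plugged in directly.
    """
    auc_oral = getattr(oral, "auc_dose_normalized", oral)
    auc_iv = getattr(iv, "auc_dose_normalized", iv)
    if auc_iv == 0:
        raise ZeroDivisionError("i.v. dose-normalized AUC is zero")
    return 100.0 * float(auc_oral) / float(auc_iv)


@dataclass
class FirstPassResult:
    """Portal-vs-jugular AUC comparison after an oral dose.

    ``first_pass_pct`` is the percentage of absorbed drug removed by the
    liver before reaching the systemic circulation.  When the jugular AUC
    exceeds the portal AUC the (negative) value is kept and flagged rather
    than clipped.
    """

    auc_portal: float
    auc_jugular: float
    first_pass_pct: float
    hepatic_extraction_flag: str
    negative_extraction: bool = False
    t_last_common: float | None = None

    def summary(self) -> str:
        lines = [
            "Hepatic first-pass analysis (oral dose, simultaneous sampling)",
            "=" * 62,
            f"  AUC portal vein   : {self.auc_portal:10.4g}",
            f"  AUC jugular vein  : {self.auc_jugular:10.4g}",
            f"  liver first pass  : {self.first_pass_pct:10.1f} %",
            f"  {self.hepatic_extraction_flag}",
        ]
        if self.negative_extraction:
            lines.append("  WARNING: jugular AUC exceeds portal AUC (negative extraction)")
        return "\n".join(lines)


def _extraction_flag(first_pass_pct: float, hepatic_blood_flow: float) -> str:
    eh = first_pass_pct / 100.0
    implied_cl = eh * hepatic_blood_flow
    if eh >= 0.7:
        cls = "high"
    elif eh >= 0.3:
        cls = "intermediate"
    else:
        cls = "low"
    return (
        f"implied hepatic CL {implied_cl:.1f} vs hepatic blood flow "
        f"{hepatic_blood_flow:.0f} mL/min/kg (E_H={eh:.2f}, {cls} extraction)"
    )


def first_pass_from_aucs(
    auc_portal: float,
    auc_jugular: float,
    hepatic_blood_flow: float = HEPATIC_BLOOD_FLOW,
) -> FirstPassResult:
    """First-pass summary from already-computed (e.g. published) AUCs."""
    if auc_portal <= 0:
        raise ValueError("portal AUC must be positive")
    pct = 100.0 * (1.0 - auc_jugular / auc_portal)
    return FirstPassResult(
        auc_portal=float(auc_portal),
        auc_jugular=float(auc_jugular),
        first_pass_pct=float(pct),
        hepatic_extraction_flag=_extraction_flag(pct, hepatic_blood_flow),
        negative_extraction=auc_jugular > auc_portal,
    )


class FirstPass:
    """First-pass model from paired portal/jugular oral profiles.

    Both profiles must come from the same subject and dose with
    simultaneous sampling.  AUC_last is computed over the common
    quantifiable time window (no terminal extrapolation), then
    ``first_pass_pct = 100 * (1 - AUC_jugular / AUC_portal)``.
    """

    def __init__(
        self,
        portal: PKProfile,
        jugular: PKProfile,
        method: str = "linear_up_log_down",
        blq_rule: str = "default",
        hepatic_blood_flow: float = HEPATIC_BLOOD_FLOW,
    ):
        if portal.route != "oral" or jugular.route != "oral":
            raise ValueError("first-pass analysis requires oral-route profiles")
        if portal.subject_id != jugular.subject_id:
            raise ValueError("portal and jugular profiles must share the subject")
        if portal.dose != jugular.dose:
            raise ValueError("portal and jugular profiles must share the dose")
        self.portal = portal
        self.jugular = jugular
        self.method = method
        self.blq_rule = blq_rule
        self.hepatic_blood_flow = hepatic_blood_flow

    def _windowed(self, profile: PKProfile, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        p = preprocess_blq(profile, self.blq_rule)
        keep = p.times <= t_end + 1e-12
        t, c = p.times[keep], p.concentrations[keep]
        if len(t) == 0 or t[0] > 0:
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[0.0], c])
        return t, c

    def fit(self) -> FirstPassResult:
        p = preprocess_blq(self.portal, self.blq_rule)
        j = preprocess_blq(self.jugular, self.blq_rule)
        t_end = float(min(p.times[-1], j.times[-1]))
        tp, cp = self._windowed(self.portal, t_end)
        tj, cj = self._windowed(self.jugular, t_end)
        auc_p = auc(tp, cp, self.method)
        auc_j = auc(tj, cj, self.method)
        result = first_pass_from_aucs(auc_p, auc_j, self.hepatic_blood_flow)
        result.t_last_common = t_end
        return result


def first_pass(portal: PKProfile, jugular: PKProfile, **kwargs) -> FirstPassResult:
    """Convenience wrapper: ``FirstPass(portal, jugular, **kwargs).fit()``."""
    return FirstPass(portal, jugular, **kwargs).fit()
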
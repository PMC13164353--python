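"""Enzyme-inhibition analysis: activity, Michaelis-Menten fits, mode, Ki, IC50.

Workflow for a candidate inhibitor:

1. endpoint inhibition percentages from paired blank/sample absorbances,
   ``100 * [(a1 - a2) - (b1 - b2)] / (a1 - a2)``;
2. initial-rate series over substrate concentrations at several inhibitor
   concentrations, fitted either by the double-reciprocal (Lineweaver-Burk)
   linearization or by direct nonlinear Michaelis-Menten regression;
3. inhibition-mode classification from the trajectories of apparent Km and
   Vmax versus inhibitor concentration (competitive: Km rises, Vmax flat;
   non-competitive: Vmax falls, Km flat; mixed: both move);
4. Ki from the secondary plot: slopes of the reciprocal lines regressed on
   inhibitor concentration, with the X-intercept at -Ki;
5. IC50 from a four-parameter logistic fit of inhibition versus
   inhibitor concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight
from scipy import optimize

__all__ = [
    "AbsorbanceAssay",
    "inhibition_percent",
    "KineticSeries",
    "KineticFit",
    "fit_series",
    "InhibitionVerdict",
    "classify",
    "estimate_ki",
    "DoseResponse",
    "fit_ic50",
    "mg_per_ml_to_micromolar",
]


# ---------------------------------------------------------------- endpoint


@dataclass(frozen=True)
class AbsorbanceAssay:
    """Blank (a1, a2) and sample (b1, b2) absorbances before/after reaction."""

    a1: float
    a2: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.b1, self.b2) < 0:
            raise ValueError("absorbances must be non-negative")
        if self.a1 <= self.a2:
            raise ValueError(
                "blank absorbance must decrease (a1 > a2); otherwise the "
                "uninhibited reaction did not proceed and % inhibition is undefined"
            )


def inhibition_percent(assay: AbsorbanceAssay) -> float:
    """Endpoint inhibition: 100 * [(a1-a2) - (b1-b2)] / (a1-a2).

    Values below 0 (apparent activation) are returned as-is with a warning.
    """
    blank = assay.a1 - assay.a2
    value = 100.0 * (blank - (assay.b1 - assay.b2)) / blank
    if value < -1e-9:
        warnings.warn(
            f"negative inhibition ({value:.2f}%): sample reacted faster than blank",
            stacklevel=2,
        )
    return value


# ------------------------------------------------------------ rate series


@dataclass
class KineticSeries:
    """Initial rates over substrate concentrations at one inhibitor level."""

    inhibitor_conc: float  # uM
    substrate_conc: np.ndarray  # mM
    rates: np.ndarray  # e.g. AU/min

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.inhibitor_conc < 0:
            raise ValueError("inhibitor concentration must be >= 0")
        if self.substrate_conc.shape != self.rates.shape:
            raise ValueError("substrate and rate arrays differ in length")
        if (self.substrate_conc <= 0).any() or (self.rates <= 0).any():
            raise ValueError("substrate concentrations and rates must be positive")
        if np.unique(self.substrate_conc).size < 3:
            raise ValueError("need at least 3 distinct substrate concentrations")


@dataclass
class KineticFit:
    """Vmax/Km of one series with standard errors and reciprocal-plot geometry."""

    inhibitor_conc: float
    vmax: float
    km: float
    se_vmax: float
    se_km: float
    method: str
    r_squared: float
    slope: float = field(init=False)  # Km/Vmax, the Lineweaver-Burk slope
    y_intercept: float = field(init=False)  # 1/Vmax
    x_intercept: float = field(init=False)  # -1/Km

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError(
                f"fit failed at [I]={self.inhibitor_conc}: "
                f"non-positive Vmax={self.vmax:.4g} or Km={self.km:.4g}"
            )
        self.slope = self.km / self.vmax
        self.y_intercept = 1.0 / self.vmax
        self.x_intercept = -1.0 / self.km


def _michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def fit_series(series: KineticSeries, method: str = "reciprocal") -> KineticFit:
    """Fit one rate series.

    ``reciprocal``: unweighted OLS of 1/v on 1/[S] (the Lineweaver-Burk
    line); parameter standard errors propagate from the regression
    covariance by the delta method.  ``nls``: direct nonlinear
    Michaelis-Menten least squares (lower variance under multiplicative
    rate noise; the standard cross-check for the linearization).
    """
    s, v = series.substrate_conc, series.rates
    if method == "reciprocal":
        x, y = 1.0 / s, 1.0 / v
        X = np.column_stack([np.ones_like(x), x])
        coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercept, slope = coef
        if intercept <= 0 or slope <= 0:
            raise ValueError(
                f"reciprocal fit at [I]={series.inhibitor_conc}: non-positive "
                "intercept or slope; Vmax/Km are not estimable from these rates"
            )
        resid = y - X @ coef
        dof = max(len(y) - 2, 1)
        cov = np.linalg.inv(X.T @ X) * float(resid @ resid) / dof
        vmax, km = 1.0 / intercept, slope / intercept
        # delta method: vmax = 1/i, km = s/i
        j = np.array([[-1.0 / intercept**2, 0.0], [-slope / intercept**2, 1.0 / intercept]])
        pcov = j @ cov @ j.T
        se_vmax, se_km = np.sqrt(np.diag(pcov))
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    elif method == "nls":
        p0 = [float(v.max()) * 1.2, float(np.median(s))]
        popt, pcov = optimize.curve_fit(_michaelis_menten, s, v, p0=p0, maxfev=10000)
        vmax, km = popt
        se_vmax, se_km = np.sqrt(np.diag(pcov))
        resid = v - _michaelis_menten(s, *popt)
        ss_tot = float(((v - v.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r} (use 'reciprocal' or 'nls')")
    return KineticFit(
        inhibitor_conc=series.inhibitor_conc,
        vmax=float(vmax),
        km=float(km),
        se_vmax=float(se_vmax),
        se_km=float(se_km),
        method=method,
        r_squared=float(r2),
    )


# ----------------------------------------------------------- mode & Ki


@dataclass
class InhibitionVerdict:
    """Assigned inhibition mode with Ki and the Km/Vmax trajectory evidence."""

    mode: str  # competitive | non-competitive | mixed | none
    ki: float | None
    evidence: list[dict]
    diagnostic: str = ""


def _shift_significant(delta: float, se: float, rel: float, tol: float, z: float) -> bool:
    return abs(rel) > tol and abs(delta) > z * se


def classify(
    fits: list[KineticFit],
    tolerance: float = 0.10,
    z: float = 2.0,
) -> InhibitionVerdict:
    """Assign the inhibition mode from Km/Vmax trajectories.

    ``fits`` must cover >= 2 inhibitor concentrations including 0; the
    highest concentration (largest contrast) is compared against the
    zero-inhibitor baseline.  A parameter counts as shifted only when its
    relative change exceeds ``tolerance`` *and* the absolute change
    exceeds ``z`` combined standard errors — the SE gate keeps weakly
    identified parameters (e.g. Vmax when apparent Km grows past the
    substrate range) from triggering spurious shifts.
    """
    fits = sorted(fits, key=lambda f: f.inhibitor_conc)
    if len(fits) < 2 or fits[0].inhibitor_conc != 0:
        raise ValueError(
            "classification needs fits at >= 2 inhibitor concentrations including 0"
        )
    if len({f.inhibitor_conc for f in fits}) < len(fits):
        raise ValueError("duplicate inhibitor concentrations give no contrast")
    base, top = fits[0], fits[-1]
    evidence = [
        {
            "inhibitor_conc": f.inhibitor_conc,
            "km": f.km,
            "vmax": f.vmax,
            "km_ratio": f.km / base.km,
            "vmax_ratio": f.vmax / base.vmax,
        }
        for f in fits
    ]
    dk_rel = top.km / base.km - 1.0
    dv_rel = 1.0 - top.vmax / base.vmax
    km_moves = _shift_significant(
        top.km - base.km, float(np.hypot(base.se_km, top.se_km)), dk_rel, tolerance, z
    )
    vmax_moves = _shift_significant(
        top.vmax - base.vmax, float(np.hypot(base.se_vmax, top.se_vmax)), dv_rel, tolerance, z
    )
    km_up = km_moves and dk_rel > 0
    km_down = km_moves and dk_rel < 0
    vmax_down = vmax_moves and dv_rel > 0

    if km_down:
        mode, diag = "none", (
            f"apparent Km decreased ({dk_rel:+.1%}); inconsistent with "
            "competitive/non-competitive/mixed trajectories"
        )
    elif km_up and vmax_down:
        mode, diag = "mixed", "both Km and Vmax shifted beyond tolerance"
    elif km_up:
        mode, diag = "competitive", "Km increased at constant Vmax"
    elif vmax_down:
        mode, diag = "non-competitive", "Vmax decreased at constant Km"
    else:
        mode, diag = "none", "no significant Km or Vmax trajectory"

    ki = None
    if mode != "none":
        try:
            ki = estimate_ki(fits)
        except ValueError as exc:
            diag += f"; Ki not estimable ({exc})"
    return InhibitionVerdict(mode=mode, ki=ki, evidence=evidence, diagnostic=diag)


def estimate_ki(fits: list[KineticFit]) -> float:
    """Ki from the secondary plot of Lineweaver-Burk slopes versus [I].

    The reciprocal-line slope Km_app/Vmax_app grows linearly in inhibitor
    concentration for competitive, non-competitive and mixed inhibition;
    the X-intercept of that line sits at -Ki.
    """
    fits = sorted(fits, key=lambda f: f.inhibitor_conc)
    conc = np.array([f.inhibitor_conc for f in fits])
    slopes = np.array([f.slope for f in fits])
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct inhibitor concentrations")
    b, a = np.polyfit(conc, slopes, 1)
    if b <= 0:
        raise ValueError("secondary-plot slope is not positive; no inhibition trend")
    ki = a / b
    if ki <= 0:
        raise ValueError("secondary-plot X-intercept is non-negative")
    return float(ki)


# ------------------------------------------------------------------ IC50


@dataclass
class DoseResponse:
    """Four-parameter-logistic dose-response fit."""

    conc: np.ndarray
    inhibition: np.ndarray
    bottom: float
    top: float
    ic50: float
    hill: float
    in_span: bool
    warning: str | None = None

    def predict(self, conc) -> np.ndarray:
        return _four_pl(np.asarray(conc, dtype=float), self.bottom, self.top, self.ic50, self.hill)


def _four_pl(c, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)


def fit_ic50(conc, inhibition) -> DoseResponse:
    """Least-squares 4PL fit; IC50 is the half-way concentration parameter.

    Requires >= 5 positive concentrations.  Inhibition values outside
    (-20, 120)% and an IC50 outside the measured span are flagged with
    warnings rather than rejected.
    """
    conc = np.asarray(conc, dtype=float)
    inhibition = np.asarray(inhibition, dtype=float)
    if conc.shape != inhibition.shape or np.unique(conc).size < 5:
        raise ValueError("need >= 5 distinct concentrations spanning the transition")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    warning = None
    if ((inhibition < -20) | (inhibition > 120)).any():
        warning = "inhibition values outside the plausible (-20, 120)% range"
        warnings.warn(warning, stacklevel=2)
    p0 = [
        float(inhibition.min()),
        float(inhibition.max()),
        float(np.exp(np.interp(
            (inhibition.min() + inhibition.max()) / 2.0,
            inhibition[np.argsort(inhibition)],
            np.log(conc)[np.argsort(inhibition)],
        ))),
        1.0,
    ]
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, conc, inhibition, p0=p0,
            bounds=([-np.inf, -np.inf, conc.min() / 1e3, 0.05],
                    [np.inf, np.inf, conc.max() * 1e3, 20.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, ic50, hill = (float(p) for p in popt)
    in_span = bool(conc.min() <= ic50 <= conc.max())
    if not in_span:
        msg = f"fitted IC50 ({ic50:.3g}) lies outside the measured span"
        warning = f"{warning}; {msg}" if warning else msg
        warnings.warn(msg, stacklevel=2)
    return DoseResponse(
        conc=conc, inhibition=inhibition, bottom=bottom, top=top,
        ic50=ic50, hill=hill, in_span=in_span, warning=warning,
    )


def mg_per_ml_to_micromolar(conc_mg_ml: float, sequence: str) -> float:
    """Convert a peptide mass concentration to uM via its average molar mass."""
    if conc_mg_ml < 0:
        raise ValueError("concentration must be >= 0")
    mw = molecular_weight(sequence.upper(), seq_type="protein")  # g/mol
    return conc_mg_ml * 1.0e6 / mw  # mg/mL == g/L; /(g/mol) -> mol/L -> uM
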
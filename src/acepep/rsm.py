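"""Box-Behnken response-surface fitting, ANOVA, and constrained optimum.

The three-factor Box-Behnken design (12 edge-midpoint runs + replicated
center runs, 17 in total) supports the full quadratic model in coded units

    Y = b0 + bA*A + bB*B + bC*C + bAB*A*B + bAC*A*C + bBC*B*C
        + bAA*A^2 + bBB*B^2 + bCC*C^2

fitted by ordinary least squares.  The ANOVA decomposes the model sum of
squares into per-term partial (type III) contributions, splits the
residual into lack-of-fit and pure error (from the center replicates),
and reports the usual response-surface diagnostics (R2, adjusted and
predicted R2, PRESS, adequate precision).  The optimum is the maximizer
of the fitted surface over the coded cube [-1, 1]^3, decoded back to
natural factor units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "TERM_NAMES",
    "FactorCoding",
    "DEFAULT_CODING",
    "BBDExperiment",
    "QuadraticFit",
    "AnovaReport",
    "fit_quadratic",
    "anova",
    "find_optimum",
    "OptimumResult",
]

#: Model terms in design-matrix column order.
TERM_NAMES = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2")


@dataclass(frozen=True)
class FactorCoding:
    """Code <-> natural maps for three factors at levels -1/0/+1.

    ``levels`` maps factor name -> (low, mid, high) natural values; the
    mid level must be the midpoint so that coding is affine.
    Intermediate values are interpolated linearly.
    """

    levels: dict

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError("exactly three factors are required")
        for name, (lo, mid, hi) in self.levels.items():
            if not (lo < mid < hi):
                raise ValueError(f"factor {name!r}: levels must be strictly increasing")
            if abs((mid - lo) - (hi - mid)) > 1e-9 * (hi - lo):
                raise ValueError(f"factor {name!r}: mid level must be the midpoint")

    @property
    def names(self) -> list[str]:
        return list(self.levels)

    def encode(self, name: str, natural: float) -> float:
        lo, mid, hi = self.levels[name]
        return (natural - mid) / ((hi - lo) / 2)

    def decode(self, name: str, coded: float) -> float:
        lo, mid, hi = self.levels[name]
        return mid + coded * (hi - lo) / 2


#: Hydrolysis-condition coding used by the bundled design:
#: temperature 50/55/60 degC, pH 8/8.5/9, time 2/3/4 h.
DEFAULT_CODING = FactorCoding(
    {"temperature": (50.0, 55.0, 60.0), "pH": (8.0, 8.5, 9.0), "time": (2.0, 3.0, 4.0)}
)


@dataclass
class BBDExperiment:
    """A 17-run three-factor Box-Behnken experiment in coded units."""

    coded: np.ndarray  # (17, 3) in {-1, 0, +1}
    response: np.ndarray  # (17,)

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.coded.shape != (17, 3) or self.response.shape != (17,):
            raise ValueError("a 3-factor BBD has 17 runs of 3 coded factors")
        if not np.isfinite(self.response).all():
            raise ValueError("responses must be finite")
        if not np.isin(self.coded, (-1.0, 0.0, 1.0)).all():
            raise ValueError("coded settings must be -1, 0 or +1")
        n_zero = (self.coded == 0).sum(axis=1)
        if (n_zero == 3).sum() != 5 or (n_zero == 1).sum() != 12:
            raise ValueError(
                "expected the Box-Behnken structure: 12 edge-midpoint runs "
                "(one factor at 0) and 5 center replicates"
            )
        # every factorial pair hits all four (+/-1, +/-1) combinations
        for i, j in ((0, 1), (0, 2), (1, 2)):
            edge = self.coded[n_zero == 1]
            pair = edge[(edge[:, i] != 0) & (edge[:, j] != 0)][:, (i, j)]
            combos = {tuple(row) for row in pair}
            if combos != {(-1, -1), (-1, 1), (1, -1), (1, 1)}:
                raise ValueError(f"factorial pair {i},{j} does not cover all four corners")

    @classmethod
    def from_natural(cls, table: pd.DataFrame, coding: FactorCoding) -> "BBDExperiment":
        """Build from a natural-units table whose last column is the response."""
        missing = [n for n in coding.names if n not in table.columns]
        if missing:
            raise ValueError(f"design table is missing factor column(s) {missing}")
        response_col = [c for c in table.columns if c not in coding.names]
        if len(response_col) != 1:
            raise ValueError("design table must have exactly one response column")
        coded = np.column_stack(
            [table[n].map(lambda v, n=n: coding.encode(n, v)).to_numpy() for n in coding.names]
        )
        return cls(coded=coded, response=table[response_col[0]].to_numpy(dtype=float))

    @property
    def is_center(self) -> np.ndarray:
        return (self.coded == 0).all(axis=1)


def _design_matrix(coded: np.ndarray) -> np.ndarray:
    a, b, c = coded[:, 0], coded[:, 1], coded[:, 2]
    return np.column_stack(
        [np.ones(len(coded)), a, b, c, a * b, a * c, b * c, a * a, b * b, c * c]
    )


@dataclass
class QuadraticFit:
    """OLS fit of the 10-term coded quadratic model."""

    design: BBDExperiment
    coefficients: dict = field(init=False)
    fitted: np.ndarray = field(init=False)
    residuals: np.ndarray = field(init=False)
    _ols: object = field(init=False, repr=False)

    def __post_init__(self) -> None:
        X = _design_matrix(self.design.coded)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "design matrix is rank-deficient; the quadratic model is not estimable"
            )
        res = sm.OLS(self.design.response, X).fit()
        self._ols = res
        self.coefficients = dict(zip(TERM_NAMES, res.params))
        self.fitted = np.asarray(res.fittedvalues)
        self.residuals = np.asarray(res.resid)

    def predict_coded(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return _design_matrix(points) @ np.array(
            [self.coefficients[t] for t in TERM_NAMES]
        )


def fit_quadratic(design: BBDExperiment) -> QuadraticFit:
    """Ordinary least squares on the coded 10-term quadratic model."""
    return QuadraticFit(design=design)


@dataclass
class AnovaReport:
    """Per-term ANOVA table plus response-surface fit diagnostics."""

    table: pd.DataFrame  # rows: Model, A..C^2, Residual, Lack of Fit, Pure Error, Cor Total
    diagnostics: dict

    def __str__(self) -> str:
        with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
            lines = [self.table.to_string()]
        lines.append("")
        for k, v in self.diagnostics.items():
            lines.append(f"{k}: {v:.4f}" if isinstance(v, float) else f"{k}: {v}")
        return "\n".join(lines)


def anova(fit: QuadraticFit) -> AnovaReport:
    """Partial-SS ANOVA with lack-of-fit split and RSM diagnostics.

    Per-term sums of squares are partial (type III), ``SS_j = beta_j^2 /
    [(X'X)^-1]_jj``; on the orthogonal Box-Behnken design these coincide
    with sequential SS for the main effects and interactions.  Pure error
    comes from the center replicates; the lack-of-fit F is tested against
    pure-error mean square.  PRESS uses the leave-one-out identity
    ``sum((e_i / (1 - h_ii))^2)``.
    """
    design = fit.design
    y = design.response
    n, p = len(y), len(TERM_NAMES)
    X = _design_matrix(design.coded)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = np.array([fit.coefficients[t] for t in TERM_NAMES])

    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_resid = float((fit.residuals**2).sum())
    ss_model = ss_total - ss_resid
    df_model, df_resid = p - 1, n - p
    ms_resid = ss_resid / df_resid

    center = design.is_center
    if center.sum() < 2:
        raise ValueError("lack-of-fit split needs at least 2 center replicates")
    yc = y[center]
    ss_pe = float(((yc - yc.mean()) ** 2).sum())
    df_pe = int(center.sum()) - 1
    ss_lof = ss_resid - ss_pe
    df_lof = df_resid - df_pe

    rows = []

    def _row(source, ss, df, ms=None, f=None, pval=None):
        rows.append(
            {"source": source, "sum_sq": ss, "df": df, "mean_sq": ms, "F": f, "p": pval}
        )

    if ms_resid > 0:
        f_model = (ss_model / df_model) / ms_resid
        _row("Model", ss_model, df_model, ss_model / df_model, f_model,
             float(stats.f.sf(f_model, df_model, df_resid)))
    else:  # exact fit: F is unbounded/undefined
        _row("Model", ss_model, df_model, ss_model / df_model)
    for j, term in enumerate(TERM_NAMES):
        if term == "Intercept":
            continue
        ss_j = float(beta[j] ** 2 / xtx_inv[j, j])
        if ms_resid > 0:
            f_j = (ss_j / 1) / ms_resid
            _row(term, ss_j, 1, ss_j, f_j, float(stats.f.sf(f_j, 1, df_resid)))
        else:
            _row(term, ss_j, 1, ss_j)
    _row("Residual", ss_resid, df_resid, ms_resid)
    if df_lof > 0 and ss_pe > 0:
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        _row("Lack of Fit", ss_lof, df_lof, ss_lof / df_lof, f_lof,
             float(stats.f.sf(f_lof, df_lof, df_pe)))
    else:
        _row("Lack of Fit", ss_lof, df_lof, ss_lof / max(df_lof, 1))
    _row("Pure Error", ss_pe, df_pe, ss_pe / df_pe if df_pe else None)
    _row("Cor Total", ss_total, n - 1)

    hat = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    press = float(((fit.residuals / (1.0 - hat)) ** 2).sum())
    if ss_total == 0:  # constant response: define the fit as perfect
        ss_total_safe = 1.0
    else:
        ss_total_safe = ss_total
    r2 = 1.0 - ss_resid / ss_total_safe
    diagnostics = {
        "std_dev": float(np.sqrt(ms_resid)),
        "r_squared": r2,
        "adj_r_squared": 1.0 - (ss_resid / df_resid) / (ss_total_safe / (n - 1)),
        "pred_r_squared": 1.0 - press / ss_total_safe,
        "press": press,
        "adeq_precision": (
            float((fit.fitted.max() - fit.fitted.min()) / np.sqrt(p * ms_resid / n))
            if ms_resid > 0
            else float("inf")
        ),
    }
    return AnovaReport(table=pd.DataFrame(rows).set_index("source"), diagnostics=diagnostics)


@dataclass
class OptimumResult:
    """Constrained maximizer of the fitted surface, coded and decoded."""

    coded: np.ndarray
    natural: dict
    predicted: float
    interior: bool
    warning: str | None = None


def _stationary_point(fit: QuadraticFit):
    c = fit.coefficients
    g = np.array([c["A"], c["B"], c["C"]])
    H = np.array(
        [
            [c["A^2"], c["AB"] / 2, c["AC"] / 2],
            [c["AB"] / 2, c["B^2"], c["BC"] / 2],
            [c["AC"] / 2, c["BC"] / 2, c["C^2"]],
        ]
    )
    try:
        xs = np.linalg.solve(-2.0 * H, g)
    except np.linalg.LinAlgError:
        return None, H
    return xs, H


def find_optimum(fit: QuadraticFit, coding: FactorCoding | None = None) -> OptimumResult:
    """Maximize the fitted quadratic over the coded cube [-1, 1]^3.

    If the stationary point is an interior maximum (negative-definite
    Hessian, inside the cube) it is returned directly; otherwise the cube
    is searched with a coarse grid refined by bounded quasi-Newton
    restarts, and a warning marks the boundary/saddle case.
    """
    coding = coding or DEFAULT_CODING
    warning = None
    xs, H = _stationary_point(fit)
    interior = False
    if (
        xs is not None
        and np.all(np.abs(xs) <= 1.0)
        and np.all(np.linalg.eigvalsh(H) < 0)
    ):
        best_x = xs
        interior = True
    else:
        # brute-force the cube, then polish the best cells
        grid = np.linspace(-1.0, 1.0, 41)
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        vals = fit.predict_coded(pts)
        order = np.argsort(vals)[::-1][:8]
        best_x, best_v = None, -np.inf
        for k in order:
            res = optimize.minimize(
                lambda x: -fit.predict_coded(x)[0],
                pts[k],
                bounds=[(-1.0, 1.0)] * 3,
                method="L-BFGS-B",
            )
            if -res.fun > best_v:
                best_v, best_x = -res.fun, res.x
        warning = (
            "no interior maximum (saddle or boundary optimum); "
            "returning the best point on the constrained cube"
        )
    predicted = float(fit.predict_coded(best_x)[0])
    natural = {
        name: float(coding.decode(name, best_x[i])) for i, name in enumerate(coding.names)
    }
    return OptimumResult(
        coded=np.asarray(best_x, dtype=float),
        natural=natural,
        predicted=predicted,
        interior=interior,
        warning=warning,
    )
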
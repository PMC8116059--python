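"""Photobleaching statistics and dimerization thermodynamics.

The chain: photobleaching step-count distributions (P1, P2, P3+) ->
fraction of subunits in dimers (least-squares against fixed monomer and
dimer control distributions) -> equilibrium dimerization isotherm

    F_Dimer = (1 + 4*Keq*chi* - sqrt(1 + 8*Keq*chi*)) / (4*Keq*chi*)

on the mole-fraction scale (chi* = chi/2 is the reactive subunit/lipid mole
fraction, since only like-oriented subunits can pair), and free energies
DeltaG0 = -R*T*ln(Keq) at the 1 subunit/lipid standard state.  Titration
models (single/two-phase exponential decay of F_Dimer vs %DL) and the
linear DeltaDeltaG regressions versus %DL or log10(%DL) complete the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
import lmfit
import statsmodels.api as sm

#: gas constant, kcal / (mole K)
R_KCAL = 1.9872e-3
#: default assay temperature (K); room temperature, configurable everywhere
DEFAULT_T = 298.15


@dataclass
class StepDistribution:
    """Photobleaching probabilities (P1, P2, P3+) with optional counts.

    chi is the protein mole fraction (subunits/lipid); the reactive mole
    fraction is chi* = chi/2.
    """

    p1: float
    p2: float
    p3plus: float
    n1: int | None = None
    n2: int | None = None
    n3plus: int | None = None
    chi: float | None = None
    pct_dl: float | None = None
    label: str = ""

    def __post_init__(self):
        total = self.p1 + self.p2 + self.p3plus
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")

    @classmethod
    def from_counts(cls, n1: int, n2: int, n3plus: int, **kw) -> "StepDistribution":
        tot = n1 + n2 + n3plus
        if tot <= 0:
            raise ValueError("counts must sum to a positive number of spots")
        return cls(n1 / tot, n2 / tot, n3plus / tot, n1, n2, n3plus, **kw)

    @property
    def chi_star(self) -> float | None:
        return None if self.chi is None else self.chi / 2.0

    @property
    def n_spots(self) -> int | None:
        if self.n1 is None:
            return None
        return self.n1 + self.n2 + self.n3plus

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3plus])


@dataclass
class ControlBasis:
    """Fixed monomer and dimer control distributions (matched lipid condition)."""

    monomer: StepDistribution
    dimer: StepDistribution

    def __post_init__(self):
        if np.allclose(self.monomer.as_array(), self.dimer.as_array()):
            raise ValueError("monomer and dimer control distributions are identical; "
                             "F_Dimer is unidentifiable")


def expected_label_distribution(p_label: float, n_subunits: int) -> StepDistribution:
    """Binomial step distribution for an n-mer, conditioned on >=1 label.

    P_k = C(n,k) p^k (1-p)^(n-k) / (1 - (1-p)^n) for k = 1..n, folded into
    (P1, P2, P3+).
    """
    if not 0 < p_label <= 1:
        raise ValueError("p_label must be in (0, 1]: an unlabeled population is unobservable")
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    from scipy.stats import binom
    k = np.arange(1, n_subunits + 1)
    pk = binom.pmf(k, n_subunits, p_label)
    pk = pk / (1.0 - (1.0 - p_label) ** n_subunits)
    p1 = pk[0] if n_subunits >= 1 else 0.0
    p2 = pk[1] if n_subunits >= 2 else 0.0
    p3 = pk[2:].sum() if n_subunits >= 3 else 0.0
    return StepDistribution(float(p1), float(p2), float(p3),
                            label=f"binomial(n={n_subunits}, p={p_label})")


@dataclass
class FDimerFit:
    f_dimer: float
    se: float
    clipped: bool = False
    residual_norm: float = 0.0


def fit_fraction_dimer(observed: StepDistribution, basis: ControlBasis,
                       weighting: str = "none") -> FDimerFit:
    """F_Dimer by least squares on P_obs = F*P_dim + (1-F)*P_mono over [0, 1].

    ``weighting='multinomial'`` weights components by 1/sqrt(P*(1-P)/N)
    using the observed counts; the default is unweighted.  The closed-form
    projection onto the monomer-dimer segment is exact; endpoint clipping
    is flagged.
    """
    p = observed.as_array()
    pm = basis.monomer.as_array()
    pd_ = basis.dimer.as_array()
    d = pd_ - pm
    w = np.ones(3)
    if weighting == "multinomial":
        n = observed.n_spots
        if n is None:
            raise ValueError("multinomial weighting needs observed counts")
        var = np.clip(p * (1 - p), 1e-6, None) / n
        w = 1.0 / np.sqrt(var)
    num = float(np.sum(w**2 * d * (p - pm)))
    den = float(np.sum(w**2 * d * d))
    f_raw = num / den
    f = float(np.clip(f_raw, 0.0, 1.0))
    resid = p - (pm + f * d)
    if observed.n_spots:
        # analytic multinomial sampling error of the projection d.(p - pm)/|d|^2
        n = observed.n_spots
        var_proj = (np.sum(w**2 * d * w**2 * d * p) - np.sum(w**2 * d * p) ** 2) / n
        se = float(np.sqrt(max(var_proj, 0.0)) / den)
    else:
        # residual-based fallback: 3 components, 1 parameter, 1 sum constraint
        se = float(np.sqrt(np.sum(resid**2) / 1.0 / den))
    return FDimerFit(f, se, clipped=(f != f_raw),
                     residual_norm=float(np.linalg.norm(resid)))


def isotherm(keq, chi_star):
    """Dimer fraction from the equilibrium dimerization isotherm.

    Evaluated in the cancellation-free form F = 4x / (1 + 4x + sqrt(1 + 8x))
    with x = Keq*chi*, algebraically identical to
    (1 + 4x - sqrt(1 + 8x)) / (4x) and stable down to x -> 0.
    """
    keq = np.asarray(keq, float)
    chi_star = np.asarray(chi_star, float)
    if np.any(keq <= 0) or np.any(chi_star <= 0):
        raise ValueError("Keq and chi* must be positive")
    x = keq * chi_star
    out = 4.0 * x / (1.0 + 4.0 * x + np.sqrt(1.0 + 8.0 * x))
    return float(out) if out.ndim == 0 else out


def mass_action_dimer_fraction(keq, chi_star):
    """Independent mass-action route: solve Keq = chi_D/chi_M^2 with
    chi* = chi_M + 2 chi_D, report F = 2 chi_D / chi*.

    Kept separate from :func:`isotherm` as a numeric cross-check.
    """
    keq = float(keq)
    chi_star = float(chi_star)
    chi_m = (-1.0 + np.sqrt(1.0 + 8.0 * keq * chi_star)) / (4.0 * keq)
    chi_d = keq * chi_m**2
    return 2.0 * chi_d / chi_star


def invert_isotherm(f_dimer: float, chi_star: float) -> float:
    """Closed-form Keq from a single (chi*, F) point: Keq = F / (2 chi* (1-F)^2)."""
    if not 0 < f_dimer < 1:
        raise ValueError("F_Dimer must be strictly between 0 and 1 to invert")
    if chi_star <= 0:
        raise ValueError("chi* must be positive")
    return f_dimer / (2.0 * chi_star * (1.0 - f_dimer) ** 2)


def free_energy(keq: float, t: float = DEFAULT_T, se_keq: float | None = None):
    """Standard dimerization free energy DeltaG0 = -R*T*ln(Keq), kcal/mole.

    Standard state: 1 subunit/lipid.  With ``se_keq``, also returns the
    propagated standard error R*T*se_keq/Keq.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    if keq <= 0:
        raise ValueError("Keq must be positive")
    dg = -R_KCAL * t * np.log(keq)
    if se_keq is None:
        return float(dg)
    return float(dg), float(R_KCAL * t * se_keq / keq)


def keq_from_free_energy(dg: float, t: float = DEFAULT_T) -> float:
    if t <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-dg / (R_KCAL * t)))


def delta_delta_g(dg_x: float, dg_ref: float, se_x: float = 0.0,
                  se_ref: float = 0.0) -> tuple[float, float]:
    """DeltaDeltaG = DeltaG0(x) - DeltaG0(reference), errors in quadrature."""
    return float(dg_x - dg_ref), float(np.hypot(se_x, se_ref))


@dataclass
class IsothermFit:
    keq: float
    kd: float
    dg: float
    t: float
    r_squared: float
    se_log10_keq: float | None = None
    dg_ci95: tuple[float, float] | None = None
    lower_limit_only: bool = False
    n_points: int = 0


def fit_isotherm(points, t: float = DEFAULT_T,
                 flag_min_f: float = 0.9) -> IsothermFit:
    """Fit Keq to (chi*, F_Dimer[, se]) points by least squares on log10(Keq).

    When the observed F never falls below ``flag_min_f`` across the sampled
    chi* range, or the fitted K_D lies outside it, the fit is flagged as a
    lower-limit-only estimate (the reaction is out of the assay's dynamic
    range and only a bound on K_D is supported).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 2 or np.unique(pts[:, 0]).size < 2:
        raise ValueError("fit_isotherm needs >=2 points with distinct chi*")
    chi_star, f = pts[:, 0], pts[:, 1]
    se = pts[:, 2] if pts.shape[1] > 2 else np.ones_like(f)
    se = np.where(se > 0, se, 1.0)
    if np.all(f <= 0) or np.all(f >= 1):
        raise ValueError("all F_Dimer at 0 or 1: Keq is unidentifiable")

    def resid(params):
        return (isotherm(10.0 ** params["log10_keq"].value, chi_star) - f) / se

    guess = np.log10(invert_isotherm(float(np.clip(np.median(f), 1e-3, 1 - 1e-3)),
                                     float(np.median(chi_star))))
    params = lmfit.Parameters()
    params.add("log10_keq", value=guess, min=guess - 12, max=guess + 12)
    res = lmfit.minimize(resid, params)
    log10_keq = float(res.params["log10_keq"].value)
    keq = 10.0 ** log10_keq
    pred = isotherm(keq, chi_star)
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se_log = res.params["log10_keq"].stderr
    dg = free_energy(keq, t)
    ci = None
    if se_log is not None:
        lo, hi = log10_keq - 1.96 * se_log, log10_keq + 1.96 * se_log
        ci = (free_energy(10.0 ** hi, t), free_energy(10.0 ** lo, t))
    kd = 1.0 / keq
    lower_limit = bool(f.min() > flag_min_f) or not (chi_star.min() <= kd <= chi_star.max())
    return IsothermFit(keq, kd, dg, t, r2, se_log, ci, lower_limit, len(f))


@dataclass
class TitrationFit:
    model: str
    f0: float
    params: dict
    r_squared: float
    residual_sum: float
    warning: str = ""

    def predict(self, pct_dl):
        dl = np.asarray(pct_dl, float)
        if self.model == "single":
            return self.f0 * np.exp(-self.params["lam"] * dl)
        p = self.params
        return self.f0 * (p["f1"] * np.exp(-p["lam1"] * dl)
                          + (1 - p["f1"]) * np.exp(-p["lam2"] * dl))


def fit_titration(points, model: str = "single",
                  f0_fixed: float | None = None) -> TitrationFit:
    """Fit F_Dimer vs %DL to a single or two-phase exponential decay.

    single:    F = F0 * exp(-lam*DL)
    two-phase: F = F0 * [F1*exp(-lam1*DL) + (1-F1)*exp(-lam2*DL)],  F1 in [0,1]

    ``f0_fixed`` pins F(0) to a supplied mean (e.g. the measured mean dimer
    fraction at 0% DL).  Decay rates are bounded at >= 0; a fit pinned at
    that bound is reported with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    dl, f = pts[:, 0], pts[:, 1]
    min_pts = 3 if model == "single" else 5
    if len(dl) < min_pts:
        raise ValueError(f"{model} titration fit needs >= {min_pts} points")
    params = lmfit.Parameters()
    f0_guess = f0_fixed if f0_fixed is not None else max(f.max(), 1e-6)
    params.add("f0", value=f0_guess, min=0.0, max=1.0, vary=f0_fixed is None)
    if model == "single":
        params.add("lam", value=0.1, min=0.0)

        def model_f(p, x):
            return p["f0"].value * np.exp(-p["lam"].value * x)
    elif model == "two-phase":
        params.add("f1", value=0.5, min=0.0, max=1.0)
        params.add("lam1", value=10.0, min=0.0)
        params.add("lam2", value=0.05, min=0.0)

        def model_f(p, x):
            return p["f0"].value * (p["f1"].value * np.exp(-p["lam1"].value * x)
                                    + (1 - p["f1"].value) * np.exp(-p["lam2"].value * x))
    else:
        raise ValueError(f"unknown titration model {model!r}")

    res = lmfit.minimize(lambda p: model_f(p, dl) - f, params)
    pred = model_f(res.params, dl)
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    out = {k: float(v.value) for k, v in res.params.items() if k != "f0"}
    if model == "two-phase":
        out = {"f1": out["f1"], "lam1": out["lam1"], "lam2": out["lam2"]}
        # report the fast phase first
        if out["lam1"] < out["lam2"]:
            out = {"f1": 1 - out["f1"], "lam1": out["lam2"], "lam2": out["lam1"]}
    warning = ""
    rates = [v for k, v in out.items() if k.startswith("lam")]
    if any(r == 0.0 for r in rates):
        warning = "a decay rate hit the >=0 bound"
        warnings.warn(warning)
    return TitrationFit(model, float(res.params["f0"].value), out, r2, ss_res, warning)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    r_squared: float
    abscissa: str
    data: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def per_10pct_dl(self) -> float:
        """Destabilization per addition of 10% DL (only for the %DL abscissa)."""
        if self.abscissa != "pct_dl":
            raise ValueError("per-10%-DL scaling applies to the pct_dl abscissa")
        return 10.0 * self.slope


def fit_linear_ddg(points, abscissa_kind: str = "pct_dl") -> RegressionFit:
    """Linear regression of DeltaDeltaG against %DL or log10(%DL), with 95% CIs.

    The %DL abscissa describes the >1% DL regime (bulk-thinning linkage);
    the log10 abscissa the <1% regime (preferential-solvation linkage).
    Points may carry a third column of per-point standard errors, in which
    case the fit is weighted (WLS, weights 1/se^2) — appropriate because the
    free-energy error of a dimer-fraction estimate grows steeply as F -> 1.
    """
    if abscissa_kind not in ("pct_dl", "log10_pct_dl"):
        raise ValueError(f"unknown abscissa {abscissa_kind!r}")
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 3:
        raise ValueError("linear regression needs >= 3 points")
    x, y = pts[:, 0], pts[:, 1]
    se = pts[:, 2] if pts.shape[1] > 2 else None
    if abscissa_kind == "log10_pct_dl":
        if np.any(x <= 0):
            raise ValueError("log10 abscissa requires positive %DL")
        x = np.log10(x)
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all x identical")
    if se is not None:
        if np.any(se <= 0):
            raise ValueError("per-point standard errors must be positive")
        model = sm.WLS(y, sm.add_constant(x), weights=1.0 / se**2).fit()
    else:
        model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        se_slope=float(model.bse[1]), se_intercept=float(model.bse[0]),
        ci95_slope=(float(ci[1][0]), float(ci[1][1])),
        ci95_intercept=(float(ci[0][0]), float(ci[0][1])),
        r_squared=float(model.rsquared), abscissa=abscissa_kind,
        data=pd.DataFrame({"x": x, "ddg": y}))
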
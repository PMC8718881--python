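"""Steady-state Michaelis-Menten analysis of spectrophotometric
depyrimidination assays.

The model is v/[E] = kcat * [S] / (KM + [S]) with [S] in uM and v/[E] in
s^-1.  Catalytic efficiency kcat/KM is reported in M^-1 s^-1 (the factor
1e6 between uM and M is applied once, in :func:`efficiency_from`).  Initial
rates come from the linear region of absorbance progress curves restricted
to <10% substrate conversion by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["MMParams", "RateDataset", "ProgressCurve", "FoldChange",
           "FitError", "mm_velocity", "initial_rate", "fit_mm",
           "fold_change", "efficiency_from", "round_sig"]

#: Default molar difference extinction coefficients for depyrimidination,
#: M^-1 cm^-1: thymidine at 290 nm and deoxyuridine at 282 nm.
DELTA_EPSILON = {"dThd@290nm": 1000.0, "dUrd@282nm": 1370.0}

UM_TO_M = 1e-6


def efficiency_from(kcat: float, km_um: float) -> float:
    """kcat/KM in M^-1 s^-1 from kcat (s^-1) and KM (uM)."""
    return kcat / (km_um * UM_TO_M)


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class MMParams:
    kcat: float                  # s^-1
    km: float                    # uM
    kcat_se: float = math.nan    # s^-1
    km_se: float = math.nan      # uM

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km <= 0:
            raise ValueError("kcat and KM must be positive")

    @property
    def efficiency(self) -> float:
        """kcat/KM, M^-1 s^-1."""
        return efficiency_from(self.kcat, self.km)

    @property
    def efficiency_se(self) -> float:
        """First-order (delta-method) propagation, ignoring kcat-KM covariance."""
        rel2 = (self.kcat_se / self.kcat) ** 2 + (self.km_se / self.km) ** 2
        return self.efficiency * math.sqrt(rel2)


@dataclass
class RateDataset:
    """Initial-velocity data: [S] in uM against v/[E] in s^-1."""
    s_um: np.ndarray
    v_over_e: np.ndarray
    replicate: np.ndarray | None = None
    n_clipped: int = 0           # negative simulated velocities clipped to 0

    def __post_init__(self) -> None:
        self.s_um = np.asarray(self.s_um, dtype=float)
        self.v_over_e = np.asarray(self.v_over_e, dtype=float)
        if self.s_um.shape != self.v_over_e.shape:
            raise ValueError("S and v/[E] must have the same shape")
        if np.any(self.s_um <= 0):
            raise ValueError("substrate concentrations must be positive")

    def n_distinct(self) -> int:
        return len(np.unique(self.s_um))

    def means(self) -> "RateDataset":
        """Replicates averaged per concentration (fit-to-means mode)."""
        s = np.unique(self.s_um)
        v = np.array([self.v_over_e[self.s_um == si].mean() for si in s])
        return RateDataset(s, v)


@dataclass
class ProgressCurve:
    """Absorbance-vs-time trace of a single depyrimidination reaction."""
    time_s: np.ndarray
    absorbance: np.ndarray
    s0_um: float                         # initial substrate, uM
    delta_epsilon: float                 # M^-1 cm^-1
    pathlength_cm: float = 1.0
    wavelength: str = "dThd@290nm"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


def mm_velocity(params: "MMParams | tuple[float, float]", s_um) -> np.ndarray | float:
    """The Michaelis-Menten rate law v/[E] = kcat*[S]/(KM+[S])."""
    kcat, km = (params.kcat, params.km) if isinstance(params, MMParams) else params
    s = np.asarray(s_um, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    v = kcat * s / (km + s)
    return float(v) if np.isscalar(s_um) else v


def initial_rate(curve: ProgressCurve, conversion_limit: float = 0.10) -> float:
    """Initial rate (M/s) from the early linear region of a progress curve.

    Points are admitted while consumed substrate, inferred from the
    absorbance change, stays below ``conversion_limit`` of the initial
    amount; the rate is |least-squares slope| / (delta_epsilon * pathlength).
    """
    da = np.abs(curve.absorbance - curve.absorbance[0])
    consumed_um = da / (curve.delta_epsilon * curve.pathlength_cm) / UM_TO_M
    ok = consumed_um < conversion_limit * curve.s0_um
    if np.count_nonzero(ok) < 4:
        raise ValueError(
            "fewer than 4 points under the conversion limit; "
            "record a shorter sampling interval or earlier time window")
    t, a = curve.time_s[ok], curve.absorbance[ok]
    slope = np.polyfit(t, a, 1)[0]
    return abs(float(slope)) / (curve.delta_epsilon * curve.pathlength_cm)


class FitError(RuntimeError):
    def __init__(self, msg: str, best: dict | None = None):
        super().__init__(msg)
        self.best = best or {}


def fit_mm(data: RateDataset, pool_replicates: bool = True, max_iter: int = 500) -> MMParams:
    """Nonlinear least-squares fit of the Michaelis-Menten model.

    Initialization: kcat0 = max(v/[E]), KM0 = median [S].  Standard errors
    come from the Jacobian-based covariance at the optimum
    (Levenberg-Marquardt, relative tolerance 1e-10).  With
    ``pool_replicates=False``, replicates are averaged per concentration
    before fitting.  A KM standard error exceeding KM itself triggers a
    poorly-identified warning (all measured [S] likely far below KM).
    """
    if data.n_distinct() < 5:
        raise ValueError("need >= 5 distinct substrate concentrations")
    d = data if pool_replicates else data.means()
    p0 = [float(d.v_over_e.max()), float(np.median(d.s_um))]

    def model(s, kcat, km):
        return kcat * s / (km + s)

    try:
        popt, pcov = curve_fit(model, d.s_um, d.v_over_e, p0=p0,
                               method="lm", maxfev=max_iter * 10,
                               xtol=1e-10, ftol=1e-10)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}",
                       best={"p0": p0}) from exc
    kcat, km = float(popt[0]), float(popt[1])
    if kcat <= 0 or km <= 0:
        raise FitError(f"fit converged to non-physical parameters kcat={kcat}, KM={km}",
                       best={"kcat": kcat, "km": km})
    se = np.sqrt(np.diag(pcov))
    params = MMParams(kcat, km, float(se[0]), float(se[1]))
    if params.km_se > params.km:
        warnings.warn(
            f"KM poorly identified (KM={km:.3g} +/- {params.km_se:.3g} uM); "
            "extend the substrate range above KM")
    return params


@dataclass
class FoldChange:
    raw: float
    rounded: float               # 2 significant figures
    quantity: str


def fold_change(a, b, quantity: str = "kcat") -> FoldChange:
    """Ratio a/b for kcat, KM, or efficiency; MMParams or plain numbers.

    Reported both raw and rounded to 2 significant figures, following the
    convention of quoting e.g. a "2.8-fold decrease".
    """
    if quantity not in ("kcat", "km", "efficiency"):
        raise ValueError("quantity must be kcat, km, or efficiency")

    def extract(x):
        if isinstance(x, MMParams):
            return {"kcat": x.kcat, "km": x.km, "efficiency": x.efficiency}[quantity]
        return float(x)

    num, den = extract(a), extract(b)
    if den == 0:
        raise ZeroDivisionError("denominator quantity is zero")
    ratio = num / den
    return FoldChange(ratio, round_sig(ratio, 2), quantity)
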
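"""Concentration-effect and current-voltage analysis for TEVC recordings.

Two models carry the whole analysis:

* the Hill equation for concentration-inhibition curves,

      fraction_remaining(c) = 1 / (1 + (c / IC50)^nH)

  with top fixed at 1 and bottom at 0 (full block assumed; free asymptotes
  are opt-in), and

* the Boltzmann-conductance model for peak-current I-V families,

      I(V) = Gmax * (V - Vrev) / (1 + exp((V0.5 - V) / k))

  from which activation midpoint V0.5 and slope k are read.  A gating
  modifier shows up as a depolarising shift of V0.5 between control and
  peptide fits, and as voltage-dependent fractional inhibition.

Data are plain pandas DataFrames: dose-response tables carry columns
``conc_nM``, ``fraction`` (and optionally ``replicate``); I-V families
carry ``potential_mV``, ``current``, ``condition``, ``replicate``.
Fits are least squares (lmfit/Levenberg-Marquardt) with multi-start
initialisation to dodge local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "HillFit",
    "BoltzmannFit",
    "hill_fraction",
    "boltzmann_current",
    "fit_hill",
    "normalize_iv",
    "fit_activation",
    "activation_shift",
    "inhibition_vs_voltage",
]

DEFAULT_VREV = 65.0  # mV, sodium reversal potential used when not fitted
FIT_TOL = 1e-8


def hill_fraction(conc, ic50, nh, top=1.0, bottom=0.0):
    """Fraction of control current remaining at concentration *conc* (nM)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** nh)


def boltzmann_current(v, gmax, v05, k, vrev):
    """Peak current at test potential *v* under the Boltzmann-conductance model."""
    v = np.asarray(v, dtype=float)
    return gmax * (v - vrev) / (1.0 + np.exp((v05 - v) / k))


@dataclass(frozen=True)
class HillFit:
    ic50: float
    nh: float
    ic50_se: float | None
    nh_se: float | None
    top: float
    bottom: float
    reliable: bool
    message: str
    n_points: int

    def predict(self, conc):
        return hill_fraction(conc, self.ic50, self.nh, self.top, self.bottom)


@dataclass(frozen=True)
class BoltzmannFit:
    v05: float
    k: float
    gmax: float
    vrev: float
    v05_se: float | None
    k_se: float | None
    via: str  # 'current' or 'conductance'

    def predict(self, v):
        return boltzmann_current(v, self.gmax, self.v05, self.k, self.vrev)


def fit_hill(
    data: pd.DataFrame,
    free_asymptotes: bool = False,
    n_starts: int = 5,
) -> HillFit:
    """Fit the Hill equation to a concentration-inhibition table.

    Requires >= 3 distinct concentrations.  IC50 is initialised at
    *n_starts* log-spaced values spanning the tested concentration range
    and the best (lowest chi-square) solution kept.  A fit is flagged
    unreliable when it fails to converge or lands outside
    [min conc / 100, max conc * 100].
    """
    conc = np.asarray(data["conc_nM"], dtype=float)
    frac = np.asarray(data["fraction"], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    distinct = np.unique(conc)
    if distinct.size < 3:
        raise ValueError(
            f"need >= 3 distinct concentrations for a Hill fit, got {distinct.size}"
        )
    model = Model(hill_fraction)
    best = None
    for start in np.geomspace(distinct.min(), distinct.max(), n_starts):
        params = model.make_params(
            ic50=dict(value=start, min=1e-9),
            nh=dict(value=1.0, min=0.05, max=10.0),
            top=dict(value=1.0, vary=free_asymptotes),
            bottom=dict(value=0.0, vary=free_asymptotes),
        )
        try:
            res = model.fit(
                frac, params, conc=conc, method="leastsq",
                fit_kws=dict(xtol=FIT_TOL, ftol=FIT_TOL),
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("Hill fit failed from every start")
    ic50 = best.params["ic50"].value
    reliable = bool(
        best.success and distinct.min() / 100.0 <= ic50 <= distinct.max() * 100.0
    )
    message = "" if reliable else (
        "fit did not converge" if not best.success
        else f"IC50 {ic50:.3g} nM outside the supported range"
    )
    return HillFit(
        ic50=ic50,
        nh=best.params["nh"].value,
        ic50_se=best.params["ic50"].stderr,
        nh_se=best.params["nh"].stderr,
        top=best.params["top"].value,
        bottom=best.params["bottom"].value,
        reliable=reliable,
        message=message,
        n_points=conc.size,
    )


def normalize_iv(family: pd.DataFrame) -> pd.DataFrame:
    """Normalise every current to its oocyte's maximum control peak current.

    Division is by the maximum *magnitude* control current of the same
    replicate, so inward (negative) currents keep their sign and the
    control peak maps to magnitude 1.
    """
    req = {"potential_mV", "current", "condition", "replicate"}
    missing = req - set(family.columns)
    if missing:
        raise ValueError(f"I-V family missing columns: {sorted(missing)}")
    out = family.copy()
    for rep, grp in family.groupby("replicate"):
        ctrl = grp.loc[grp["condition"] == "control", "current"]
        if ctrl.empty:
            raise ValueError(f"replicate {rep!r} has no control rows")
        denom = ctrl.abs().max()
        if denom == 0:
            raise ValueError(f"replicate {rep!r} has zero control current")
        out.loc[grp.index, "current"] = grp["current"] / denom
    return out


def _mean_iv(family: pd.DataFrame, condition: str | None) -> tuple[np.ndarray, np.ndarray]:
    df = family
    if condition is not None and "condition" in df.columns:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"no rows for condition {condition!r}")
    g = df.groupby("potential_mV")["current"].mean()
    return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)


def fit_activation(
    family: pd.DataFrame,
    condition: str | None = "control",
    vrev: float = DEFAULT_VREV,
    via: str = "current",
) -> BoltzmannFit:
    """Fit the Boltzmann-conductance model to a peak-current I-V family.

    Replicates are averaged per potential.  Two equivalent routes are
    offered (they agree on noiseless data): ``via='current'`` fits I(V)
    directly; ``via='conductance'`` transforms to G = I/(V − Vrev) on
    potentials below Vrev and fits the logistic.  Vrev is fixed, not
    fitted, and recorded in the result.
    """
    v, i = _mean_iv(family, condition)
    usable = v < vrev
    if usable.sum() < 4:
        raise ValueError("fewer than 4 potentials below Vrev; cannot fit")
    g_emp = i[usable] / (v[usable] - vrev)
    gmax0 = float(np.max(g_emp))
    starts = np.quantile(v[usable], [0.25, 0.4, 0.5, 0.6, 0.75])
    best = None
    if via == "current":
        model = Model(boltzmann_current)
        xname, xdata, ydata = "v", v, i
    elif via == "conductance":
        def logistic_g(v, gmax, v05, k):
            return gmax / (1.0 + np.exp((v05 - v) / k))
        model = Model(logistic_g)
        xname, xdata, ydata = "v", v[usable], g_emp
    else:
        raise ValueError("via must be 'current' or 'conductance'")
    for v05_start in starts:
        params = model.make_params(
            gmax=dict(value=gmax0 if gmax0 != 0 else 1.0),
            v05=dict(value=float(v05_start)),
            k=dict(value=6.0, min=0.5, max=40.0),
        )
        if via == "current":
            params.add("vrev", value=vrev, vary=False)
        try:
            res = model.fit(
                ydata, params, **{xname: xdata}, method="leastsq",
                fit_kws=dict(xtol=FIT_TOL, ftol=FIT_TOL),
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("activation fit failed from every start")
    return BoltzmannFit(
        v05=best.params["v05"].value,
        k=best.params["k"].value,
        gmax=best.params["gmax"].value,
        vrev=vrev,
        v05_se=best.params["v05"].stderr,
        k_se=best.params["k"].stderr,
        via=via,
    )


def activation_shift(control: BoltzmannFit, peptide: BoltzmannFit) -> float:
    """Gating shift ΔV0.5 = V0.5(peptide) − V0.5(control); positive = depolarising."""
    return peptide.v05 - control.v05


def inhibition_vs_voltage(
    control: pd.DataFrame,
    peptide: pd.DataFrame,
    floor: float = 0.05,
) -> pd.DataFrame:
    """Fraction of current inhibited at each test potential.

    Both tables must share the same potential grid; replicates are averaged.
    Potentials where the control current magnitude is below *floor* times
    its maximum are dropped (the ratio is unstable near the reversal
    potential and at subthreshold steps).
    """
    vc, ic = _mean_iv(control, None)
    vp, ip = _mean_iv(peptide, None)
    if not np.array_equal(vc, vp):
        raise ValueError("control and peptide potential grids differ")
    keep = np.abs(ic) >= floor * np.abs(ic).max()
    frac = 1.0 - ip[keep] / ic[keep]
    return pd.DataFrame({"potential_mV": vc[keep], "fraction_inhibited": frac})
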
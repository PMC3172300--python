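"""Michaelis-Menten kinetics: fitting, catalytic efficiency, substrate
ranking and inter-construct fold changes.

The central model is v = Vmax * S / (Km + S). Fits are bounded nonlinear
least squares (lmfit) with three data-driven starts; standard errors come
from the linearised covariance at the optimum. Velocities are taken in
caller-declared units and carried through unchanged — when they are
specific activities (µmol·min⁻¹·mg⁻¹), the fitted Vmax *is* the specific
activity, and kcat (s⁻¹) follows from the enzyme molar mass:
kcat = Vmax * M / 6e4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = ["MMFit", "SubstrateRanking", "fit_michaelis_menten", "rank_substrates", "fold_change"]


def _mm(S, vmax, km):
    return vmax * S / (km + S)


@dataclass
class MMFit:
    """Result of a Michaelis-Menten fit.

    ``vmax`` and ``km`` are in the units of the input table. When the
    velocities are per-mg specific activities and a molar mass was given,
    ``kcat`` (s⁻¹) and ``efficiency`` (= kcat/Km, s⁻¹·M⁻¹ when Km was
    converted to molar by the caller-supplied factor) are populated.
    """

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    rss: float
    converged: bool
    flag: str = "ok"
    specific_activity: float | None = None
    kcat: float | None = None
    kcat_se: float | None = None
    efficiency: float | None = None
    efficiency_se: float | None = None
    n_points: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def fit_michaelis_menten(
    assay: pd.DataFrame,
    enzyme_conc: float | None = None,
    molar_mass: float | None = None,
    km_to_molar: float | None = None,
    velocity_is_specific_activity: bool = True,
) -> MMFit:
    """Fit v = Vmax*S/(Km+S) to an assay table.

    Parameters
    ----------
    assay
        Table with columns ``substrate_conc`` and ``velocity`` (replicates
        as extra rows).
    enzyme_conc
        Enzyme concentration (M). Required to derive kcat when velocities
        are molar rates rather than specific activities.
    molar_mass
        Enzyme molar mass (g/mol); enables kcat and kcat/Km when the
        velocities are specific activities in µmol·min⁻¹·mg⁻¹.
    km_to_molar
        Factor converting the substrate-concentration unit to molar
        (e.g. 1e-3 for mM); enables ``efficiency`` in s⁻¹·M⁻¹.
    velocity_is_specific_activity
        Declares the velocity unit. True (default): µmol·min⁻¹·mg⁻¹,
        so specific_activity = Vmax. False: molar rate (M/s); the
        specific activity then requires ``enzyme_conc`` and ``molar_mass``.

    Raises
    ------
    ValueError
        For fewer than 4 distinct substrate concentrations.

    Notes
    -----
    Data without saturation curvature (velocity effectively linear in S)
    cannot constrain Vmax and Km separately; such fits are flagged
    ``"unsaturated"`` with ``converged=False`` instead of silently
    extrapolating.
    """
    s = assay["substrate_conc"].to_numpy(dtype=float)
    v = assay["velocity"].to_numpy(dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")

    vmax0 = float(v.max())
    half = vmax0 / 2.0
    km0 = float(s[np.argmin(np.abs(v - half))])
    km0 = max(km0, 1e-12)
    starts = [
        (vmax0, km0),
        (2.0 * vmax0, float(np.median(s))),
        (1.2 * vmax0, float(np.quantile(s, 0.25))),
    ]

    model = Model(_mm)
    best = None
    for v0, k0 in starts:
        params = model.make_params(vmax=dict(value=v0, min=1e-12),
                                   km=dict(value=k0, min=1e-12))
        try:
            res = model.fit(v, params, S=s, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("Michaelis-Menten fit failed from all starts")

    vmax = float(best.params["vmax"].value)
    km = float(best.params["km"].value)
    vmax_se = float(best.params["vmax"].stderr or np.nan)
    km_se = float(best.params["km"].stderr or np.nan)
    rss = float(best.chisqr)

    # curvature check: a straight line through the origin explains the data
    # almost as well as the hyperbola, or Km sits far beyond the data range
    slope = float(np.sum(s * v) / np.sum(s * s))
    rss_lin = float(np.sum((v - slope * s) ** 2))
    unsaturated = km > 5.0 * s.max() or (rss_lin - rss) <= 1e-3 * max(rss_lin, 1e-300)
    flag = "unsaturated" if unsaturated else "ok"

    fit = MMFit(
        vmax=vmax,
        km=km,
        vmax_se=vmax_se,
        km_se=km_se,
        rss=rss,
        converged=bool(best.success) and not unsaturated,
        flag=flag,
        n_points=len(v),
    )

    if velocity_is_specific_activity:
        fit.specific_activity = vmax
        if molar_mass is not None:
            # µmol/min/mg * g/mol -> s^-1
            fit.kcat = vmax * molar_mass / 6.0e4
            fit.kcat_se = vmax_se * molar_mass / 6.0e4
    else:
        if enzyme_conc is not None:
            fit.kcat = vmax / enzyme_conc
            fit.kcat_se = vmax_se / enzyme_conc
            if molar_mass is not None:
                # M/s / M = s^-1; back to µmol/min/mg
                fit.specific_activity = fit.kcat * 6.0e4 / molar_mass
    if fit.kcat is not None and km_to_molar is not None:
        km_molar = km * km_to_molar
        fit.efficiency = fit.kcat / km_molar
        rel = np.hypot(
            (fit.kcat_se or 0.0) / fit.kcat if fit.kcat else 0.0,
            km_se / km if km else 0.0,
        )
        fit.efficiency_se = abs(fit.efficiency) * rel
    return fit


@dataclass
class SubstrateRanking:
    """Substrates ordered by decreasing catalytic efficiency, with the
    spread (max - min efficiency) that summarises how discriminating the
    enzyme is."""

    order: list[tuple[str, float]]
    spread: float

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.order]


def rank_substrates(fits: dict[str, "MMFit | float"]) -> SubstrateRanking:
    """Rank substrates by kcat/Km (descending, stable for ties).

    Accepts a mapping substrate -> MMFit (using ``.efficiency``) or
    substrate -> efficiency value. Substrates without an efficiency are
    excluded with a warning.
    """
    pairs: list[tuple[str, float]] = []
    for name, fit in fits.items():
        eff = fit.efficiency if isinstance(fit, MMFit) else fit
        if eff is None or not np.isfinite(eff):
            warnings.warn(f"substrate {name!r} has no efficiency; excluded from ranking")
            continue
        pairs.append((name, float(eff)))
    if len(pairs) < 2:
        raise ValueError("ranking needs at least 2 substrates with efficiencies")
    order = sorted(pairs, key=lambda p: -p[1])  # Python sort is stable
    effs = [e for _, e in order]
    return SubstrateRanking(order=order, spread=float(max(effs) - min(effs)))


def fold_change(
    fit_num: MMFit, fit_den: MMFit, on: str = "specific_activity"
) -> tuple[float, float]:
    """Ratio of two fits' activities (or efficiencies) with propagated SE.

    Used for the D1D2-versus-D1 comparison that quantifies how tethering
    the membrane-distal D2 domain modulates the catalytic D1 domain.
    Returns ``(ratio, se)``.
    """
    if not (fit_num.converged and fit_den.converged):
        raise ValueError("both fits must have converged")
    attr = {"specific_activity": ("specific_activity", "vmax_se"),
            "efficiency": ("efficiency", "efficiency_se")}
    if on not in attr:
        raise ValueError(f"on must be one of {sorted(attr)}")
    name, se_name = attr[on]
    a = getattr(fit_num, name)
    b = getattr(fit_den, name)
    if a is None or b is None:
        raise ValueError(f"{name} not available on both fits")
    if b == 0:
        raise ZeroDivisionError(f"denominator {name} is zero")
    sa = getattr(fit_num, se_name) or 0.0
    sb = getattr(fit_den, se_name) or 0.0
    ratio = a / b
    se = abs(ratio) * float(np.hypot(sa / a if a else 0.0, sb / b))
    return float(ratio), se
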
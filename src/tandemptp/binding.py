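"""Equilibrium ligand-binding and SPR kinetic fits with one-site and
two-independent-site models.

Equilibrium (fluorescence quench) titrations follow
F(L) = F0 - sum_i A_i * L / (KD_i + L); SPR sensograms follow independent
Langmuir sites with association
R_i(t) = Rmax_i * C/(C+KD_i) * (1 - exp(-(ka_i*C + kd_i) t)) and
exponential dissociation. SPR fitting is global: one (ka, kd, Rmax) set
shared across all analyte concentrations, which is what makes the rate
constants identifiable. Rate parameters are fitted in log10 space
(positivity plus scale-free steps); sites are reported in ascending-KD
order so fits are invariant to site relabelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

__all__ = [
    "SiteBindingFit",
    "SPRKineticFit",
    "SPRSite",
    "fit_site_binding",
    "fit_sensogram_kinetics",
    "equilibrium_check",
]

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Equilibrium titrations
# ---------------------------------------------------------------------------

@dataclass
class SiteBindingFit:
    """Equilibrium fit: per-site (kd, amplitude) ascending in kd, plus the
    baseline F0. ``model_comparison_p`` holds the F-test p-value of the
    two-site model against the nested one-site model (populated for
    n_sites=2); a large p means the second site is not supported."""

    n_sites: int
    sites: list[tuple[float, float]]
    site_ses: list[tuple[float, float]]
    f0: float
    f0_se: float
    rss: float
    converged: bool
    model_comparison_p: float | None = None


def _titration_model(conc, f0, kds, amps, quench):
    sign = -1.0 if quench else 1.0
    f = np.full_like(conc, f0, dtype=float)
    for kd, a in zip(kds, amps):
        f += sign * a * conc / (kd + conc)
    return f


def _fit_titration_once(conc, signal, n_sites, quench, start_kds, start_amps, f00):
    params = lmfit.Parameters()
    params.add("f0", value=f00)
    for i in range(n_sites):
        params.add(f"lkd{i}", value=np.log10(start_kds[i]))
        params.add(f"a{i}", value=start_amps[i], min=0.0)

    def resid(p):
        kds = [10.0 ** p[f"lkd{i}"].value for i in range(n_sites)]
        amps = [p[f"a{i}"].value for i in range(n_sites)]
        return _titration_model(conc, p["f0"].value, kds, amps, quench) - signal

    return lmfit.minimize(resid, params, method="least_squares")


def fit_site_binding(
    titration: pd.DataFrame, n_sites: int, quench: bool = True
) -> SiteBindingFit:
    """Fit a one- or two-independent-site equilibrium binding model to a
    titration table (columns ``ligand_conc``, ``signal``).

    For n_sites=2 the nested one-site model is also fitted and compared by
    an F-test on the residual sums of squares; an insignificant
    improvement (p > 0.05) triggers a warning — the data are then
    indistinguishable from single-site binding.
    """
    if n_sites not in (1, 2):
        raise ValueError("n_sites must be 1 or 2")
    conc = titration["ligand_conc"].to_numpy(dtype=float)
    signal = titration["signal"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 5:
        raise ValueError("need at least 5 distinct ligand concentrations")

    f00 = float(signal[np.argmin(conc)])
    amp_tot = float(abs(signal.max() - signal.min()))
    mid = float(np.median(conc[conc > 0]))
    if n_sites == 1:
        start_sets = [([mid], [amp_tot]), ([mid / 10], [amp_tot]), ([mid * 10], [amp_tot])]
    else:
        start_sets = [
            ([mid / 30, mid * 3], [amp_tot / 2] * 2),
            ([mid / 3, mid * 30], [amp_tot / 2] * 2),
            ([mid, mid * 10], [amp_tot / 2] * 2),
        ]

    best = None
    for kds0, amps0 in start_sets:
        try:
            res = _fit_titration_once(conc, signal, n_sites, quench, kds0, amps0, f00)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("titration fit failed from all starts")

    sites, ses = [], []
    for i in range(n_sites):
        lkd = best.params[f"lkd{i}"]
        a = best.params[f"a{i}"]
        kd = 10.0 ** lkd.value
        kd_se = kd * LN10 * (lkd.stderr or np.nan)
        sites.append((float(kd), float(a.value)))
        ses.append((float(kd_se), float(a.stderr or np.nan)))
    order = np.argsort([kd for kd, _ in sites], kind="stable")
    sites = [sites[i] for i in order]
    ses = [ses[i] for i in order]

    p_value = None
    if n_sites == 2:
        one = fit_site_binding(titration, 1, quench)
        df2 = len(signal) - (1 + 2 * 2)
        d_df = 2
        if best.chisqr > 0 and df2 > 0:
            f_stat = ((one.rss - best.chisqr) / d_df) / (best.chisqr / df2)
            p_value = float(stats.f.sf(max(f_stat, 0.0), d_df, df2))
        else:
            p_value = 0.0
        if p_value > 0.05:
            warnings.warn(
                "two-site fit not significantly better than one site "
                f"(F-test p = {p_value:.3g}); data may be single-site"
            )

    return SiteBindingFit(
        n_sites=n_sites,
        sites=sites,
        site_ses=ses,
        f0=float(best.params["f0"].value),
        f0_se=float(best.params["f0"].stderr or np.nan),
        rss=float(best.chisqr),
        converged=bool(best.success),
        model_comparison_p=p_value,
    )


# ---------------------------------------------------------------------------
# SPR kinetics
# ---------------------------------------------------------------------------

@dataclass
class SPRSite:
    """One fitted Langmuir site. ``kd_eq`` is the identity kd/ka (M),
    never an independently fitted parameter."""

    ka: float
    kd: float
    rmax: float
    ka_se: float = np.nan
    kd_se: float = np.nan
    rmax_se: float = np.nan
    kd_eq_se: float = np.nan

    @property
    def kd_eq(self) -> float:
        return self.kd / self.ka


@dataclass
class SPRKineticFit:
    """Global SPR kinetic fit across analyte concentrations: shared
    (ka, kd, Rmax) per site, sites ordered by ascending equilibrium KD
    (zero-amplitude sites last)."""

    n_sites: int
    sites: list[SPRSite]
    rss: float
    converged: bool
    concs: list[float] = field(default_factory=list)


def _spr_predict(t, t_assoc, conc, kas, kds, rmaxs):
    total = np.zeros_like(t, dtype=float)
    for ka, kd, rmax in zip(kas, kds, rmaxs):
        kd_eq = kd / ka
        req = rmax * conc / (conc + kd_eq)
        kobs = ka * conc + kd
        r_end = req * (1.0 - np.exp(-kobs * t_assoc))
        assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
        dissoc = r_end * np.exp(-kd * np.maximum(t - t_assoc, 0.0))
        total += np.where(t <= t_assoc, assoc, dissoc)
    return total


def _group_sensograms(sensograms: pd.DataFrame):
    groups = []
    for conc, sub in sensograms.groupby("conc_M", sort=True):
        t = sub["time_s"].to_numpy(dtype=float)
        r = sub["response_RU"].to_numpy(dtype=float)
        phase = sub["phase"].to_numpy()
        if not (phase == "assoc").any() or not (phase == "dissoc").any():
            raise ValueError(
                f"sensogram at {conc} M lacks an association or dissociation phase"
            )
        t_assoc = float(t[phase == "assoc"].max())
        groups.append((float(conc), t, r, t_assoc))
    if len(groups) < 3:
        raise ValueError("global SPR fit needs sensograms at >= 3 analyte concentrations")
    return groups


def _check_identifiable(groups) -> None:
    """Reject data where neither phase carries rate information: a flat
    dissociation phase combined with an association phase that never
    approaches a plateau."""
    conc, t, r, t_assoc = max(groups, key=lambda g: g[0])
    assoc = t <= t_assoc
    r_assoc, r_dissoc = r[assoc], r[~assoc]
    scale = float(np.max(np.abs(r))) or 1.0
    drop = (r_dissoc[0] - r_dissoc[-1]) / scale if r_dissoc.size > 1 else 0.0
    n_tail = max(2, r_assoc.size // 10)
    tail_rise = (r_assoc[-1] - r_assoc[-n_tail]) / scale
    if drop < 1e-3 and tail_rise > 0.01:
        raise ValueError(
            "kinetics unidentifiable: dissociation is flat and association "
            "has not reached saturation"
        )


def _kd_estimates(groups) -> tuple[float, float]:
    """Fast/slow dissociation-rate guesses from the highest-concentration
    dissociation phase (early vs late log-linear slope)."""
    conc, t, r, t_assoc = max(groups, key=lambda g: g[0])
    mask = t > t_assoc
    td, rd = t[mask] - t_assoc, np.maximum(r[mask], 1e-9)
    n = td.size

    def slope(seg):
        tt, rr = td[seg], np.log(rd[seg])
        if tt.size < 3:
            return 1e-3
        b = np.polyfit(tt, rr, 1)[0]
        return max(-b, 1e-7)

    early = slice(0, max(3, n // 10))
    late = slice(max(0, n - n // 2), n)
    return slope(early), slope(late)


def _fit_spr_once(groups, n_sites, start, rmax_fixed):
    params = lmfit.Parameters()
    for i in range(n_sites):
        la0, ld0, rm0 = start[i]
        params.add(f"lka{i}", value=la0, min=-6, max=10)
        params.add(f"lkd{i}", value=ld0, min=-10, max=4)
        fixed = rmax_fixed[i] if rmax_fixed is not None else None
        if fixed is not None:
            params.add(f"rmax{i}", value=float(fixed), vary=False)
        else:
            params.add(f"rmax{i}", value=rm0, min=0.0)

    def resid(p):
        kas = [10.0 ** p[f"lka{i}"].value for i in range(n_sites)]
        kds = [10.0 ** p[f"lkd{i}"].value for i in range(n_sites)]
        rmaxs = [p[f"rmax{i}"].value for i in range(n_sites)]
        out = [
            _spr_predict(t, t_assoc, conc, kas, kds, rmaxs) - r
            for conc, t, r, t_assoc in groups
        ]
        return np.concatenate(out)

    return lmfit.minimize(resid, params, method="least_squares")


def fit_sensogram_kinetics(
    sensograms: pd.DataFrame,
    n_sites: int,
    rmax_fixed: list | None = None,
) -> SPRKineticFit:
    """Globally fit one- or two-independent-site Langmuir kinetics to
    sensograms at several analyte concentrations.

    Parameters
    ----------
    sensograms
        Table with columns ``time_s, response_RU, conc_M, phase``
        (phase in {assoc, dissoc}); at least 3 concentrations.
    n_sites
        1 or 2 independent sites.
    rmax_fixed
        Optional per-site list; a non-None entry fixes that site's Rmax
        (e.g. ``[None, 0.0]`` collapses the second site).

    The fit shares (ka, kd, Rmax) across concentrations and uses several
    deterministic starts built from dissociation slopes and the
    association half-time, keeping the best by residual sum of squares.
    """
    if n_sites not in (1, 2):
        raise ValueError("n_sites must be 1 or 2")
    groups = _group_sensograms(sensograms)
    _check_identifiable(groups)

    cmax, t, r, t_assoc = max(groups, key=lambda g: g[0])
    rmax0 = 1.05 * float(np.max(r))
    kd_fast, kd_slow = _kd_estimates(groups)
    # association time-to-63% at the highest concentration -> kobs
    assoc = t <= t_assoc
    ra = r[assoc]
    target = 0.63 * ra[-1]
    idx = np.argmax(ra >= target) if np.any(ra >= target) else len(ra) - 1
    t63 = max(float(t[assoc][idx]), np.diff(t[assoc]).min() if assoc.sum() > 1 else 1.0)
    kobs = 1.0 / t63
    ka0 = max((kobs - kd_slow) / cmax, 1e-4)

    if n_sites == 1:
        starts = [
            [(np.log10(ka0), np.log10(kd_slow), rmax0)],
            [(np.log10(ka0 * 10), np.log10(kd_fast), rmax0)],
            [(np.log10(ka0 / 10), np.log10(kd_slow), rmax0)],
        ]
    else:
        half = rmax0 / 2.0
        starts = [
            [(np.log10(ka0), np.log10(kd_slow), half),
             (np.log10(ka0 * 100), np.log10(kd_fast), half)],
            [(np.log10(ka0), np.log10(kd_fast), half),
             (np.log10(ka0 * 100), np.log10(kd_slow), half)],
            [(np.log10(ka0 / 10), np.log10(kd_slow), half),
             (np.log10(ka0 * 10), np.log10(kd_fast), half)],
            [(np.log10(ka0), np.log10(kd_slow), half),
             (np.log10(ka0 * 1000), np.log10(kd_fast * 10), half)],
        ]

    best = None
    for start in starts:
        try:
            res = _fit_spr_once(groups, n_sites, start, rmax_fixed)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("SPR fit failed from all starts")

    sites = []
    var_names = list(best.var_names)
    covar = getattr(best, "covar", None)
    for i in range(n_sites):
        lka, lkd = best.params[f"lka{i}"], best.params[f"lkd{i}"]
        rmax = best.params[f"rmax{i}"]
        ka, kd = 10.0 ** lka.value, 10.0 ** lkd.value
        ka_se = ka * LN10 * (lka.stderr or np.nan)
        kd_se = kd * LN10 * (lkd.stderr or np.nan)
        kd_eq_se = np.nan
        if covar is not None and f"lka{i}" in var_names and f"lkd{i}" in var_names:
            ia, id_ = var_names.index(f"lka{i}"), var_names.index(f"lkd{i}")
            var_log = covar[id_, id_] + covar[ia, ia] - 2.0 * covar[id_, ia]
            if var_log >= 0:
                kd_eq_se = (kd / ka) * LN10 * np.sqrt(var_log)
        sites.append(
            SPRSite(
                ka=float(ka), kd=float(kd), rmax=float(rmax.value),
                ka_se=float(ka_se), kd_se=float(kd_se),
                rmax_se=float(rmax.stderr or np.nan), kd_eq_se=float(kd_eq_se),
            )
        )
    # canonical order: active sites ascending KD, zero-amplitude sites last
    sites.sort(key=lambda s: (s.rmax <= 0, s.kd_eq))
    return SPRKineticFit(
        n_sites=n_sites,
        sites=sites,
        rss=float(best.chisqr),
        converged=bool(best.success),
        concs=[g[0] for g in groups],
    )


def equilibrium_check(fit: SPRKineticFit, conc: float) -> float:
    """Predicted equilibrium plateau sum_i Rmax_i * C / (C + KD_i) — a
    consistency diagnostic against the long-time limit of the association
    phase."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return float(sum(s.rmax * conc / (conc + s.kd_eq) for s in fit.sites))
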
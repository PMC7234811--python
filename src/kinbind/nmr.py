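"""NMR observables for backbone-amide analysis of the inhibitor.

Implements the standard per-residue quantities used to map the binding
interface and dynamics: compounded chemical-shift perturbation (CSP, with the
0.154 nitrogen scaling), steady-state heteronuclear NOE with its propagated
error, CPMG effective transverse relaxation (R2,eff over a 40 ms relaxation
period) and the exchange contribution ΔRex, two-time-point PRE-Γ2 with full
error propagation, σ-band classification of PRE profiles, and bound-minus-free
difference profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import (
    InsufficientDataError,
    InvalidStateError,
    NoOverlapError,
)

__all__ = [
    "csp",
    "csp_table",
    "hetnoe",
    "r2eff",
    "delta_rex",
    "pre_gamma2",
    "classify_pre",
    "delta_profiles",
    "fit_decay_rate",
    "reduce_peak_table",
    "NITROGEN_SCALING",
]

#: Scaling factor applied to the nitrogen shift in the compounded CSP.
NITROGEN_SCALING = 0.154


def csp(delta_hn, delta_n):
    """Compounded chemical shift perturbation, ppm.

    Δδ = sqrt(Δδ_HN² + (0.154 Δδ_N)²); accepts scalars or arrays.
    """
    delta_hn = np.asarray(delta_hn, float)
    delta_n = np.asarray(delta_n, float)
    if not (np.all(np.isfinite(delta_hn)) and np.all(np.isfinite(delta_n))):
        raise InvalidStateError("shift differences must be finite")
    out = np.sqrt(delta_hn**2 + (NITROGEN_SCALING * delta_n) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-residue CSP plus the table mean and standard deviation.

    ``table`` needs columns ``residue, delta_hn, delta_n``; the returned
    frame carries ``csp`` per residue with the mean/std in ``attrs`` (used to
    draw the significance threshold lines mean + nσ).
    """
    if table["residue"].duplicated().any():
        raise InvalidStateError("residue ids must be unique")
    out = table[["residue"]].copy()
    out["csp"] = csp(table["delta_hn"].to_numpy(), table["delta_n"].to_numpy())
    out.attrs["mean"] = float(out["csp"].mean())
    out.attrs["std"] = float(out["csp"].std(ddof=1))
    return out


def hetnoe(i_sat, i_unsat, sigma_sat=0.0, sigma_unsat=0.0):
    """Heteronuclear NOE ratio and its propagated error.

    NOE = Isat/Iunsat; σNOE = |NOE| sqrt((σsat/Isat)² + (σunsat/Iunsat)²).
    """
    i_sat = np.asarray(i_sat, float)
    i_unsat = np.asarray(i_unsat, float)
    if np.any(i_unsat == 0):
        raise InvalidStateError("unsaturated intensity is zero: NOE undefined")
    noe = i_sat / i_unsat
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt((np.asarray(sigma_sat, float) / i_sat) ** 2
                      + (np.asarray(sigma_unsat, float) / i_unsat) ** 2)
    sigma = np.abs(noe) * rel
    if np.ndim(noe) == 0:
        return float(noe), float(sigma)
    return noe, sigma


def r2eff(i0, i, total_time: float = 0.040):
    """Effective transverse relaxation rate, R2,eff = ln(I0/I)/T (s^-1).

    I >= I0 yields a non-positive rate and is allowed (flagged by the
    caller); non-positive intensities are undetectable.
    """
    i0 = np.asarray(i0, float)
    i = np.asarray(i, float)
    if total_time <= 0:
        raise InvalidStateError("total CPMG time must be > 0")
    if np.any(i0 <= 0) or np.any(i <= 0):
        raise InvalidStateError("non-positive intensity: peak undetectable")
    out = np.log(i0 / i) / total_time
    return float(out) if out.ndim == 0 else out


def delta_rex(r2eff_low, r2eff_high):
    """Exchange contribution ΔRex = R2,eff(low νCPMG) − R2,eff(high νCPMG).

    Convention: lowest nonzero refocusing frequency (12.5 Hz) minus the
    highest (1000 Hz).
    """
    return np.asarray(r2eff_low, float) - np.asarray(r2eff_high, float)


def pre_gamma2(i_para_ta, i_para_tb, i_dia_ta, i_dia_tb, ta: float, tb: float,
               sigma_para=0.0, sigma_dia=0.0):
    """Two-time-point PRE-Γ2 and its propagated error (s^-1).

    Γ2 = ln[(Idia(Tb) Ipara(Ta)) / (Idia(Ta) Ipara(Tb))] / (Tb − Ta);
    σΓ2 adds the four relative spectral-noise terms in quadrature.  Any
    non-positive intensity marks the residue as broadened beyond detection.
    """
    if not tb > ta > 0:
        raise InvalidStateError("delays must satisfy Tb > Ta > 0")
    vals = [np.asarray(v, float) for v in (i_para_ta, i_para_tb, i_dia_ta, i_dia_tb)]
    if any(np.any(~np.isfinite(v)) or np.any(v <= 0) for v in vals):
        raise InvalidStateError("non-positive intensity: residue undetectable")
    ipa, ipb, ida, idb = vals
    dt = tb - ta
    gamma2 = np.log((idb * ipa) / (ida * ipb)) / dt
    sp = np.asarray(sigma_para, float)
    sd = np.asarray(sigma_dia, float)
    sigma = np.sqrt((sd / ida) ** 2 + (sd / idb) ** 2
                    + (sp / ipa) ** 2 + (sp / ipb) ** 2) / dt
    if np.ndim(gamma2) == 0:
        return float(gamma2), float(sigma)
    return gamma2, sigma


_BANDS = ("weak", "medium", "elevated", "strong")


def classify_pre(table: pd.DataFrame, value_col: str = "gamma2") -> pd.DataFrame:
    """σ-band classification of a per-residue PRE profile.

    Each detectable value is banded by its z-score against the table's own
    mean and standard deviation: weak < 1σ, medium in [1σ, 2σ), elevated in
    [2σ, 3σ), strong ≥ 3σ.  Rows flagged undetectable (NaN value) pass
    through with band ``'undetectable'``.  The classification is invariant
    under affine rescaling of the whole table.
    """
    vals = table[value_col].to_numpy(float)
    finite = np.isfinite(vals)
    if finite.sum() < 3:
        raise InsufficientDataError("need >= 3 finite values for mean and sigma")
    mean = vals[finite].mean()
    std = vals[finite].std(ddof=1)
    if std == 0:
        raise InvalidStateError("all values identical: sigma = 0, bands undefined")
    z = (vals - mean) / std
    band = np.where(z < 1, "weak",
                    np.where(z < 2, "medium",
                             np.where(z < 3, "elevated", "strong")))
    out = table.copy()
    out["z"] = z
    out["band"] = np.where(finite, band, "undetectable")
    out.loc[~finite, "z"] = np.nan
    out.attrs["mean"] = float(mean)
    out.attrs["std"] = float(std)
    out.attrs["thresholds"] = {f"mean+{n}sigma": float(mean + n * std)
                               for n in (1, 2, 3)}
    return out


def delta_profiles(free: pd.DataFrame, bound: pd.DataFrame,
                   on: str = "residue") -> tuple[pd.DataFrame, dict]:
    """Bound-minus-free differences for every shared numeric column.

    Returns (differences, unmatched) where ``unmatched`` lists residues
    present in only one table — they are reported, never silently dropped.
    """
    shared = free.merge(bound, on=on, suffixes=("_free", "_bound"))
    if shared.empty:
        raise NoOverlapError("free and bound tables share no residues")
    cols = [c for c in free.columns
            if c != on and c in bound.columns
            and np.issubdtype(free[c].dtype, np.number)]
    out = shared[[on]].copy()
    for c in cols:
        out[f"delta_{c}"] = shared[f"{c}_bound"] - shared[f"{c}_free"]
    unmatched = {
        "free_only": sorted(set(free[on]) - set(bound[on])),
        "bound_only": sorted(set(bound[on]) - set(free[on])),
    }
    return out, unmatched


def fit_decay_rate(delays, intensities):
    """Mono-exponential two-parameter fit I(t) = I0 exp(-R t).

    Used for the R1/R2 relaxation series; duplicated delays contribute to
    the residual-based error like any other point.  Returns (rate, rate_se,
    i0).
    """
    t = np.asarray(delays, float)
    y = np.asarray(intensities, float)
    if t.size < 3:
        raise InsufficientDataError("decay fit needs >= 3 delays")
    # log-linear start, then proper nonlinear refinement
    pos = y > 0
    slope, icept = np.polyfit(t[pos], np.log(y[pos]), 1)
    popt, pcov = optimize.curve_fit(
        lambda tt, i0, r: i0 * np.exp(-r * tt), t, y,
        p0=[np.exp(icept), -slope], maxfev=10000,
    )
    return float(popt[1]), float(np.sqrt(pcov[1, 1])), float(popt[0])


def reduce_peak_table(table: pd.DataFrame,
                      ta: float = 0.004, tb: float = 0.014,
                      cpmg_time: float = 0.040) -> pd.DataFrame:
    """Per-residue observables from a long-format peak-intensity table.

    Consumes the schema written by the synthetic generator (columns
    ``residue, channel, delay_s, nu_cpmg_hz, intensity, noise_rms, flag``)
    and returns one row per residue with ``noe, noe_sigma, r2eff_12p5,
    r2eff_1000, delta_rex, gamma2, gamma2_sigma`` (NaN where a needed peak
    is undetectable).
    """
    rows = []
    for residue, grp in table.groupby("residue", sort=True):
        rec: dict = {"residue": residue}

        def peak(channel, **sel):
            g = grp[grp["channel"] == channel]
            for col, val in sel.items():
                g = g[np.isclose(g[col], val)]
            if g.empty:
                return None, 0.0
            r = g.iloc[0]
            if r["flag"] == "undetectable" or not np.isfinite(r["intensity"]):
                return None, float(r["noise_rms"])
            return float(r["intensity"]), float(r["noise_rms"])

        i_sat, s_sat = peak("sat")
        i_unsat, s_unsat = peak("unsat")
        if i_sat is not None and i_unsat is not None:
            rec["noe"], rec["noe_sigma"] = hetnoe(i_sat, i_unsat, s_sat, s_unsat)
        else:
            rec["noe"] = rec["noe_sigma"] = np.nan

        i0, _ = peak("cpmg_ref")
        for nu, name in ((12.5, "r2eff_12p5"), (1000.0, "r2eff_1000")):
            i_nu, _ = peak("cpmg", nu_cpmg_hz=nu)
            rec[name] = (r2eff(i0, i_nu, cpmg_time)
                         if i0 is not None and i_nu is not None else np.nan)
        rec["delta_rex"] = rec["r2eff_12p5"] - rec["r2eff_1000"]

        ipa, spa = peak("para", delay_s=ta)
        ipb, _ = peak("para", delay_s=tb)
        ida, sda = peak("dia", delay_s=ta)
        idb, _ = peak("dia", delay_s=tb)
        if None not in (ipa, ipb, ida, idb):
            rec["gamma2"], rec["gamma2_sigma"] = pre_gamma2(
                ipa, ipb, ida, idb, ta, tb, sigma_para=spa, sigma_dia=sda)
        else:
            rec["gamma2"] = rec["gamma2_sigma"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
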
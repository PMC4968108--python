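"""Peak-area tables -> attribute levels and absolute drug concentrations.

Implements the MS data-processing rules of stable-isotope internal-calibrant
peptide quantitation:

* charge states of one peptide form are summed into a single peak area;
* an attribute's relative level is the modified peptide's area divided by
  the summed areas of all forms (modified and unmodified) of that peptide;
* absolute concentration is the light/heavy area ratio scaled by the known
  calibrant amount per serum volume;
* total drug concentration is the unweighted mean over a reference panel of
  high-intensity peptides free of modifications and assay carryover;
* peptides clearing faster than the total drug (in vivo terminal
  degradation) are flagged by the slope of log(peptide/total) against time.

Missing data are flagged as NaN, never imputed as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "StandardCurve",
    "DegenerateCurveError",
    "merge_charge_states",
    "relative_percent",
    "absolute_concentration",
    "fit_standard_curve",
    "select_reference_peptides",
    "total_concentration",
    "terminal_degradation_screen",
    "quantify_study",
]

_KEY = ["subject", "time_days", "peptide_id", "mod_form"]

#: light/heavy ratios below this floor are treated as below the assay's
#: quantitation limit and flagged missing in absolute quantitation
DEFAULT_LLOQ_RATIO = 1e-4

UNMODIFIED = "none"


class DegenerateCurveError(ValueError):
    """Standard curve has no concentration response (zero slope)."""


def merge_charge_states(raw: pd.DataFrame) -> pd.DataFrame:
    """Sum per-charge peak areas into one row per (subject, time, peptide, form).

    ``raw`` must carry a ``charge`` column; duplicate rows for the same
    charge state are contradictory exports and rejected.
    """
    if "charge" not in raw.columns:
        raise ValueError("raw table must have a 'charge' column")
    dup = raw.duplicated(subset=_KEY + ["charge"], keep=False)
    if dup.any():
        bad = raw.loc[dup, _KEY + ["charge"]].drop_duplicates()
        raise ValueError(f"conflicting duplicate rows for the same charge state:\n{bad}")
    merged = (
        raw.groupby(_KEY, as_index=False)[["light_area", "heavy_area"]]
        .sum()
        .sort_values(_KEY, kind="mergesort")
        .reset_index(drop=True)
    )
    return merged


def _peptide_slice(table: pd.DataFrame, peptide_id: str) -> pd.DataFrame:
    sub = table[table["peptide_id"] == peptide_id]
    if sub.empty:
        raise ValueError(f"peptide {peptide_id!r} not present in the table")
    return sub


def relative_percent(table: pd.DataFrame, peptide_id: str, mod_form: str) -> pd.DataFrame:
    """Relative level of ``mod_form`` on ``peptide_id`` per subject and time.

    fraction = area(mod_form) / sum of areas over all forms of the peptide.
    Returns a tidy frame (subject, time_days, value) with value the fraction
    in [0, 1]; time points where every form has zero area are flagged as NaN
    (no drug signal), not 0.
    """
    sub = _peptide_slice(table, peptide_id)
    if mod_form not in set(sub["mod_form"]):
        raise ValueError(f"form {mod_form!r} not observed for peptide {peptide_id!r}")
    wide = sub.pivot_table(
        index=["subject", "time_days"], columns="mod_form", values="light_area", aggfunc="sum"
    )
    denom = wide.sum(axis=1)
    frac = wide[mod_form].where(denom > 0) / denom.where(denom > 0)
    out = frac.rename("value").reset_index()
    return out.sort_values(["subject", "time_days"]).reset_index(drop=True)


def absolute_concentration(
    table: pd.DataFrame,
    peptide_id: str,
    calibrant_amount: float = 2.5,
    serum_volume: float = 12.5,
    lloq_ratio: float = DEFAULT_LLOQ_RATIO,
) -> pd.DataFrame:
    """Absolute drug concentration (ug/mL) from the light/heavy area ratio.

    Areas are summed over the peptide's forms; concentration =
    (light/heavy) * calibrant_amount[ug] / serum_volume[uL] * 1000. Points
    with zero heavy area, or with a nonzero ratio below ``lloq_ratio``, are
    flagged NaN. A ratio of exactly 0 (pre-dose) is a valid 0 concentration.
    """
    if calibrant_amount <= 0 or serum_volume <= 0:
        raise ValueError("calibrant_amount and serum_volume must be > 0")
    sub = _peptide_slice(table, peptide_id)
    g = sub.groupby(["subject", "time_days"], as_index=False)[["light_area", "heavy_area"]].sum()
    heavy = g["heavy_area"].to_numpy()
    light = g["light_area"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(heavy > 0, light / np.where(heavy > 0, heavy, 1.0), np.nan)
    ratio = np.where((ratio > 0) & (ratio < lloq_ratio), np.nan, ratio)
    scale = calibrant_amount / serum_volume * 1000.0  # ug/uL -> ug/mL
    out = g[["subject", "time_days"]].copy()
    out["value"] = ratio * scale
    return out.sort_values(["subject", "time_days"]).reset_index(drop=True)


@dataclass(frozen=True)
class StandardCurve:
    """OLS line of light/heavy ratio against spiked concentration."""

    slope: float
    intercept: float
    r_squared: float
    n_levels: int


def fit_standard_curve(curve: pd.DataFrame) -> StandardCurve:
    """Fit the spike-in response line; requires >= 3 concentration levels.

    A curve whose ratios do not respond to concentration (zero variance of
    the fitted response) has an undefined R^2 and is rejected as degenerate.
    """
    required = {"concentration", "light_area", "heavy_area"}
    if not required <= set(curve.columns):
        raise ValueError(f"curve table must have columns {sorted(required)}")
    levels = np.sort(curve["concentration"].unique())
    if levels.size < 3:
        raise ValueError(f"need >= 3 concentration levels, got {levels.size}")
    work = curve[curve["heavy_area"] > 0]
    x = work["concentration"].to_numpy(dtype=float)
    y = (work["light_area"] / work["heavy_area"]).to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    if res.ess <= 0 or np.isclose(slope, 0.0):
        raise DegenerateCurveError("standard curve has no concentration response (slope ~ 0)")
    # guard against float fuzz pushing a perfect fit epsilon outside [0, 1]
    r2 = float(min(1.0, max(0.0, res.rsquared)))
    return StandardCurve(slope=slope, intercept=float(res.params[0]), r_squared=r2,
                         n_levels=int(levels.size))


def select_reference_peptides(table: pd.DataFrame, k: int = 20) -> list[str]:
    """Reference panel for total-concentration averaging.

    Eligibility: the peptide has no modified form anywhere in the table and
    no light signal in the pre-dose (t = 0) sample of any subject. Eligible
    peptides are ranked by median light intensity across all samples,
    descending, ties broken lexicographically by id; the top ``k`` are
    returned. If fewer than ``k`` are eligible, all eligible ids are
    returned with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    has_mod = table.loc[table["mod_form"] != UNMODIFIED, "peptide_id"].unique()
    pre = table[table["time_days"] == 0]
    carryover = pre.loc[pre["light_area"] > 0, "peptide_id"].unique()
    excluded = set(has_mod) | set(carryover)
    eligible = table[~table["peptide_id"].isin(excluded)]
    if eligible.empty:
        raise ValueError("no eligible reference peptides (all modified or carryover)")
    med = eligible.groupby("peptide_id")["light_area"].median()
    ranked = sorted(med.index, key=lambda pid: (-med[pid], pid))
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} eligible reference peptides (requested {k}); using all",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]


def total_concentration(
    table: pd.DataFrame,
    reference_peptides: list[str],
    calibrant_amount: float = 2.5,
    serum_volume: float = 12.5,
    lloq_ratio: float = DEFAULT_LLOQ_RATIO,
) -> pd.DataFrame:
    """Unweighted mean of per-peptide absolute concentrations.

    Returns (subject, time_days, value, n_peptides, flagged); a time point is
    flagged when more than half the reference peptides are missing there.
    Missing peptides are dropped from the mean, never imputed.
    """
    if not reference_peptides:
        raise ValueError("reference peptide list must be non-empty")
    per = []
    for pid in reference_peptides:
        s = absolute_concentration(table, pid, calibrant_amount, serum_volume, lloq_ratio)
        s = s.assign(peptide_id=pid)
        per.append(s)
    stacked = pd.concat(per, ignore_index=True)
    g = stacked.groupby(["subject", "time_days"])["value"]
    out = g.mean().rename("value").reset_index()
    out["n_peptides"] = g.count().to_numpy()
    out["flagged"] = out["n_peptides"] < len(reference_peptides) / 2.0
    return out.sort_values(["subject", "time_days"]).reset_index(drop=True)


def terminal_degradation_screen(
    peptide_series: pd.DataFrame,
    total_series: pd.DataFrame,
    slope_threshold: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen peptides whose concentration decays faster than the total drug.

    For each peptide in ``peptide_series`` (tidy: subject, time_days, value,
    peptide_id — a single-peptide frame without the id column is accepted),
    regresses log(peptide/total) on time pooled over subjects and reports the
    slope (1/day), its standard error and p-value. A peptide is flagged when
    the slope is below ``-slope_threshold`` with p < ``alpha`` (one-sided
    rule: ratios rising over time are never flagged).
    """
    pep = peptide_series.copy()
    if "peptide_id" not in pep.columns:
        pep["peptide_id"] = "peptide"
    tot = total_series.rename(columns={"value": "total"})[["subject", "time_days", "total"]]
    reports = []
    for pid, sub in pep.groupby("peptide_id"):
        merged = sub.merge(tot, on=["subject", "time_days"], how="inner")
        merged = merged[(merged["value"] > 0) & (merged["total"] > 0)].dropna(
            subset=["value", "total"]
        )
        if merged["time_days"].nunique() < 3:
            raise ValueError(
                f"peptide {pid!r}: need >= 3 shared positive time points, "
                f"got {merged['time_days'].nunique()}"
            )
        y = np.log(merged["value"].to_numpy() / merged["total"].to_numpy())
        x = sm.add_constant(merged["time_days"].to_numpy(dtype=float))
        res = sm.OLS(y, x).fit()
        slope, se = float(res.params[1]), float(res.bse[1])
        pval = float(res.pvalues[1])
        flagged = bool(slope < -slope_threshold and pval < alpha)
        reports.append((pid, slope, se, pval, flagged))
    return pd.DataFrame(
        reports, columns=["peptide_id", "log_ratio_slope", "slope_se", "p_value", "flagged"]
    )


def quantify_study(
    table: pd.DataFrame,
    attributes: dict[str, str],
    k_reference: int = 20,
    calibrant_amount: float = 2.5,
    serum_volume: float = 12.5,
    screen_degradation: bool = True,
) -> dict:
    """One-call quantitation of a full study peak table.

    ``attributes`` maps attribute name -> reporter peptide id (the modified
    form label is the attribute name itself, as written by the generator).
    Selects the reference panel, optionally drops panel members that fail
    the terminal-degradation screen against the provisional panel mean, and
    returns total concentration, per-attribute fraction series, the panel
    and the screen report.
    """
    panel = select_reference_peptides(table, k=k_reference)
    screen = None
    if screen_degradation and len(panel) > 1:
        provisional = total_concentration(table, panel, calibrant_amount, serum_volume)
        per = pd.concat(
            [
                absolute_concentration(table, pid, calibrant_amount, serum_volume).assign(
                    peptide_id=pid
                )
                for pid in panel
            ],
            ignore_index=True,
        )
        screen = terminal_degradation_screen(per, provisional)
        dropped = set(screen.loc[screen["flagged"], "peptide_id"])
        if dropped:
            panel = [p for p in panel if p not in dropped]
    total = total_concentration(table, panel, calibrant_amount, serum_volume)
    fractions = {
        name: relative_percent(table, pep, name) for name, pep in attributes.items()
    }
    return {
        "total_concentration": total,
        "fractions": fractions,
        "reference_peptides": panel,
        "degradation_screen": screen,
    }
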
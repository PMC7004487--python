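"""Bioluminescence ATP assay: standard-curve calibration and paired
comparison of stimulated release against artificial-saliva controls.

Luciferase light output is linear in [ATP] over the nM range the assay
uses, so relative light units (RLU) are calibrated with an ordinary
least-squares line through the known standards and back-converted as
``[ATP] = (RLU − intercept)/slope``. Stimulated wells are paired with the
matched artificial-saliva well of the same preparation; the per-condition
comparison is a two-sided paired t test on the converted concentrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import StandardCurve, StatResult
from .stats import paired_t

__all__ = ["fit_standard_curve", "convert_to_concentration", "convert_and_compare"]

CONTROL_CONDITION = "artificial saliva"


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """OLS fit of RLU on known [ATP] (nM) over the standard wells.

    ``standards`` needs columns ``concentration_nM`` and ``rlu`` with at
    least 3 distinct concentrations. Raises when the fitted slope is not
    positive (failed assay).
    """
    conc = np.asarray(standards["concentration_nM"], dtype=float)
    rlu = np.asarray(standards["rlu"], dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    fit = sps.linregress(conc, rlu)
    if fit.slope <= 0:
        raise ValueError(
            f"non-positive standard-curve slope ({fit.slope:.3g}): assay invalid"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def convert_to_concentration(
    readings: pd.DataFrame, curve: StandardCurve
) -> pd.DataFrame:
    """Back-convert RLU to [ATP] (nM); clip negatives to 0 with a flag.

    Adds ``concentration_nM``, ``clipped`` (negative back-calculation) and
    ``extrapolated`` (outside the fitted standard range) columns.
    """
    out = readings.copy()
    conc = curve.to_concentration(out["rlu"].to_numpy())
    out["clipped"] = conc < 0
    out["concentration_nM"] = np.clip(conc, 0.0, None)
    lo, hi = curve.conc_range
    out["extrapolated"] = (conc < lo) | (conc > hi)
    return out


def convert_and_compare(
    readings: pd.DataFrame, curve: StandardCurve
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concentrations per well plus paired tests vs artificial saliva.

    ``readings`` needs columns ``condition``, ``rlu`` and ``preparation``
    (the pairing unit: one trial/preparation measured once per
    condition). Standards rows (condition ``"standard"``) are ignored
    here. Returns the converted per-well table (with ``ratio_vs_saliva``)
    and a per-condition summary with the paired t statistic, df = n−1 and
    two-sided p. Raises listing offending preparations when a stimulated
    preparation lacks its matched saliva measurement.
    """
    wells = readings.loc[readings["condition"] != "standard"].copy()
    wells = convert_to_concentration(wells, curve)
    saliva = wells.loc[wells["condition"] == CONTROL_CONDITION]
    if saliva.empty:
        raise ValueError("no artificial-saliva control wells present")
    saliva_by_prep = saliva.set_index("preparation")["concentration_nM"]
    if saliva_by_prep.index.duplicated().any():
        raise ValueError("multiple saliva wells for one preparation")

    stim = wells.loc[wells["condition"] != CONTROL_CONDITION]
    unmatched = sorted(set(stim["preparation"]) - set(saliva_by_prep.index))
    if unmatched:
        raise ValueError(
            f"stimulated preparations without a matched saliva well: {unmatched}"
        )
    wells["saliva_nM"] = wells["preparation"].map(saliva_by_prep)
    with np.errstate(divide="ignore", invalid="ignore"):
        wells["ratio_vs_saliva"] = np.where(
            wells["saliva_nM"] > 0,
            wells["concentration_nM"] / wells["saliva_nM"],
            np.nan,
        )

    summaries = []
    for condition, sub in stim.groupby("condition", observed=True):
        paired = saliva_by_prep.loc[sub["preparation"]].to_numpy()
        x = sub["concentration_nM"].to_numpy()
        try:
            res: StatResult = paired_t(x, paired)
            t, df, p = res.statistic, res.df, res.p_value
            degenerate = False
        except ValueError:
            # constant nonzero differences: t undefined, flagged not faked
            t, df, p = np.nan, len(x) - 1, np.nan
            degenerate = True
        summaries.append(
            {
                "condition": condition,
                "n_pairs": len(x),
                "mean_concentration_nM": float(sub["concentration_nM"].mean()),
                "mean_ratio_vs_saliva": float(
                    wells.loc[wells["condition"] == condition, "ratio_vs_saliva"].mean()
                ),
                "t": t,
                "df": df,
                "p": p,
                "degenerate": degenerate,
            }
        )
    return wells, pd.DataFrame(summaries)
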
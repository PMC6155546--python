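"""qPCR-calibrated absolute quantification and deviation statistics.

Three pieces reproduce the quantification framework:

* Ct -> CFU.g^-1 conversion via the linear calibrations
  CFU = exp((Ct - intercept) / slope), with the published constants
  (39.43, -1.52) for 16S probes and (40.98, -1.44) for housekeeping probes;
* conversion of relative read counts to absolute reads,
  na = nr x Q / Nt, where Q is the total bacterial load of the sample
  (all-bacteria qPCR) and Nt the normalized per-sample read sum;
* per-stratum (phylum x marker) ordinary least squares of log10(na) on
  log10(qPCR CFU), with per-species median deviations from the fitted line.
  Positive deviations mean the marker overestimates a species' relative
  abundance, negative deviations an underestimate; |median| < 0.1 log10 is
  reported as unbiased.

Species with zero reads are excluded from log-space fitting and reported as
not detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from gyrbench.synthetic_data import CalibrationCurve, CURVE_16S, CURVE_HOUSEKEEPING

__all__ = [
    "ct_to_cfu",
    "cfu_to_ct",
    "to_absolute",
    "RegressionFit",
    "fit_quant_model",
    "species_deviation",
    "build_quant_records",
    "UNBIASED_BAND",
]

#: |median deviation| below this (log10 units) is called unbiased.
UNBIASED_BAND = 0.1

_CURVES = {"16S": CURVE_16S, "housekeeping": CURVE_HOUSEKEEPING}


def ct_to_cfu(ct: float, curve: CalibrationCurve | str) -> float:
    """Population estimate in CFU.g^-1 from a threshold cycle."""
    if isinstance(curve, str):
        curve = _CURVES[curve]
    if not math.isfinite(ct):
        raise ValueError(f"Ct must be finite, got {ct}")
    return math.exp((ct - curve.intercept) / curve.slope)


def cfu_to_ct(cfu: float, curve: CalibrationCurve | str) -> float:
    """Inverse calibration: expected Ct at a given load."""
    if isinstance(curve, str):
        curve = _CURVES[curve]
    if cfu <= 0:
        raise ValueError(f"CFU must be > 0, got {cfu}")
    return curve.intercept + curve.slope * math.log(cfu)


def to_absolute(nr: float, q: float, nt: float) -> float:
    """Absolute read count na = nr x Q / Nt."""
    if nt <= 0:
        raise ValueError(f"Nt must be > 0, got {nt}")
    if q <= 0:
        raise ValueError(f"Q must be > 0, got {q}")
    if nr < 0:
        raise ValueError(f"nr must be >= 0, got {nr}")
    return nr * q / nt


@dataclass
class RegressionFit:
    """OLS of log10(na) on log10(CFU) within one stratum."""

    stratum: str
    slope: float
    intercept: float
    r2: float
    residuals: pd.Series  # log10 units, indexed like the input rows

    def predict(self, log10_cfu: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(log10_cfu, dtype=float)


def fit_quant_model(records: pd.DataFrame, stratum: str = "") -> RegressionFit:
    """Fit log10(na) ~ log10(cfu) by ordinary least squares.

    ``records`` needs columns ``na`` and ``cfu``; rows with na == 0 (species
    not detected) are excluded from log space. Requires >= 3 usable points.
    """
    usable = records[(records["na"] > 0) & (records["cfu"] > 0)]
    if len(usable) < 3:
        raise ValueError(
            f"stratum {stratum or '<all>'}: need >= 3 detected points, got {len(usable)}"
        )
    x = np.log10(usable["cfu"].to_numpy(dtype=float))
    y = np.log10(usable["na"].to_numpy(dtype=float))
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    return RegressionFit(
        stratum=stratum,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        residuals=pd.Series(y - fitted, index=usable.index),
    )


def species_deviation(fit: RegressionFit, records: pd.DataFrame) -> pd.DataFrame:
    """Per-species deviation statistics against a fitted model.

    Deviation per observation = log10(na) - fitted value. Reports the signed
    median, the median absolute deviation from the line, and a sign call
    (overestimated / underestimated / unbiased within +/-0.1 log10).
    Species with no detected observation are reported as not detected.
    """
    rows = []
    for species, group in records.groupby("species"):
        detected = group[(group["na"] > 0) & (group["cfu"] > 0)]
        if detected.empty:
            rows.append(
                {
                    "species": species,
                    "n_obs": 0,
                    "median_deviation": np.nan,
                    "median_abs_deviation": np.nan,
                    "call": "not detected",
                }
            )
            continue
        dev = np.log10(detected["na"].to_numpy(dtype=float)) - np.asarray(
            fit.predict(np.log10(detected["cfu"].to_numpy(dtype=float)))
        )
        med = float(np.median(dev))
        if abs(med) < UNBIASED_BAND:
            call = "unbiased"
        else:
            call = "overestimated" if med > 0 else "underestimated"
        rows.append(
            {
                "species": species,
                "n_obs": int(len(dev)),
                "median_deviation": med,
                "median_abs_deviation": float(np.median(np.abs(dev))),
                "call": call,
            }
        )
    return pd.DataFrame(rows)


def build_quant_records(
    reads: pd.DataFrame,
    qpcr: pd.DataFrame,
    nt_by_sample: Mapping[str, float],
    phylum_by_species: Mapping[str, str] | None = None,
    marker: str = "gyrB",
) -> pd.DataFrame:
    """Join read counts with qPCR loads into quantification records.

    ``reads`` needs columns (species, sample, nr); ``qpcr`` columns
    (species, sample, Ct, curve) including ``all_bacteria`` rows that provide
    Q per sample. Output columns: species, sample, nr, Q, Nt, na, cfu,
    stratum.
    """
    qpcr = qpcr.copy()
    qpcr["cfu"] = [ct_to_cfu(ct, curve) for ct, curve in zip(qpcr["Ct"], qpcr["curve"])]
    totals = qpcr[qpcr["species"] == "all_bacteria"].set_index("sample")["cfu"]
    species_cfu = qpcr[qpcr["species"] != "all_bacteria"].set_index(["species", "sample"])["cfu"]

    rows = []
    for _, rec in reads.iterrows():
        sample, species = rec["sample"], rec["species"]
        if sample not in totals.index or (species, sample) not in species_cfu.index:
            continue
        q = float(totals[sample])
        nt = float(nt_by_sample[sample])
        nr = float(rec["nr"])
        na = to_absolute(nr, q, nt) if nr > 0 else 0.0
        stratum = (
            f"{phylum_by_species.get(species, 'unknown')}_{marker}"
            if phylum_by_species is not None
            else marker
        )
        rows.append(
            {
                "species": species,
                "sample": sample,
                "nr": nr,
                "Q": q,
                "Nt": nt,
                "na": na,
                "cfu": float(species_cfu[(species, sample)]),
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)
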
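"""Quantification formulas for the assays that accompany layer imaging.

* Stomatal index: SI = 100 * stomata / (stomata + other epidermal cells),
  the percentage of epidermal cells that are stomata.
* Stomatal density: SD = stomata per mm^2 of counted leaf area (the counting
  convention is a 400 um x 400 um region of interest, i.e. 0.16 mm^2).
* Relative gene expression by the 2^-ddCt method against a reference gene
  (e.g. UBC21 or UBQ10) and a calibrator condition, with amplification
  efficiency fixed at 2 and replicate dCt values averaged per condition.
* Dual-luciferase normalisation: firefly luminescence divided by the
  co-transfected Renilla luminescence (transfection control).

Hypothesis tests on these quantities (Welch's t-test, one-way ANOVA,
Holm-Sidak correction) are deliberately thin pass-throughs to scipy and
statsmodels and carry no logic of their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

DEFAULT_ROI_AREA_MM2 = 0.16  # 400 um x 400 um counting window


@dataclass
class CountRecord:
    """Stomata and (non-stomatal) epidermal-cell counts in one ROI."""

    sample_id: str
    stomata: int
    epidermal_cells: int
    roi_area_mm2: float = DEFAULT_ROI_AREA_MM2

    def __post_init__(self) -> None:
        if self.stomata < 0 or self.epidermal_cells < 0:
            raise ValueError("counts must be >= 0")
        if self.roi_area_mm2 <= 0:
            raise ValueError("roi_area_mm2 must be > 0")


@dataclass
class CtRecord:
    """One qPCR threshold-cycle measurement."""

    sample_id: str
    condition: str
    gene: str
    ct: float
    reference_gene: str = "UBC21"

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise ValueError("ct must be > 0")


@dataclass
class LucRecord:
    """Paired firefly / Renilla luminescence readings from one well."""

    sample_id: str
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.firefly < 0:
            raise ValueError("firefly luminescence must be >= 0")
        if not self.renilla > 0:
            raise ValueError("no transfection-control signal: renilla must be > 0")


def stomatal_index(rec_or_stomata: Union[CountRecord, int],
                   epidermal_cells: int | None = None) -> float:
    """Stomatal index in percent: 100 * stomata / (stomata + epidermal cells).

    Accepts a :class:`CountRecord` or the two counts directly.
    """
    if isinstance(rec_or_stomata, CountRecord):
        stomata, cells = rec_or_stomata.stomata, rec_or_stomata.epidermal_cells
    else:
        if epidermal_cells is None:
            raise TypeError("pass a CountRecord or (stomata, epidermal_cells)")
        stomata, cells = int(rec_or_stomata), int(epidermal_cells)
    if stomata < 0 or cells < 0:
        raise ValueError("counts must be >= 0")
    if stomata + cells == 0:
        raise ValueError("stomatal index undefined: no cells counted")
    return 100.0 * stomata / (stomata + cells)


def stomatal_density(rec_or_stomata: Union[CountRecord, int],
                     roi_area_mm2: float | None = None) -> float:
    """Stomatal density: stomata per mm^2 of counted area."""
    if isinstance(rec_or_stomata, CountRecord):
        stomata, area = rec_or_stomata.stomata, rec_or_stomata.roi_area_mm2
    else:
        if roi_area_mm2 is None:
            raise TypeError("pass a CountRecord or (stomata, roi_area_mm2)")
        stomata, area = int(rec_or_stomata), float(roi_area_mm2)
    if area <= 0:
        raise ValueError("roi_area_mm2 must be > 0")
    return stomata / area


def count_table(records: Iterable[CountRecord]) -> pd.DataFrame:
    """Per-sample SI and SD table from count records."""
    rows = [
        {
            "sample_id": r.sample_id,
            "stomata": r.stomata,
            "epidermal_cells": r.epidermal_cells,
            "roi_area_mm2": r.roi_area_mm2,
            "stomatal_index": stomatal_index(r),
            "stomatal_density": stomatal_density(r),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _ct_frame(records: Union[Iterable[CtRecord], pd.DataFrame]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "sample_id": r.sample_id,
                "condition": r.condition,
                "gene": r.gene,
                "ct": r.ct,
                "reference_gene": r.reference_gene,
            }
            for r in records
        )
    required = {"sample_id", "condition", "gene", "ct", "reference_gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    return df


def ddct(records: Union[Iterable[CtRecord], pd.DataFrame],
         calibrator_condition: str) -> pd.DataFrame:
    """Relative expression per (gene, condition) by the 2^-ddCt method.

    Per sample, dCt = Ct_target - Ct_reference (reference gene measured in
    the same sample). dCt is averaged over replicate samples per condition,
    ddCt = mean dCt(condition) - mean dCt(calibrator), and relative
    expression is 2^-ddCt. The calibrator condition maps to exactly 1.0.

    Returns a DataFrame with columns gene, condition, n, delta_ct, ddct,
    relative_expression.
    """
    df = _ct_frame(records)
    refs = df[df["gene"] == df["reference_gene"]][["sample_id", "gene", "ct"]]
    refs = refs.rename(columns={"gene": "reference_gene", "ct": "ct_ref"})
    refs = refs.drop_duplicates(subset=["sample_id", "reference_gene"])
    targets = df[df["gene"] != df["reference_gene"]]
    if targets.empty:
        raise ValueError("no target-gene measurements in Ct table")
    merged = targets.merge(refs, on=["sample_id", "reference_gene"], how="left")
    bad = merged[merged["ct_ref"].isna()]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"missing reference-gene ({r['reference_gene']}) Ct for sample "
            f"{r['sample_id']!r}, gene {r['gene']!r}"
        )
    if calibrator_condition not in set(merged["condition"]):
        raise ValueError(f"calibrator condition {calibrator_condition!r} not present")
    merged["delta_ct"] = merged["ct"] - merged["ct_ref"]
    per_cond = (
        merged.groupby(["gene", "condition"], sort=True)["delta_ct"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "delta_ct", "size": "n"})
        .reset_index()
    )
    cal = per_cond[per_cond["condition"] == calibrator_condition][["gene", "delta_ct"]]
    cal = cal.rename(columns={"delta_ct": "delta_ct_cal"})
    out = per_cond.merge(cal, on="gene", how="left")
    if out["delta_ct_cal"].isna().any():
        g = out[out["delta_ct_cal"].isna()].iloc[0]["gene"]
        raise ValueError(f"gene {g!r} has no measurement in the calibrator condition")
    out["ddct"] = out["delta_ct"] - out["delta_ct_cal"]
    out["relative_expression"] = 2.0 ** (-out["ddct"])
    is_cal = out["condition"] == calibrator_condition
    out.loc[is_cal, "relative_expression"] = 1.0  # exact by construction
    return out[["gene", "condition", "n", "delta_ct", "ddct", "relative_expression"]]


def luciferase_ratio(rec_or_firefly: Union[LucRecord, float],
                     renilla: float | None = None) -> float:
    """Firefly luminescence normalised by the Renilla transfection control."""
    if isinstance(rec_or_firefly, LucRecord):
        firefly, ren = rec_or_firefly.firefly, rec_or_firefly.renilla
    else:
        if renilla is None:
            raise TypeError("pass a LucRecord or (firefly, renilla)")
        firefly, ren = float(rec_or_firefly), float(renilla)
    if ren <= 0:
        raise ValueError("no transfection-control signal: renilla must be > 0")
    if firefly < 0:
        raise ValueError("firefly luminescence must be >= 0")
    return firefly / ren


def luciferase_table(records: Iterable[LucRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "firefly": r.firefly,
            "renilla": r.renilla,
            "normalized_activity": luciferase_ratio(r),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# --- thin statistical pass-throughs (no logic of their own) -----------------

def welch_ttest(a: Sequence[float], b: Sequence[float]):
    """Welch's unequal-variance t-test (scipy.stats.ttest_ind, equal_var=False)."""
    from scipy import stats

    return stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)


def one_way_anova(*groups: Sequence[float]):
    """One-way ANOVA (scipy.stats.f_oneway)."""
    from scipy import stats

    return stats.f_oneway(*[np.asarray(g) for g in groups])


def holm_sidak(pvalues: Sequence[float], alpha: float = 0.05):
    """Holm-Sidak multiple-testing correction (statsmodels multipletests)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues), alpha=alpha, method="holm-sidak")
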
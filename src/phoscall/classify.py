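"""Threshold calibration, modulation calling, and effector classification.

Sites are called per condition from the moderated-test FDR and the replicate-
median log2FC (strict inequalities: down means fdr < fdr_call and
summary_log2FC < log2fc_down). Classification across the three inhibitor
conditions then reads off the pathway position of each site:

* shared effector   — down under every inhibitor (downstream of ERK);
* specific:<cond>   — passes the stricter FDR cut under exactly one inhibitor
                      and is not down-called under any other (candidate direct
                      substrate of that inhibitor's target kinase);
* partial           — down under some but not all, and not specific;
* none              — everything else.

The down/FDR thresholds can be calibrated from positive-control sites (known
pathway effectors): the loosest control behaviour, rounded outward to a 0.1
grid, becomes the threshold, so every control is admitted by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DOWN, UP, UNCHANGED, NA = "down", "up", "unchanged", "NA"
SHARED, PARTIAL, NONE = "shared_effector", "partial", "none"

_GRID = 0.1
_EPS = 1e-9


class CalibrationError(ValueError):
    """Control sites are missing or unusable for threshold calibration."""


@dataclass(frozen=True)
class ThresholdSet:
    """Modulation-calling thresholds (log2FC cuts and FDR levels)."""

    log2fc_down: float = -0.7
    log2fc_up: float = 0.7
    fdr_call: float = 0.1
    fdr_specific: float = 0.05

    def __post_init__(self) -> None:
        if not self.log2fc_down < 0 < self.log2fc_up:
            raise ValueError("need log2fc_down < 0 < log2fc_up")
        if not 0 < self.fdr_specific <= self.fdr_call < 1:
            raise ValueError("need 0 < fdr_specific <= fdr_call < 1")


@dataclass
class CalibrationResult:
    thresholds: ThresholdSet
    raw_log2fc: float  # least negative control summary_log2FC (unrounded)
    raw_fdr: float     # largest control FDR (unrounded)


def _ceil_grid(x: float) -> float:
    return math.ceil(x / _GRID - _EPS) * _GRID


def calibrate_thresholds(results: pd.DataFrame, control_site_ids) -> CalibrationResult:
    """Derive calling thresholds from known-effector (positive-control) sites.

    ``results`` must carry site_id, condition, summary_log2FC and fdr. The
    down cut is the maximum (least negative) control summary_log2FC across
    conditions, rounded outward (toward zero) to one decimal; the FDR cut is
    the maximum control FDR rounded up to one decimal. If a control sits
    exactly on the rounded grid value, the threshold moves one further grid
    step so the strict inequalities still admit it. The up cut mirrors the
    down cut symmetrically and the specific-effector FDR is capped at the
    calling FDR.
    """
    controls = list(dict.fromkeys(control_site_ids))
    if not controls:
        raise CalibrationError("empty control site list")
    present = set(results["site_id"])
    missing = [c for c in controls if c not in present]
    if missing:
        raise CalibrationError(f"control sites absent from results: {missing}")

    sub = results[results["site_id"].isin(controls)]
    sub = sub[sub["fdr"].notna() & sub["summary_log2FC"].notna()]
    if sub.empty:
        raise CalibrationError("no control site has a usable test result")

    raw_fc = float(sub["summary_log2FC"].max())
    raw_fdr = float(sub["fdr"].max())

    fc_cut = _ceil_grid(raw_fc)
    if raw_fc >= fc_cut - _EPS:  # control exactly on the grid: widen one step
        fc_cut += _GRID
    fc_cut = round(fc_cut, 10)
    if fc_cut >= 0:
        raise CalibrationError(
            f"controls are not down-modulated (max summary_log2FC {raw_fc:.3g})"
        )
    fdr_cut = _ceil_grid(raw_fdr)
    if raw_fdr >= fdr_cut - _EPS:
        fdr_cut += _GRID
    fdr_cut = round(fdr_cut, 10)
    if fdr_cut >= 1:
        raise CalibrationError(
            f"control FDRs too large to calibrate a threshold (max {raw_fdr:.3g})"
        )
    thresholds = ThresholdSet(
        log2fc_down=fc_cut,
        log2fc_up=-fc_cut,
        fdr_call=fdr_cut,
        fdr_specific=min(0.05, fdr_cut),
    )
    return CalibrationResult(thresholds, raw_fc, raw_fdr)


def call_modulation_row(summary_log2fc: float, fdr: float,
                        thresholds: ThresholdSet) -> str:
    if fdr is None or math.isnan(fdr) or math.isnan(summary_log2fc):
        return NA
    if fdr < thresholds.fdr_call:
        if summary_log2fc < thresholds.log2fc_down:
            return DOWN
        if summary_log2fc > thresholds.log2fc_up:
            return UP
    return UNCHANGED


def call_modulation(results: pd.DataFrame,
                    thresholds: ThresholdSet | None = None) -> pd.DataFrame:
    """Append a ``call`` column (down/up/unchanged/NA) to test results.

    All inequalities are strict: a site sitting exactly at log2FC -0.7 or
    FDR 0.1 is unchanged.
    """
    thresholds = thresholds or ThresholdSet()
    out = results.copy()
    fc = out["summary_log2FC"].to_numpy(dtype=float)
    fdr = out["fdr"].to_numpy(dtype=float)
    na = ~np.isfinite(fdr) | ~np.isfinite(fc)
    sig = np.isfinite(fdr) & (fdr < thresholds.fdr_call)
    call = np.where(sig & (fc < thresholds.log2fc_down), DOWN,
                    np.where(sig & (fc > thresholds.log2fc_up), UP, UNCHANGED))
    call = np.where(na, NA, call)
    out["call"] = call
    return out


def classify_effectors(calls: pd.DataFrame,
                       thresholds: ThresholdSet | None = None,
                       specific_requires_fc: bool = False) -> pd.DataFrame:
    """Classify each site across conditions from its per-condition calls.

    ``calls`` is the output of :func:`call_modulation` covering every
    condition for the same site universe. A site with an NA call in any
    condition can never be a shared effector (no imputation of unobserved
    conditions). ``specific_requires_fc=True`` switches the "not modulated
    elsewhere" rule for specific effectors from "not down-called" to the
    stricter "log2FC above the down cut regardless of FDR".

    Returns a DataFrame of site_id and effector_class; classes partition the
    site universe.
    """
    thresholds = thresholds or ThresholdSet()
    conditions = list(dict.fromkeys(calls["condition"]))
    by_cond = {c: g.set_index("site_id") for c, g in calls.groupby("condition", sort=False)}
    universe = None
    for cond in conditions:
        ids = set(by_cond[cond].index)
        if universe is None:
            universe = ids
        elif ids != universe:
            raise ValueError(f"condition {cond!r} covers a different site set")

    site_order = list(dict.fromkeys(calls["site_id"]))
    records = []
    for site in site_order:
        rows = {c: by_cond[c].loc[site] for c in conditions}
        is_down = {c: rows[c]["call"] == DOWN for c in conditions}
        if all(is_down.values()):
            records.append((site, SHARED))
            continue
        specific = None
        for c in conditions:
            r = rows[c]
            fdr, fc = r["fdr"], r["summary_log2FC"]
            if not (pd.notna(fdr) and fdr < thresholds.fdr_specific
                    and pd.notna(fc) and fc < thresholds.log2fc_down):
                continue
            if specific_requires_fc:
                others_clear = all(
                    pd.notna(rows[o]["summary_log2FC"])
                    and rows[o]["summary_log2FC"] >= thresholds.log2fc_down
                    for o in conditions if o != c
                )
            else:
                others_clear = all(not is_down[o] for o in conditions if o != c)
            if others_clear:
                specific = c
                break
        if specific is not None:
            records.append((site, f"specific:{specific}"))
        elif any(is_down.values()):
            records.append((site, PARTIAL))
        else:
            records.append((site, NONE))
    return pd.DataFrame(records, columns=["site_id", "effector_class"])


def class_counts(classes: pd.DataFrame) -> pd.Series:
    """Sites per effector class, shared/specific first."""
    return classes["effector_class"].value_counts()
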
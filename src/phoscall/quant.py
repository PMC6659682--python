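"""Class I filtering, SILAC ratio computation and proteome normalization.

The quantification chain is: heavy/light intensity ratio per phosphosite and
replicate, divided by the matching protein-group heavy/light ratio, then log2.
A normalized value of -1 therefore corresponds to a fold-change of 0.5, i.e.
a 50% reduction in site phosphorylation relative to the vehicle control after
accounting for protein abundance changes.

Only the heavy (drug) and light (vehicle) channels enter any computation; the
medium super-SILAC channel is parsed upstream but deliberately unused.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# class I definition: confident localization of the phosphate within the peptide
LOCALIZATION_PROB_MIN = 0.75
SCORE_DIFF_MIN = 5.0

REP_COL = "log2fc_rep{rep}"


def filter_class1(sites, localization_prob_min: float = LOCALIZATION_PROB_MIN,
                  score_diff_min: float = SCORE_DIFF_MIN):
    """Partition records into (kept, rejected) by the class I criterion.

    A site is kept when ``localization_prob >= 0.75`` and ``score_diff >= 5``
    (both cutoffs inclusive). Records with missing evidence fields are
    rejected and logged. The partition is exhaustive and disjoint.
    """
    kept, rejected = [], []
    for rec in sites:
        prob, diff = rec.localization_prob, rec.score_diff
        if prob is None or diff is None or math.isnan(prob) or math.isnan(diff):
            logger.warning("site %s missing localization evidence; rejected",
                           rec.site_id)
            rejected.append(rec)
        elif prob >= localization_prob_min and diff >= score_diff_min:
            kept.append(rec)
        else:
            rejected.append(rec)
    return kept, rejected


def _channel_ratio(channels: dict) -> float:
    """H/L from one replicate's channel dict; NaN when not computable."""
    h = channels.get("H", math.nan)
    l = channels.get("L", math.nan)
    if h is None or l is None or math.isnan(h) or math.isnan(l):
        return math.nan
    if l <= 0:
        logger.debug("light intensity %r not positive; ratio set to missing", l)
        return math.nan
    return h / l


def site_ratio(record, condition: str, replicate: int) -> float:
    """Heavy/light intensity ratio for one site, condition and replicate.

    Returns NaN when either channel is missing or the light intensity is not
    positive (a division-by-zero would otherwise occur).
    """
    reps = record.intensities.get(condition, {})
    return _channel_ratio(reps.get(replicate, {}))


def normalize_to_proteome(site_ratio_value: float, protein_ratio_value: float) -> float:
    """log2 of the phosphosite H/L ratio divided by the protein H/L ratio.

    Antisymmetric in its arguments: swapping site and protein ratios flips
    the sign. Requires both ratios positive.
    """
    if site_ratio_value <= 0 or protein_ratio_value <= 0:
        raise ValueError("ratios must be positive for log2 normalization")
    return math.log2(site_ratio_value / protein_ratio_value)


def label_incorporation(labelled: float, unlabelled: float) -> float:
    """Percent SILAC label incorporation, 100 * labelled / (labelled + unlabelled).

    Used as a labelling QC: near-complete incorporation (e.g. >98%) means
    ratio distortion from unlabelled carry-over is negligible.
    """
    if labelled < 0 or unlabelled < 0:
        raise ValueError("counts must be non-negative")
    if labelled == 0 and unlabelled == 0:
        raise ValueError("labelled and unlabelled cannot both be zero")
    return 100.0 * labelled / (labelled + unlabelled)


def normalize_table(site_records, protein_records, conditions=None,
                    replicates=None) -> pd.DataFrame:
    """Build the per-site, per-condition normalized log2FC table.

    One row per (site, condition) with columns ``log2fc_rep1..N``, the
    replicate median ``summary_log2FC``, and a ``protein_quantified`` flag.

    A replicate log2FC is missing whenever either the phosphosite or the
    matching protein H/L ratio is missing in that replicate. Sites whose
    protein has no record at all are normalized against a protein ratio of
    1.0 in every replicate and flagged ``protein_quantified = False`` so
    users can filter them, rather than being dropped silently.
    """
    proteins = {rec.protein_id: rec for rec in protein_records}

    if conditions is None or replicates is None:
        seen_conds: list[str] = []
        seen_reps: set[int] = set()
        for rec in site_records:
            for cond, reps in rec.intensities.items():
                if cond not in seen_conds:
                    seen_conds.append(cond)
                seen_reps.update(reps)
        conditions = conditions or seen_conds
        replicates = replicates or sorted(seen_reps)

    rows = []
    for rec in site_records:
        prot = proteins.get(rec.protein_id)
        if prot is None:
            logger.info("protein %s not quantified; site %s normalized against 1.0",
                        rec.protein_id, rec.site_id)
        for cond in conditions:
            row = {"site_id": rec.site_id, "condition": cond,
                   "protein_quantified": prot is not None}
            values = []
            for rep in replicates:
                sr = site_ratio(rec, cond, rep)
                if prot is None:
                    pr = 1.0
                else:
                    pr = _channel_ratio(prot.intensities.get(cond, {}).get(rep, {}))
                if math.isnan(sr) or math.isnan(pr):
                    value = math.nan
                else:
                    value = normalize_to_proteome(sr, pr)
                row[REP_COL.format(rep=rep)] = value
                values.append(value)
            arr = np.asarray(values, dtype=float)
            row["summary_log2FC"] = (
                float(np.nanmedian(arr)) if np.isfinite(arr).any() else math.nan
            )
            rows.append(row)
    cols = ["site_id", "condition"] + [REP_COL.format(rep=r) for r in replicates] \
        + ["summary_log2FC", "protein_quantified"]
    return pd.DataFrame(rows, columns=cols)


def replicate_columns(norm_table: pd.DataFrame) -> list[str]:
    return [c for c in norm_table.columns if c.startswith("log2fc_rep")]
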
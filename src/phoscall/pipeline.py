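"""End-to-end driver: records in, effector classes out.

Chains class I filtering, proteome normalization, the moderated test with
per-condition BH FDR, optional threshold calibration from positive-control
sites, modulation calling, and cross-condition effector classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classify, quant, stats


@dataclass
class PipelineResult:
    normalized: pd.DataFrame   # per-site, per-condition replicate log2FCs
    results: pd.DataFrame      # moderated-test statistics with FDR
    calls: pd.DataFrame        # results + modulation call column
    classes: pd.DataFrame      # site_id -> effector_class
    thresholds: classify.ThresholdSet
    n_class1: int
    n_rejected: int


def run_pipeline(site_records, protein_records, conditions=None,
                 thresholds: classify.ThresholdSet | None = None,
                 control_site_ids=None, min_replicates: int = 2,
                 global_fdr: bool = False,
                 specific_requires_fc: bool = False) -> PipelineResult:
    """Run the full quantification-to-classification chain.

    When ``control_site_ids`` is given, calling thresholds are calibrated
    from those known-effector sites and any explicit ``thresholds`` argument
    is ignored; otherwise the supplied (or default) thresholds are used.
    """
    kept, rejected = quant.filter_class1(site_records)
    normalized = quant.normalize_table(kept, protein_records, conditions=conditions)
    results = stats.test_all_conditions(normalized, min_replicates=min_replicates,
                                        global_fdr=global_fdr)
    if control_site_ids:
        thresholds = classify.calibrate_thresholds(results, control_site_ids).thresholds
    elif thresholds is None:
        thresholds = classify.ThresholdSet()
    calls = classify.call_modulation(results, thresholds)
    classes = classify.classify_effectors(
        calls, thresholds, specific_requires_fc=specific_requires_fc)
    return PipelineResult(normalized=normalized, results=results, calls=calls,
                          classes=classes, thresholds=thresholds,
                          n_class1=len(kept), n_rejected=len(rejected))
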
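import math

import pytest
from hypothesis import settings

from phoscall.io_formats import PhosphoSiteRecord, ProteinRecord

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

CONDITIONS = ("BRAFi", "MEKi", "ERKi")


def make_site(site_id="s1", protein_id="P1", position=8, residue="S",
              localization_prob=0.95, score_diff=20.0, flank=None,
              ratios=None, conditions=CONDITIONS, n_replicates=3):
    """Build a site record whose H/L ratio equals ``ratios[cond][rep]``.

    ``ratios`` maps condition -> {replicate: ratio or nan}; light is fixed at
    1000 so heavy = 1000 * ratio.
    """
    if flank is None:
        flank = "A" * 7 + residue + "A" * 7
    intensities = {}
    for cond in conditions:
        intensities[cond] = {}
        for rep in range(1, n_replicates + 1):
            ratio = (ratios or {}).get(cond, {}).get(rep, 1.0)
            if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
                h = l = math.nan
            else:
                l = 1000.0
                h = 1000.0 * ratio
            intensities[cond][rep] = {"H": h, "M": (h + l) / 2 if h == h else math.nan,
                                      "L": l}
    return PhosphoSiteRecord(site_id=site_id, protein_id=protein_id,
                             position=position, residue=residue,
                             localization_prob=localization_prob,
                             score_diff=score_diff, flank=flank,
                             intensities=intensities)


def make_protein(protein_id="P1", ratios=None, conditions=CONDITIONS,
                 n_replicates=3):
    intensities = {}
    for cond in conditions:
        intensities[cond] = {}
        for rep in range(1, n_replicates + 1):
            ratio = (ratios or {}).get(cond, {}).get(rep, 1.0)
            if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
                h = l = math.nan
            else:
                l = 5000.0
                h = 5000.0 * ratio
            intensities[cond][rep] = {"H": h, "M": (h + l) / 2 if h == h else math.nan,
                                      "L": l}
    return ProteinRecord(protein_id=protein_id, intensities=intensities)


@pytest.fixture
def simple_site():
    return make_site()


@pytest.fixture
def simple_protein():
    return make_protein()
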
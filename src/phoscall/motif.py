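"""Kinase specificity matrices from positional-scanning peptide arrays.

An arrayed positional-scanning peptide library fixes one position around a
central S/T phospho-acceptor to each of the 20 amino acids while the other
variable positions hold an equimolar degenerate mixture (17 amino acids,
excluding Cys, Ser and Thr). Radiolabel incorporation per mixture measures
the kinase's preference for that residue at that position.

Quantified arrays are normalized so that the 20 residue values at each
position average to one on the linear scale, then log2-transformed, giving a
position-specific scoring matrix (PSSM). Phosphosite flanks are scored by
summing the log2 preferences of their residues over the variable positions
(-5..-1, +1..+4); the acceptor itself never contributes.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FLANK_WIDTH, PSSM_POSITIONS

logger = logging.getLogger(__name__)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
#: degenerate positions exclude Cys (oxidation artefacts) and Ser/Thr
#: (competing acceptors)
DEGENERATE_ALPHABET = tuple(a for a in AMINO_ACIDS if a not in ("C", "S", "T"))
ARRAY_POSITIONS = (-5, -4, -3, -2, -1, 1, 2, 3, 4)

_POS_LABEL = {p: f"{p:+d}" for p in ARRAY_POSITIONS}


class TemplateError(ValueError):
    """Peptide-library template lacks an acceptor or variable positions."""


class AcceptorError(ValueError):
    """Flank center residue is incompatible with the matrix's acceptor."""


@dataclass(frozen=True)
class MixtureDescriptor:
    """One peptide mixture: a single variable position fixed to one residue."""

    position: int       # relative to the acceptor (negative = N-terminal)
    fixed_residue: str
    degenerate_alphabet: tuple = DEGENERATE_ALPHABET


@dataclass
class PeptideArrayMatrix:
    """Raw radiolabel quantification, 20 residues x 9 positions, all > 0."""

    values: pd.DataFrame
    kinase: str = ""
    template: str = ""

    def __post_init__(self) -> None:
        self.values = _check_matrix(self.values, require_positive=True)


@dataclass
class SpecificityMatrix:
    """Normalized kinase preference matrix (per-position mean 1 on linear scale)."""

    values: pd.DataFrame
    kinase: str = ""
    scale: str = "log2"  # "log2" or "linear"
    acceptor: str = "ST"

    def __post_init__(self) -> None:
        self.values = _check_matrix(
            self.values, require_positive=(self.scale == "linear")
        )


def _check_matrix(values: pd.DataFrame, require_positive: bool) -> pd.DataFrame:
    df = values.copy().astype(float)
    missing_res = [a for a in AMINO_ACIDS if a not in df.index]
    if missing_res:
        raise ValueError(f"matrix missing residues {missing_res}")
    cols = [str(c) for c in df.columns]
    df.columns = cols
    missing_pos = [p for p in PSSM_POSITIONS if p not in cols]
    if missing_pos:
        raise ValueError(f"matrix missing positions {missing_pos}")
    df = df.loc[list(AMINO_ACIDS), PSSM_POSITIONS]
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("matrix contains non-finite values")
    if require_positive and not (df.to_numpy() > 0).all():
        raise ValueError("linear-scale matrix values must be positive")
    return df


# ---------------------------------------------------------------------------
# library enumeration


def parse_template(template: str):
    """Split a library template into tokens; returns (tokens, acceptor index).

    Tokens may be '-'-separated (``Y-A-x-x-x-S/T-x-A``) or single characters.
    The acceptor token is ``S/T`` (or a bare ``s``/``t`` in character form is
    not accepted — the acceptor must be explicit).
    """
    if "-" in template:
        tokens = [t.strip() for t in template.split("-") if t.strip()]
    else:
        m = re.search(r"S/T", template)
        if m:
            tokens = list(template[:m.start()]) + ["S/T"] + list(template[m.end():])
        else:
            tokens = list(template)
    acceptors = [i for i, t in enumerate(tokens) if t.upper() == "S/T"]
    if len(acceptors) != 1:
        raise TemplateError(
            f"template must contain exactly one S/T acceptor token, found "
            f"{len(acceptors)}"
        )
    return tokens, acceptors[0]


def enumerate_library(template: str) -> list[MixtureDescriptor]:
    """All (variable position, fixed residue) mixtures for a library template.

    Each ``x`` position is fixed in turn to each of the 20 amino acids while
    the remaining ``x`` positions stay degenerate, so a template with nine
    variable positions enumerates 180 mixtures.
    """
    tokens, acceptor_idx = parse_template(template)
    variable = [i for i, t in enumerate(tokens) if t.lower() == "x"]
    if not variable:
        raise TemplateError("template contains no variable 'x' positions")
    return [
        MixtureDescriptor(position=i - acceptor_idx, fixed_residue=aa)
        for i in variable
        for aa in AMINO_ACIDS
    ]


# ---------------------------------------------------------------------------
# PSSM construction


def build_pssm(array: PeptideArrayMatrix | pd.DataFrame,
               kinase: str | None = None) -> SpecificityMatrix:
    """Normalize a raw array to per-position mean one, then log2-transform.

    value[r, p] = log2( raw[r, p] / mean_over_residues(raw[., p]) ), so the
    exponentiated matrix has column means of exactly 1 (equivalently the
    2**values sum to 20 per position).
    """
    if isinstance(array, PeptideArrayMatrix):
        raw = array.values
        kinase = kinase if kinase is not None else array.kinase
    else:
        raw = _check_matrix(array, require_positive=True)
        kinase = kinase or ""
    normalized = raw / raw.mean(axis=0)
    return SpecificityMatrix(values=np.log2(normalized), kinase=kinase,
                             scale="log2")


def average_pssms(matrices, kinase: str | None = None,
                  order: str = "normalize-then-average") -> SpecificityMatrix:
    """Combine replicate arrays into one specificity matrix.

    ``normalize-then-average`` (default) builds a log2 PSSM per array and
    averages them; ``average-then-normalize`` averages the raw linear arrays
    first. With identical replicates both orders reduce to the single-array
    result.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no arrays to average")
    if kinase is None:
        kinase = getattr(matrices[0], "kinase", "") or ""
    if order == "normalize-then-average":
        parts = [build_pssm(m).values for m in matrices]
        return SpecificityMatrix(values=sum(parts) / len(parts), kinase=kinase)
    if order == "average-then-normalize":
        raws = [m.values if isinstance(m, PeptideArrayMatrix) else m
                for m in matrices]
        mean_raw = sum(r.astype(float) for r in raws) / len(raws)
        return build_pssm(mean_raw, kinase=kinase)
    raise ValueError(f"unknown order {order!r}")


# ---------------------------------------------------------------------------
# flank scoring


@dataclass
class SiteScore:
    site_id: str
    kinase: str
    score: float
    rank: int | None = None


def score_flank(flank: str, pssm: SpecificityMatrix,
                site_id: str = "") -> SiteScore:
    """Additive log2 score of a 15-mer flank against one specificity matrix.

    Positions -5..-1 and +1..+4 relative to the central acceptor contribute
    their matrix value; the acceptor itself, ``_`` padding, and residues not
    in the matrix contribute zero. The flank center must be S or T for an
    S/T-directed matrix.
    """
    if len(flank) != 2 * FLANK_WIDTH + 1:
        raise ValueError(f"flank must be {2 * FLANK_WIDTH + 1} characters")
    center = flank[FLANK_WIDTH]
    if center not in pssm.acceptor:
        raise AcceptorError(
            f"flank center {center!r} incompatible with {pssm.acceptor}-directed matrix"
        )
    if pssm.scale != "log2":
        raise ValueError("scoring requires a log2-scale matrix")
    score = 0.0
    for pos in ARRAY_POSITIONS:
        res = flank[FLANK_WIDTH + pos]
        if res in pssm.values.index:
            score += float(pssm.values.at[res, _POS_LABEL[pos]])
    return SiteScore(site_id=site_id, kinase=pssm.kinase, score=score)


def rank_kinases(flank: str, matrices, site_id: str = "") -> list[SiteScore]:
    """Score a flank against several matrices, best first.

    Ties are broken lexicographically by kinase name. Matrices whose
    acceptor is incompatible with the flank are skipped; if none are
    compatible an empty list is returned with a warning.
    """
    scores = []
    for pssm in matrices:
        try:
            scores.append(score_flank(flank, pssm, site_id=site_id))
        except AcceptorError:
            logger.debug("kinase %s skipped: incompatible acceptor", pssm.kinase)
    if not scores:
        warnings.warn(f"no matrix compatible with flank {flank!r}",
                      RuntimeWarning, stacklevel=2)
        return []
    scores.sort(key=lambda s: (-s.score, s.kinase))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores
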
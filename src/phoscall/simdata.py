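"""Synthetic SILAC phosphoproteomics experiments with known ground truth.

The generator emulates a three-inhibitor perturbation screen: for each of
three conditions (default BRAFi/MEKi/ERKi) and three biological replicates it
produces heavy (drug) and light (vehicle) channel intensities for every
phosphosite and its parent protein, such that the proteome-normalized log2
ratio of a site is Normal(true effect, noise_sd). Planted classes:

* shared effectors     — a common negative log2 effect in every condition
                         (sites downstream of the full kinase cascade);
* specific effectors   — the effect in exactly one condition (candidate
                         direct substrates of that condition's target);
* null sites           — true effect zero everywhere.

Protein-level H/L ratios drift around one (sd ``protein_ratio_sd``) and are
shared between a site and its parent protein, so proteome normalization
removes them exactly. A medium channel (super-SILAC internal standard) is
written as the H/L average but is never used downstream. Missing replicates
are injected completely at random; a configurable fraction of sites fails
the class I localization filter. Each site sits at a real position in a
generated protein sequence, so flanks are consistent with the FASTA the
generator can write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (PAD, PSSM_POSITIONS, PhosphoSiteRecord, ProteinRecord,
                         extract_flank)
from .motif import AMINO_ACIDS, ARRAY_POSITIONS, SpecificityMatrix

NULL = "null"
SHARED = "shared_effector"


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror a triple-inhibitor screen in biological triplicate:
    a strong planted effect of -1.5 log2 units against replicate noise of
    0.25 log2 units, ~2% shared and ~1% per-condition specific effectors,
    10% missing replicate measurements and 10% of sites failing confident
    localization.
    """

    n_sites: int = 1000
    n_proteins: int = 400
    n_replicates: int = 3
    conditions: tuple = ("BRAFi", "MEKi", "ERKi")
    frac_shared_effectors: float = 0.02
    frac_specific_effectors: float = 0.01   # per condition
    effect_log2fc: float = -1.5             # log2 units
    noise_sd: float = 0.25                  # sd of replicate log2FC, log2 units
    missing_rate: float = 0.1               # MCAR at the replicate level
    protein_ratio_sd: float = 0.1           # sd of protein-level log2 H/L drift
    frac_class2: float = 0.1                # fraction failing the class I filter
    base_log2_intensity: float = 23.0       # light-channel abundance scale
    base_log2_intensity_sd: float = 2.0
    replicate_log2_intensity_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_proteins < 1:
            raise ConfigError("n_sites and n_proteins must be positive")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be positive")
        if not self.conditions:
            raise ConfigError("need at least one condition")
        for name, frac in [("frac_shared_effectors", self.frac_shared_effectors),
                           ("frac_specific_effectors", self.frac_specific_effectors),
                           ("missing_rate", self.missing_rate),
                           ("frac_class2", self.frac_class2)]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {frac}")
        total = self.frac_shared_effectors \
            + len(self.conditions) * self.frac_specific_effectors
        if total > 1.0 + 1e-12:
            raise ConfigError(
                "frac_shared + n_conditions * frac_specific must not exceed 1"
            )
        for name, sd in [("noise_sd", self.noise_sd),
                         ("protein_ratio_sd", self.protein_ratio_sd)]:
            if sd < 0:
                raise ConfigError(f"{name} must be non-negative, got {sd}")


@dataclass
class GroundTruth:
    """Planted class labels and per-condition true effects.

    ``table`` has one row per site: site_id, label (shared_effector,
    specific:<condition>, or null) and one ``effect_<condition>`` column per
    condition with the true log2 effect.
    """

    table: pd.DataFrame
    conditions: tuple = ()
    sequences: dict = field(default_factory=dict)

    def labels(self) -> pd.Series:
        return self.table.set_index("site_id")["label"]

    def shared_ids(self) -> set:
        return set(self.table.loc[self.table["label"] == SHARED, "site_id"])

    def specific_ids(self, condition: str) -> set:
        return set(self.table.loc[
            self.table["label"] == f"specific:{condition}", "site_id"])

    def null_ids(self) -> set:
        return set(self.table.loc[self.table["label"] == NULL, "site_id"])

    def effect(self, site_id: str, condition: str) -> float:
        row = self.table.set_index("site_id").loc[site_id]
        return float(row[f"effect_{condition}"])


def _random_protein_sequences(rng, n_proteins: int):
    alphabet = np.array(list(AMINO_ACIDS))
    lengths = rng.integers(100, 500, size=n_proteins)
    return ["".join(rng.choice(alphabet, size=ln)) for ln in lengths]


def simulate_experiment(config: SimulationConfig):
    """Generate one synthetic experiment.

    Returns ``(sites, proteins, truth)``: lists of phosphosite and protein
    records (the same objects the readers produce) and the ground truth.
    Deterministic for a fixed config (including seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    conditions = list(cfg.conditions)
    reps = list(range(1, cfg.n_replicates + 1))

    # --- site classes and true effects -----------------------------------
    n_shared = int(round(cfg.frac_shared_effectors * cfg.n_sites))
    n_specific = int(round(cfg.frac_specific_effectors * cfg.n_sites))
    labels = np.array([NULL] * cfg.n_sites, dtype=object)
    order = rng.permutation(cfg.n_sites)
    cursor = 0
    labels[order[cursor:cursor + n_shared]] = SHARED
    cursor += n_shared
    for cond in conditions:
        labels[order[cursor:cursor + n_specific]] = f"specific:{cond}"
        cursor += n_specific

    effects = np.zeros((cfg.n_sites, len(conditions)))
    for j, cond in enumerate(conditions):
        effects[labels == SHARED, j] = cfg.effect_log2fc
        effects[labels == f"specific:{cond}", j] = cfg.effect_log2fc

    # --- protein sequences and site placement ----------------------------
    sequences = _random_protein_sequences(rng, cfg.n_proteins)
    protein_ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    site_protein = rng.integers(0, cfg.n_proteins, size=cfg.n_sites)
    positions = np.array([
        int(rng.integers(1, len(sequences[p]) + 1)) for p in site_protein
    ])
    residues = rng.choice(np.array(["S", "T", "Y"]),
                          size=cfg.n_sites, p=[0.75, 0.2, 0.05])
    # rewrite the chosen position so sequence and site record agree
    seq_chars = [list(s) for s in sequences]
    for i in range(cfg.n_sites):
        seq_chars[site_protein[i]][positions[i] - 1] = residues[i]
    sequences = ["".join(chars) for chars in seq_chars]
    # two sites may share a (protein, position); the final sequence wins
    residues = np.array([
        sequences[site_protein[i]][positions[i] - 1] for i in range(cfg.n_sites)
    ])

    # --- localization evidence -------------------------------------------
    fails = rng.random(cfg.n_sites) < cfg.frac_class2
    loc_prob = rng.uniform(0.75, 1.0, size=cfg.n_sites)
    score_diff = rng.uniform(5.0, 60.0, size=cfg.n_sites)
    fail_mode = rng.random(cfg.n_sites) < 0.5
    loc_prob[fails & fail_mode] = rng.uniform(
        0.0, 0.749, size=int((fails & fail_mode).sum()))
    score_diff[fails & ~fail_mode] = rng.uniform(
        0.0, 4.99, size=int((fails & ~fail_mode).sum()))

    # --- channel intensities ----------------------------------------------
    n_cond, n_rep = len(conditions), cfg.n_replicates
    site_base = rng.normal(cfg.base_log2_intensity, cfg.base_log2_intensity_sd,
                           size=cfg.n_sites)
    prot_base = rng.normal(cfg.base_log2_intensity + 2.0,
                           cfg.base_log2_intensity_sd, size=cfg.n_proteins)
    # protein-level H/L drift, shared between a site and its parent protein
    prot_g = rng.normal(0.0, cfg.protein_ratio_sd,
                        size=(cfg.n_proteins, n_cond, n_rep))
    eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_sites, n_cond, n_rep))

    site_light = 2.0 ** (
        site_base[:, None, None]
        + rng.normal(0.0, cfg.replicate_log2_intensity_sd,
                     size=(cfg.n_sites, n_cond, n_rep))
    )
    site_heavy = site_light * 2.0 ** (
        prot_g[site_protein] + effects[:, :, None] + eps
    )
    prot_light = 2.0 ** (
        prot_base[:, None, None]
        + rng.normal(0.0, cfg.replicate_log2_intensity_sd,
                     size=(cfg.n_proteins, n_cond, n_rep))
    )
    prot_heavy = prot_light * 2.0 ** prot_g

    missing = rng.random((cfg.n_sites, n_cond, n_rep)) < cfg.missing_rate
    site_heavy = np.where(missing, np.nan, site_heavy)
    site_light = np.where(missing, np.nan, site_light)

    # --- assemble records --------------------------------------------------
    sites = []
    for i in range(cfg.n_sites):
        pid = protein_ids[site_protein[i]]
        intensities = {}
        for j, cond in enumerate(conditions):
            intensities[cond] = {}
            for k, rep in enumerate(reps):
                h, l = site_heavy[i, j, k], site_light[i, j, k]
                m = (h + l) / 2.0  # super-SILAC internal standard; unused
                intensities[cond][rep] = {"H": float(h), "M": float(m),
                                          "L": float(l)}
        sites.append(PhosphoSiteRecord(
            site_id=f"site{i:05d}",
            protein_id=pid,
            position=int(positions[i]),
            residue=str(residues[i]),
            localization_prob=float(loc_prob[i]),
            score_diff=float(score_diff[i]),
            flank=extract_flank(sequences[site_protein[i]], int(positions[i])),
            intensities=intensities,
        ))

    proteins = []
    for pidx in range(cfg.n_proteins):
        intensities = {}
        for j, cond in enumerate(conditions):
            intensities[cond] = {}
            for k, rep in enumerate(reps):
                h, l = prot_heavy[pidx, j, k], prot_light[pidx, j, k]
                intensities[cond][rep] = {"H": float(h), "M": float((h + l) / 2.0),
                                          "L": float(l)}
        proteins.append(ProteinRecord(protein_id=protein_ids[pidx],
                                      intensities=intensities))

    truth_rows = {
        "site_id": [r.site_id for r in sites],
        "label": labels,
    }
    for j, cond in enumerate(conditions):
        truth_rows[f"effect_{cond}"] = effects[:, j]
    truth = GroundTruth(table=pd.DataFrame(truth_rows),
                        conditions=tuple(conditions),
                        sequences=dict(zip(protein_ids, sequences)))
    return sites, proteins, truth


def write_fasta(truth: GroundTruth, path) -> None:
    """Write the generated protein sequences (synthetic) as FASTA."""
    with open(path, "w") as fh:
        for pid, seq in truth.sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    # keep_default_na: the class label "null" must not parse as NaN
    table = pd.read_csv(path, sep="\t", keep_default_na=False,
                        na_values=["", "NA", "NaN", "nan"])
    conds = tuple(c[len("effect_"):] for c in table.columns
                  if c.startswith("effect_"))
    return GroundTruth(table=table, conditions=conds)


# ---------------------------------------------------------------------------
# peptide arrays


def simulate_peptide_array(pssm_truth, total_counts: float = 1e6,
                           noise_cv: float = 0.1, seed: int = 0):
    """Raw array counts proportional to a linear-scale truth matrix.

    Multiplicative lognormal noise with coefficient of variation ``noise_cv``
    (mean 1) is applied cell-wise; with ``noise_cv = 0`` the output is an
    exact rescaling of the truth, so PSSM construction inverts it exactly.
    """
    from .motif import PeptideArrayMatrix, _check_matrix  # avoid cycle at import

    if isinstance(pssm_truth, SpecificityMatrix):
        if pssm_truth.scale != "linear":
            raise ValueError("truth matrix must be on the linear scale")
        truth = pssm_truth.values
    else:
        truth = pssm_truth
    truth = _check_matrix(truth, require_positive=True)
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    scale = total_counts / float(truth.to_numpy().sum())
    raw = truth.to_numpy() * scale
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv ** 2))
        raw = raw * rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                                  size=raw.shape)
    values = pd.DataFrame(raw, index=truth.index, columns=truth.columns)
    return PeptideArrayMatrix(values=values, kinase="truth")


def example_truth_matrix(kinase: str = "BRAF-like") -> SpecificityMatrix:
    """A synthetic linear-scale ground-truth motif for simulations.

    Not measured data: a constructed stand-in motif with the qualitative
    hallmarks of a RAF-family serine kinase — Leu/Met preferred at -3,
    hydrophobic residues at +1, aromatic residues at +2 — on top of graded
    secondary preferences at every position (real arrays never read out as
    exactly flat), normalized to per-position mean one. Deterministic.
    """
    # fixed-seed graded background of ~0.35 log2-units spread
    rng = np.random.default_rng(20090)
    background = 2.0 ** rng.normal(0.0, 0.35, size=(len(AMINO_ACIDS),
                                                    len(PSSM_POSITIONS)))
    values = pd.DataFrame(background, index=list(AMINO_ACIDS),
                          columns=PSSM_POSITIONS)
    values.loc["L", "-3"] *= 5.0
    values.loc["M", "-3"] *= 4.0
    for res in ("L", "I", "V", "M", "F"):
        values.loc[res, "+1"] *= 3.0
    for res in ("F", "W", "Y"):
        values.loc[res, "+2"] *= 3.0
    values.loc["P", "-2"] *= 1.8
    values.loc["R", "-5"] *= 1.5
    values = values / values.mean(axis=0)
    return SpecificityMatrix(values=values, kinase=kinase, scale="linear")


def best_flank(pssm: SpecificityMatrix, acceptor: str = "S") -> str:
    """The argmax 15-mer flank of a matrix (log2 or linear scale)."""
    chars = [PAD] * 15
    chars[7] = acceptor
    for pos in ARRAY_POSITIONS:
        col = pssm.values[f"{pos:+d}"]
        chars[7 + pos] = str(col.idxmax())
    return "".join(chars)
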
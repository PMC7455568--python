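"""Synthetic study generator with planted ground truth.

Emulates the pooled-cartilage study design: 8 samples, one per
(genotype x surgery x week) cell, no replicates.  Genes fall into four
planted classes:

* ``attenuated`` — positive DMM response in WT, zero-or-negative in KO,
  with the same true effects at both weeks (the signal the selection rule
  exists to find);
* ``shared_de`` — the same DMM response in both genotypes, drawn
  independently per week with a random sign;
* ``null`` — no condition effect;
* ``unexpressed`` — baseline far below the TPM filter in every sample.

Expression is built on the log2 scale: log2 TPM = baseline + effect (DMM
samples only) + N(0, noise_sd) per sample, then exponentiated.  Noise is
multiplicative on TPM, matching the ratio-based DIF statistic.  Column
sums are not re-normalised after simulation: the pipeline's contrasts are
per-gene ratios, which are invariant to a per-gene TPM scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    GENOTYPES,
    WEEKS,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
)

CLASSES = ("attenuated", "shared_de", "null", "unexpressed")


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Fractions partition the gene classes (remainder = null); effects are
    log2 fold changes of the DMM response; ``noise_sd`` is the per-sample
    log2-scale noise.  ``baseline_log2_tpm_min`` truncates expressed
    baselines so the planted unexpressed class is exactly the set the TPM
    filter removes when noise is off.
    """

    n_genes: int = 2000
    frac_attenuated: float = 0.05
    frac_shared_de: float = 0.10
    frac_unexpressed: float = 0.10
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    noise_sd: float = 0.25
    baseline_log2_tpm_mean: float = 4.0
    baseline_log2_tpm_sd: float = 2.0
    baseline_log2_tpm_min: float = 0.5
    unexpressed_log2_tpm: float = -6.0
    seed: int = 7

    def validate(self) -> "SimulationConfig":
        fracs = (self.frac_attenuated, self.frac_shared_de, self.frac_unexpressed)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if self.n_genes < 8:
            raise ValueError("n_genes must be >= 8")
        if self.effect_sd < 0 or self.noise_sd < 0 or self.baseline_log2_tpm_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        return self


@dataclasses.dataclass
class PlantedTruth:
    """Per-gene class labels and true log2 DMM effects per genotype/week."""

    table: pd.DataFrame  # index gene; class, wt_effect_w{2,4}, ko_effect_w{2,4}

    def genes_in_class(self, cls: str) -> set[str]:
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return set(self.table.index[self.table["class"] == cls])

    @property
    def attenuated(self) -> set[str]:
        return self.genes_in_class("attenuated")


def _sample_id(genotype: str, condition: str, week: int) -> str:
    return f"{genotype}_{condition}_w{week}"


def simulate_study(config: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate the 8-sample TPM matrix and its planted truth.

    Same config (incl. seed) twice gives byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"Simg{i:05d}" for i in range(n)]

    n_att = round(config.frac_attenuated * n)
    n_sh = round(config.frac_shared_de * n)
    n_un = round(config.frac_unexpressed * n)
    labels = np.array(
        ["attenuated"] * n_att + ["shared_de"] * n_sh + ["unexpressed"] * n_un
        + ["null"] * (n - n_att - n_sh - n_un)
    )
    rng.shuffle(labels)

    baseline = np.maximum(
        rng.normal(config.baseline_log2_tpm_mean, config.baseline_log2_tpm_sd, n),
        config.baseline_log2_tpm_min,
    )
    baseline[labels == "unexpressed"] = config.unexpressed_log2_tpm + rng.normal(
        0.0, 0.5, (labels == "unexpressed").sum()
    )

    # effect[genotype][week] per gene; attenuated effects shared across weeks,
    # shared_de effects drawn independently per week (same in both genotypes)
    eff = {g: {w: np.zeros(n) for w in WEEKS} for g in GENOTYPES}
    att = labels == "attenuated"
    wt_eff = np.abs(rng.normal(config.effect_mean, config.effect_sd, att.sum()))
    ko_eff = -np.abs(rng.normal(config.effect_mean / 2, config.effect_sd, att.sum()))
    sh = labels == "shared_de"
    for w in WEEKS:
        eff["WT"][w][att] = wt_eff
        eff["KO"][w][att] = ko_eff
        shared = rng.normal(config.effect_mean, config.effect_sd, sh.sum())
        shared *= rng.choice([-1.0, 1.0], sh.sum())
        eff["WT"][w][sh] = shared
        eff["KO"][w][sh] = shared

    cols: dict[str, np.ndarray] = {}
    for genotype in GENOTYPES:
        for week in WEEKS:
            for condition in CONDITIONS:
                log2tpm = baseline.copy()
                if condition == "DMM":
                    log2tpm = log2tpm + eff[genotype][week]
                log2tpm = log2tpm + rng.normal(0.0, config.noise_sd, n)
                cols[_sample_id(genotype, condition, week)] = np.exp2(log2tpm)

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(
        [
            {"sample_id": _sample_id(g, c, w), "genotype": g,
             "condition": c, "week": w}
            for g in GENOTYPES for w in WEEKS for c in CONDITIONS
        ]
    ).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, meta=meta).validate()

    truth = pd.DataFrame({"class": labels}, index=values.index)
    for w in WEEKS:
        truth[f"wt_effect_w{w}"] = eff["WT"][w]
        truth[f"ko_effect_w{w}"] = eff["KO"][w]
    return matrix, PlantedTruth(table=truth)


def make_fixture_collections(
    truth: PlantedTruth,
    n_sets: int = 10,
    set_size: int = 50,
    seed: int = 0,
    frac_planted_members: float = 0.8,
) -> tuple[GeneSetCollection, OrthologMap]:
    """Build a gene-set collection with one set enriched for planted genes.

    The first set draws ``frac_planted_members`` of its members from the
    attenuated class (uppercased into the human namespace) and the rest at
    random; the remaining ``n_sets - 1`` sets are uniform draws from all
    genes.  The ortholog map is identity-like: every simulated mouse
    symbol pairs with its uppercase human form.
    """
    genes = list(truth.table.index)
    if set_size > len(genes):
        raise ValueError("set_size exceeds number of simulated genes")
    rng = np.random.default_rng(seed)
    attenuated = sorted(truth.attenuated)
    others = sorted(set(genes) - set(attenuated))

    n_planted = min(round(frac_planted_members * set_size), len(attenuated))
    planted_members = list(rng.choice(attenuated, n_planted, replace=False)) if n_planted else []
    filler = list(rng.choice(others, set_size - n_planted, replace=False))
    sets: dict[str, frozenset[str]] = {
        "PLANTED_ATTENUATED_RESPONSE": frozenset(
            g.upper() for g in planted_members + filler
        )
    }
    for i in range(1, n_sets):
        members = rng.choice(genes, set_size, replace=False)
        sets[f"RANDOM_SET_{i:02d}"] = frozenset(g.upper() for g in members)
    omap = OrthologMap(pairs=[(g.upper(), g) for g in genes])
    return GeneSetCollection(sets=sets), omap


def write_truth(truth: PlantedTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
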
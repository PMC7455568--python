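"""Differential-response (DIF) gene selection.

The core statistic compares each gene's surgery response between
genotypes.  With ``E_x`` the TPM of a gene in condition x, the per-genotype
contrast at a given week is

    L_g = log2((E_DMM + eps) / (E_sham + eps))

and the attenuation score is ``DIF = L_KO - L_WT``.  A negative DIF means
the DMM response present in wild type is suppressed in the knockout.  A
gene is selected at a week when, with strict inequalities,

    (i)   L_KO < 0
    (ii)  L_WT > 0
    (iii) DIF  < DIF_25%   (lower quartile of DIF over the filtered universe)

and (iv) a gene is a *common* gene when (i)-(iii) hold at both the 2- and
4-week timepoints.  The significance of the overlap between the two
per-week selections is an upper-tail hypergeometric probability against
the filtered gene universe.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ComputationError
from .io import CONDITIONS, GENOTYPES, WEEKS, ExpressionMatrix

logger = logging.getLogger(__name__)

#: numpy.quantile method names accepted for the DIF_25% convention
QUANTILE_RULES = ("linear", "lower", "higher", "midpoint", "nearest")


@dataclasses.dataclass
class ContrastTable:
    """Per-gene log2(DMM/sham) contrasts per genotype and week.

    ``l_wt`` and ``l_ko`` are gene x week DataFrames over the same filtered
    universe; ``pseudocount`` is the TPM offset eps used in both ratios.
    """

    l_wt: pd.DataFrame
    l_ko: pd.DataFrame
    pseudocount: float

    @property
    def genes(self) -> pd.Index:
        return self.l_wt.index

    @property
    def weeks(self) -> list[int]:
        return list(self.l_wt.columns)


@dataclasses.dataclass
class DifTable:
    """Per-gene DIF scores and the per-week lower-quartile threshold."""

    dif: pd.DataFrame  # gene x week
    q25: dict[int, float]
    quantile_rule: str = "linear"
    quartile_scope: str = "per_week"

    @property
    def genes(self) -> pd.Index:
        return self.dif.index


@dataclasses.dataclass
class SelectionResult:
    """Per-week selected sets, their intersection, and overlap significance."""

    universe: list[str]
    per_week: dict[int, set[str]]
    common: set[str]
    overlap_p: float

    @property
    def universe_size(self) -> int:
        return len(self.universe)


def filter_expressed(matrix: ExpressionMatrix, tpm_min: float = 1.0) -> ExpressionMatrix:
    """Retain genes with TPM strictly above ``tpm_min`` in at least one sample.

    This defines the gene universe for every downstream statistic
    (contrasts, DIF quartile, overlap and enrichment backgrounds).
    """
    keep = (matrix.values > tpm_min).any(axis=1)
    if not keep.any():
        raise ComputationError(
            f"no expressed genes: no gene exceeds TPM {tpm_min} in any sample"
        )
    out = ExpressionMatrix(values=matrix.values.loc[keep], meta=matrix.meta)
    logger.info("expression filter: %d of %d genes with TPM > %g in >= 1 sample",
                keep.sum(), len(keep), tpm_min)
    return out


def log2_contrast(matrix: ExpressionMatrix, pseudocount: float = 1.0,
                  weeks: Iterable[int] = WEEKS) -> ContrastTable:
    """Compute L = log2((E_DMM + eps)/(E_sham + eps)) per genotype and week.

    Cell values are the pooled sample's TPM (the study design has one pool
    per cell) or the cell mean when replicates are present.  With eps = 0
    every used cell value must be positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    weeks = list(weeks)
    tables: dict[str, pd.DataFrame] = {}
    for genotype in GENOTYPES:
        cols = {}
        for week in weeks:
            e_dmm = matrix.cell_values(genotype, "DMM", week)
            e_sham = matrix.cell_values(genotype, "sham", week)
            if pseudocount == 0:
                for cond, e in (("DMM", e_dmm), ("sham", e_sham)):
                    if (e == 0).any():
                        gene = e.index[(e == 0).to_numpy().argmax()]
                        raise ComputationError(
                            f"zero TPM with pseudocount 0: gene {gene!r} in cell "
                            f"({genotype}, {cond}, week {week})"
                        )
            cols[week] = np.log2(e_dmm + pseudocount) - np.log2(e_sham + pseudocount)
        tables[genotype] = pd.DataFrame(cols)
    return ContrastTable(l_wt=tables["WT"], l_ko=tables["KO"],
                         pseudocount=pseudocount)


def dif_scores(contrasts: ContrastTable, quantile_rule: str = "linear",
               quartile_scope: str = "per_week") -> DifTable:
    """DIF = L_KO - L_WT per gene and week, plus the DIF_25% threshold.

    ``quartile_scope='per_week'`` takes the lower quartile of each week's
    DIF values over the full filtered universe; ``'pooled'`` pools both
    weeks' DIF values into a single threshold applied to every week.
    ``quantile_rule`` selects the numpy.quantile interpolation convention
    (default: linear interpolation between order statistics).
    """
    if quantile_rule not in QUANTILE_RULES:
        raise ValueError(f"unknown quantile rule {quantile_rule!r}")
    if quartile_scope not in ("per_week", "pooled"):
        raise ValueError(f"unknown quartile scope {quartile_scope!r}")
    if not contrasts.l_wt.index.equals(contrasts.l_ko.index):
        raise ComputationError("contrast tables cover different gene universes")
    dif = contrasts.l_ko - contrasts.l_wt
    if dif.isna().to_numpy().any():
        gene = dif.index[dif.isna().any(axis=1).to_numpy().argmax()]
        raise ComputationError(f"missing contrast for gene {gene!r}")
    if quartile_scope == "pooled":
        pooled = float(np.quantile(dif.to_numpy().ravel(), 0.25, method=quantile_rule))
        q25 = {int(w): pooled for w in dif.columns}
    else:
        q25 = {
            int(w): float(np.quantile(dif[w].to_numpy(), 0.25, method=quantile_rule))
            for w in dif.columns
        }
    return DifTable(dif=dif, q25=q25, quantile_rule=quantile_rule,
                    quartile_scope=quartile_scope)


def select_week(contrasts: ContrastTable, difs: DifTable, week: int) -> set[str]:
    """Genes passing requirements (i)-(iii) at one week, strict inequalities."""
    if week not in contrasts.weeks:
        raise ValueError(f"week {week!r} not in design weeks {contrasts.weeks}")
    mask = (
        (contrasts.l_ko[week] < 0)
        & (contrasts.l_wt[week] > 0)
        & (difs.dif[week] < difs.q25[week])
    )
    return set(contrasts.genes[mask])


def common_genes(set_w2: set[str], set_w4: set[str]) -> set[str]:
    """Requirement (iv): genes selected at both timepoints."""
    return set(set_w2) & set(set_w4)


def overlap_pvalue(k: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for an observed set overlap.

    Population ``N`` (the filtered universe), ``n1`` marked successes,
    ``n2`` draws, ``k`` observed overlap.
    """
    if not (0 <= k <= min(n1, n2) <= N and max(n1, n2) <= N):
        raise ValueError(
            f"inconsistent overlap counts: k={k}, n1={n1}, n2={n2}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, n1, n2))


def run_selection(matrix: ExpressionMatrix, tpm_min: float = 1.0,
                  pseudocount: float = 1.0, quantile_rule: str = "linear",
                  quartile_scope: str = "per_week",
                  weeks: Iterable[int] = WEEKS,
                  ) -> tuple[ExpressionMatrix, ContrastTable, DifTable, SelectionResult]:
    """Filter -> contrasts -> DIF -> per-week selection -> intersection -> overlap p."""
    filtered = filter_expressed(matrix, tpm_min=tpm_min)
    contrasts = log2_contrast(filtered, pseudocount=pseudocount, weeks=weeks)
    difs = dif_scores(contrasts, quantile_rule=quantile_rule,
                      quartile_scope=quartile_scope)
    per_week = {int(w): select_week(contrasts, difs, int(w)) for w in contrasts.weeks}
    wk = sorted(per_week)
    common = set.intersection(*(per_week[w] for w in wk)) if per_week else set()
    n = len(filtered.gene_ids)
    if len(wk) == 2:
        p = overlap_pvalue(len(common), len(per_week[wk[0]]), len(per_week[wk[1]]), n)
    else:
        p = float("nan")
    for w in wk:
        logger.info("week %d: %d genes pass (i)-(iii); DIF_25%% = %.4f",
                    w, len(per_week[w]), difs.q25[w])
    logger.info("common genes: %d of universe %d (overlap p = %.3g)",
                len(common), n, p)
    result = SelectionResult(universe=list(filtered.gene_ids), per_week=per_week,
                             common=common, overlap_p=p)
    return filtered, contrasts, difs, result


def genewise_scale(matrix: ExpressionMatrix, genes: Iterable[str]) -> pd.DataFrame:
    """Z-score each gene's TPM row across samples (mean 0, sample sd).

    Standardisation uses the sample standard deviation (ddof=1), the usual
    heat-map convention.  Constant rows cannot be scaled; they are emitted
    as all-zero with a warning.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"gene(s) absent from matrix: {missing[:5]}")
    sub = matrix.values.loc[genes]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s) emitted as zeros",
            stacklevel=2,
        )
    scaled = sub.sub(mu, axis=0).div(sd.where(~constant, 1.0), axis=0)
    scaled[constant] = 0.0
    return scaled


def export_dif_attributes(difs: DifTable, genes: Iterable[str],
                          week_policy: str = "per_week") -> pd.DataFrame:
    """Node-attribute table of DIF scores for external network rendering.

    ``week_policy='per_week'`` emits one DIF column per week;
    ``'mean'`` emits their average as a single ``DIF`` column.
    """
    genes = sorted(genes)
    missing = [g for g in genes if g not in difs.dif.index]
    if missing:
        raise KeyError(f"gene(s) absent from DIF table: {missing[:5]}")
    sub = difs.dif.loc[genes]
    if week_policy == "per_week":
        out = pd.DataFrame({"gene": genes})
        for w in sub.columns:
            out[f"DIF_w{int(w)}"] = sub[w].to_numpy()
    elif week_policy == "mean":
        out = pd.DataFrame({"gene": genes, "DIF": sub.mean(axis=1).to_numpy()})
    else:
        raise ValueError(f"unknown week policy {week_policy!r}")
    return out
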
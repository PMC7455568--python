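"""End-to-end pipeline: filter -> contrasts -> DIF -> selection -> enrichment.

`run_pipeline` wires the stages together from file paths, writes every
result table plus a JSON run manifest (config echo, input digests, stage
summary numbers, tool version) that fully determines a re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import enrich_mouse_query
from .errors import DifselError
from .io import (
    ExpressionMatrix,
    read_expression_matrix,
    read_gmt,
    read_ortholog_map,
    write_results,
)
from .selection import export_dif_attributes, genewise_scale, run_selection

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "tpm_min": float,
    "pseudocount": float,
    "quantile_rule": str,
    "quartile_scope": str,
    "week_policy": str,
}


@dataclasses.dataclass
class PipelineConfig:
    """Tunables of the selection stage (strictness of the rule is fixed)."""

    tpm_min: float = 1.0
    pseudocount: float = 1.0
    quantile_rule: str = "linear"
    quartile_scope: str = "per_week"
    week_policy: str = "per_week"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a plain-text ``key = value`` config file."""
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise DifselError(f"{path}: line {lineno}: expected key = value")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in _CONFIG_FIELDS:
                    raise DifselError(f"{path}: line {lineno}: unknown key {key!r}")
                kwargs[key] = _CONFIG_FIELDS[key](value.strip())
        return cls(**kwargs)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_selection_table(contrasts, difs, result) -> pd.DataFrame:
    """Per-gene table of contrasts, DIF and pass flags for selected genes."""
    genes = sorted(result.common)
    rows = {"gene": genes}
    for w in contrasts.weeks:
        rows[f"L_WT_w{w}"] = contrasts.l_wt.loc[genes, w].to_numpy()
        rows[f"L_KO_w{w}"] = contrasts.l_ko.loc[genes, w].to_numpy()
        rows[f"DIF_w{w}"] = difs.dif.loc[genes, w].to_numpy()
        rows[f"pass_w{w}"] = [g in result.per_week[w] for g in genes]
    return pd.DataFrame(rows)


def build_overlap_table(result) -> pd.DataFrame:
    weeks = sorted(result.per_week)
    row = {f"n_week{w}": len(result.per_week[w]) for w in weeks}
    row.update(
        n_common=len(result.common),
        universe_size=result.universe_size,
        hypergeom_p=result.overlap_p,
    )
    return pd.DataFrame([row])


def run_pipeline(
    matrix_path: str | Path,
    samples_path: str | Path,
    out_dir: str | Path,
    gmt_path: str | Path | None = None,
    orthologs_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    skip_enrichment_on_missing: bool = False,
    seed: int | None = None,
) -> dict:
    """Execute the full analysis and write result tables plus a manifest.

    Enrichment needs both a GMT collection and an ortholog map; when
    either is missing it is skipped with a warning if
    ``skip_enrichment_on_missing`` is set, otherwise it is an error.
    Returns the manifest dict.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_expression_matrix(matrix_path, samples_path)
    filtered, contrasts, difs, result = run_selection(
        matrix,
        tpm_min=cfg.tpm_min,
        pseudocount=cfg.pseudocount,
        quantile_rule=cfg.quantile_rule,
        quartile_scope=cfg.quartile_scope,
    )

    enrichment = None
    inputs = {"matrix": str(matrix_path), "samples": str(samples_path)}
    if gmt_path is not None and orthologs_path is not None:
        collection = read_gmt(gmt_path)
        omap = read_ortholog_map(orthologs_path)
        enrichment = enrich_mouse_query(
            result.common, result.universe, collection, omap
        )
        inputs.update(gmt=str(gmt_path), orthologs=str(orthologs_path))
    elif not skip_enrichment_on_missing:
        raise DifselError(
            "enrichment inputs missing (GMT and/or ortholog map); "
            "pass --skip-enrichment-on-missing to proceed without enrichment"
        )
    else:
        logger.warning("enrichment skipped: GMT and/or ortholog map not provided")

    selected = build_selection_table(contrasts, difs, result)
    overlap = build_overlap_table(result)
    attributes = export_dif_attributes(difs, result.common,
                                       week_policy=cfg.week_policy)
    write_results(out, selected, overlap, attributes, enrichment)
    if result.common:
        scaled = genewise_scale(filtered, sorted(result.common))
        scaled.to_csv(out / "scaled_expression.tsv", sep="\t",
                      index_label="gene", float_format="%.17g")

    manifest = {
        "tool": "difsel",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {name: {"path": p, "sha256": _digest(p)}
                   for name, p in inputs.items()},
        "universe_size": result.universe_size,
        "per_week_sizes": {str(w): len(s) for w, s in result.per_week.items()},
        "n_common": len(result.common),
        "overlap_p": result.overlap_p,
        "dif_q25": {str(w): q for w, q in difs.q25.items()},
        "top_enrichment": (
            enrichment.head(10).to_dict(orient="records")
            if enrichment is not None else None
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
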
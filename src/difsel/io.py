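"""Readers and writers for the pipeline's external formats.

Formats handled here: gene x sample TPM matrices with a sample sheet
(genotype, surgery condition, week), GMT gene-set collections in the
MSigDB dialect, two-column human/mouse ortholog maps, and the TSV result
tables the selection and enrichment stages emit.

Conventions fixed at load time so every downstream comparison happens in
a single namespace: human symbols are uppercased, mouse symbols are
capitalized, duplicate gene rows are collapsed deterministically to the
row with the largest total TPM.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

GENOTYPES = ("WT", "KO")
CONDITIONS = ("sham", "DMM")
WEEKS = (2, 4)

#: float format preserving round-trip identity through TSV
_FLOAT_FMT = "%.17g"


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with per-sample design metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Non-negative TPM values, index = unique gene symbols,
        columns = sample ids in sample-sheet order.
    meta : pandas.DataFrame
        Indexed by sample id with columns ``genotype`` (WT/KO),
        ``condition`` (sham/DMM) and ``week`` (2/4). The canonical
        study design has exactly one pooled sample per design cell;
        replicated cells are accepted and mean-aggregated downstream.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_cell(self, genotype: str, condition: str, week: int) -> list[str]:
        m = self.meta
        mask = (
            (m["genotype"] == genotype)
            & (m["condition"] == condition)
            & (m["week"] == week)
        )
        return list(m.index[mask])

    def cell_values(self, genotype: str, condition: str, week: int) -> pd.Series:
        """Per-gene TPM for one design cell (mean over replicates)."""
        cols = self.samples_in_cell(genotype, condition, week)
        if not cols:
            raise MetadataError(
                f"design cell ({genotype}, {condition}, week {week}) has no sample"
            )
        return self.values[cols].mean(axis=1)

    def validate(self) -> "ExpressionMatrix":
        v = self.values.to_numpy()
        if not np.isfinite(v).all():
            raise FormatError("expression matrix contains non-finite values")
        if (v < 0).any():
            g, s = np.argwhere(v < 0)[0]
            raise FormatError(
                f"negative TPM at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene symbol after load: {dup!r}")
        for gt in GENOTYPES:
            for cond in CONDITIONS:
                for wk in WEEKS:
                    if not self.samples_in_cell(gt, cond, wk):
                        raise MetadataError(
                            f"design cell ({gt}, {cond}, week {wk}) has no sample"
                        )
        return self


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (human symbol namespace for hallmark collections)."""

    sets: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclasses.dataclass
class OrthologMap:
    """Deduplicated (human_symbol, mouse_symbol) pairs; may be many-to-many."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.mouse_to_human: dict[str, set[str]] = {}
        self.human_to_mouse: dict[str, set[str]] = {}
        for hu, mo in self.pairs:
            self.mouse_to_human.setdefault(mo, set()).add(hu)
            self.human_to_mouse.setdefault(hu, set()).add(mo)

    def __len__(self) -> int:
        return len(self.pairs)


def _parse_week(token: str | int) -> int:
    try:
        week = int(token)
    except (TypeError, ValueError):
        raise MetadataError(f"unknown week token {token!r}") from None
    if week not in WEEKS:
        raise MetadataError(f"unknown week token {token!r} (expected 2 or 4)")
    return week


def _collapse_duplicates(values: pd.DataFrame) -> pd.DataFrame:
    """Keep, per symbol, the row with maximal total TPM.

    Deterministic and order-independent: ties on the total are broken by
    the lexicographically largest row vector, so permuting input rows
    cannot change the outcome.
    """
    if not values.index.has_duplicates:
        return values
    totals = values.sum(axis=1).to_numpy()
    keep: dict[str, int] = {}
    for i, sym in enumerate(values.index):
        j = keep.get(sym)
        if j is None:
            keep[sym] = i
        elif (totals[i], tuple(values.iloc[i])) > (totals[j], tuple(values.iloc[j])):
            keep[sym] = i
    return values.iloc[sorted(keep.values(), key=lambda i: values.index[i])]


def read_expression_matrix(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    id_to_symbol: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Load a TPM matrix plus sample sheet into a validated ExpressionMatrix.

    The matrix TSV has a header row of sample ids and gene symbols in the
    first column; the sample sheet needs columns ``sample_id``,
    ``genotype``, ``condition``, ``week``. ``id_to_symbol`` optionally
    translates deposited gene identifiers (e.g. Ensembl) to symbols
    before duplicate collapsing.
    """
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "condition", "week"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"sample sheet missing columns: {sorted(required - set(sheet.columns))}"
        )
    meta = pd.DataFrame(
        {
            "genotype": sheet["genotype"].tolist(),
            "condition": sheet["condition"].tolist(),
            "week": [_parse_week(w) for w in sheet["week"]],
        },
        index=pd.Index(sheet["sample_id"].tolist(), name="sample_id"),
    )
    for col, allowed in (("genotype", GENOTYPES), ("condition", CONDITIONS)):
        bad = set(meta[col]) - set(allowed)
        if bad:
            raise MetadataError(f"unknown {col} token(s): {sorted(bad)}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise FormatError(f"duplicate sample id in sheet: {dup!r}")

    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    missing = set(meta.index) - set(raw.columns)
    if missing:
        raise FormatError(
            f"sample(s) in sheet absent from matrix: {sorted(missing)}"
        )
    extra = set(raw.columns) - set(meta.index)
    if extra:
        raise FormatError(
            f"sample(s) in matrix absent from sheet: {sorted(extra)}"
        )
    values = raw[list(meta.index)]
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any():
            row = values.index[coerced.isna().to_numpy().argmax()]
            raise FormatError(
                f"non-numeric TPM at gene {row!r}, sample {col!r}"
            )
    values = values.astype(float)
    values.index = values.index.astype(str)
    if id_to_symbol is not None:
        values.index = pd.Index(
            [id_to_symbol.get(g, g) for g in values.index], name=values.index.name
        )
    values = _collapse_duplicates(values)
    values = values.sort_index()
    return ExpressionMatrix(values=values, meta=meta).validate()


def write_expression_matrix(
    matrix: ExpressionMatrix, matrix_path: str | Path, sample_sheet_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene",
                         float_format=_FLOAT_FMT)
    sheet = matrix.meta.reset_index()
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, then members per line).

    Members are uppercased into the human symbol namespace; duplicate set
    names are an error.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} is empty")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Load a two-column (human_symbol, mouse_symbol) TSV, optional header.

    Human symbols are uppercased, mouse symbols capitalized; duplicate
    pairs are dropped.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(
                    f"{path}: line {lineno}: expected two non-empty fields"
                )
            hu, mo = fields[0].strip(), fields[1].strip()
            if lineno == 1 and {hu.lower(), mo.lower()} & {
                "human", "human_symbol", "mouse", "mouse_symbol",
            }:
                continue  # header row
            pair = (hu.upper(), mo.capitalize())
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("human_symbol\tmouse_symbol\n")
        for hu, mo in omap.pairs:
            fh.write(f"{hu}\t{mo}\n")


def write_results(
    out_dir: str | Path,
    selected_genes: pd.DataFrame,
    overlap: pd.DataFrame,
    node_attributes: pd.DataFrame,
    enrichment: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the result tables as TSV under ``out_dir``.

    Emits ``selected_genes.tsv``, ``overlap.tsv``, ``node_attributes.tsv``
    and, when an enrichment table is given, ``enrichment.tsv``. Floats are
    serialized at full round-trip precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables: list[tuple[str, pd.DataFrame]] = [
        ("selected_genes", selected_genes),
        ("overlap", overlap),
        ("node_attributes", node_attributes),
    ]
    if enrichment is not None:
        tables.append(("enrichment", enrichment))
    for name, table in tables:
        p = out / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths[name] = p
    return paths
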
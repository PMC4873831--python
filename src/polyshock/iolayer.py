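"""Tabular I/O and in-memory containers.

All external interfaces are UTF-8 TSV:

* expression matrix — first column ``gene_id``, remaining columns sample ids,
  values on the log2 scale (already normalized upstream; a ``log2_transform``
  flag applies log2(x+1) for linear-scale inputs);
* sample manifest — columns ``sample_id role tissue generation replicate``;
* homeolog table — columns ``gene_id sample_id a_fraction`` (proportion or
  percent, auto-detected);
* call tables — fixed column order, sorted rows, 6-decimal reals, so repeated
  writes are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("polyshock.iolayer")

ROLES = ("parentA", "parentB", "mix", "polyploid", "natural")
MANIFEST_COLUMNS = ("sample_id", "role", "tissue", "generation", "replicate")

#: Column order of gene-category call tables (one row per gene x tissue x
#: generation; ``pattern`` is the expression-space label).
CATEGORY_CALL_COLUMNS = (
    "gene_id",
    "tissue",
    "generation",
    "parental_status",
    "ped_direction",
    "additivity",
    "pattern",
    "mpv",
)

#: Column order of homeolog partitioning call tables.
PARTITIONING_CALL_COLUMNS = (
    "gene_id",
    "tissue",
    "generation",
    "expression_class",
    "altered",
    "outcome",
    "mix_mean_fraction",
    "poly_mean_fraction",
    "p_altered",
    "mix_biased",
    "poly_biased",
)

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


@dataclass(frozen=True)
class SampleMeta:
    """One sample's manifest entry."""

    sample_id: str
    role: str
    tissue: str
    generation: str
    replicate: int


@dataclass
class ExpressionDataset:
    """Genes x samples log2 expression with per-sample metadata.

    ``values`` is indexed by gene_id with one column per sample (column order
    equals manifest order); ``manifest`` is indexed by sample_id.
    """

    values: pd.DataFrame
    manifest: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[SampleMeta]:
        return [
            SampleMeta(sid, r.role, r.tissue, r.generation, int(r.replicate))
            for sid, r in self.manifest.iterrows()
        ]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_ids(self, role=None, tissue=None, generation=None) -> list[str]:
        """Sample ids matching the given metadata filters, in manifest order."""
        m = self.manifest
        mask = pd.Series(True, index=m.index)
        if role is not None:
            mask &= m["role"] == role
        if tissue is not None:
            mask &= m["tissue"] == tissue
        if generation is not None:
            mask &= m["generation"] == generation
        return list(m.index[mask])

    def matrix(self, sample_ids) -> np.ndarray:
        """Values for the given samples as a genes x samples float array."""
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return self.values.loc[:, list(sample_ids)].to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(gene_ids)], self.manifest)

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(self.values.loc[:, ids], self.manifest.loc[ids])

    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.manifest["tissue"]:
            seen.setdefault(t, None)
        return list(seen)


@dataclass
class HomeologTable:
    """Long-format A-subgenome allele fractions (pyrosequencing analog).

    ``frame`` has columns gene_id, sample_id, a_fraction with fractions in
    [0, 1]; the B fraction is 1 - a_fraction by construction.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene_id", "sample_id", "a_fraction"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"homeolog table requires columns {sorted(need)}")

    def fractions(self, gene_id: str, sample_ids) -> np.ndarray:
        f = self.frame
        sel = f[(f["gene_id"] == gene_id) & f["sample_id"].isin(list(sample_ids))]
        return sel["a_fraction"].to_numpy(dtype=float)


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a sample manifest TSV."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(raw.columns) != list(MANIFEST_COLUMNS):
        raise ValueError(
            f"manifest columns must be {list(MANIFEST_COLUMNS)}, got {list(raw.columns)}"
        )
    dup = raw["sample_id"][raw["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample_id in manifest: {sorted(set(dup))}")
    bad_roles = sorted(set(raw["role"]) - set(ROLES))
    if bad_roles:
        raise ValueError(f"unknown role token(s) {bad_roles}; allowed: {list(ROLES)}")
    try:
        reps = raw["replicate"].astype(int)
    except ValueError as exc:
        raise ValueError(f"non-integer replicate in manifest: {exc}") from exc
    if (reps < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    out = raw.assign(replicate=reps).set_index("sample_id", drop=False)
    out.index.name = None
    return out


def read_expression(matrix_path, manifest_path, *, log2_transform: bool = False) -> ExpressionDataset:
    """Assemble a validated :class:`ExpressionDataset` from TSV files.

    Genes keep their input order; samples are ordered as in the manifest.
    Rows containing missing values are dropped and logged; a non-numeric,
    non-missing cell is an error naming its gene and sample.
    """
    manifest = read_manifest(manifest_path)
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "gene_id":
        raise ValueError(f"first matrix column must be 'gene_id', got {raw.columns[0]!r}")
    genes = raw["gene_id"]
    dup = genes[genes.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate gene_id in matrix: {sorted(set(dup))}")

    matrix_samples = list(raw.columns[1:])
    manifest_samples = list(manifest.index)
    only_manifest = sorted(set(manifest_samples) - set(matrix_samples))
    only_matrix = sorted(set(matrix_samples) - set(manifest_samples))
    if only_manifest or only_matrix:
        parts = []
        if only_manifest:
            parts.append(f"in manifest but not matrix: {only_manifest}")
        if only_matrix:
            parts.append(f"in matrix but not manifest: {only_matrix}")
        raise ValueError("manifest/matrix sample mismatch: " + "; ".join(parts))

    values = raw.set_index("gene_id")[manifest_samples]
    missing_mask = values.apply(lambda col: col.str.strip().str.lower().isin(_MISSING_TOKENS))
    numeric = values.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & ~missing_mask
    if bad.to_numpy().any():
        g = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[g]][0]
        raise ValueError(
            f"non-numeric expression value {values.loc[g, s]!r} at gene {g!r}, sample {s!r}"
        )
    drop = numeric.isna().any(axis=1)
    if drop.any():
        dropped = list(numeric.index[drop])
        logger.info(
            "dropping %d gene row(s) with missing values: %s%s",
            len(dropped),
            dropped[:10],
            " ..." if len(dropped) > 10 else "",
        )
        numeric = numeric[~drop]
    numeric = numeric.astype(float)
    if log2_transform:
        numeric = np.log2(numeric + 1.0)
    return ExpressionDataset(values=numeric, manifest=manifest)


def read_homeolog(path) -> HomeologTable:
    """Read an allele-fraction TSV, normalizing fractions to [0, 1].

    The scale (percent vs proportion) is auto-detected: any value above 1
    marks the file as percent-scale.  A percent-scale file that also contains
    nonzero values below 1 is rejected as mixing the two conventions.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    need = ["gene_id", "sample_id", "a_fraction"]
    if list(raw.columns)[:3] != need:
        raise ValueError(f"homeolog table columns must start with {need}, got {list(raw.columns)}")
    frac = pd.to_numeric(raw["a_fraction"], errors="raise").astype(float)
    if ((frac < 0) | (frac > 100)).any():
        bad = raw.loc[(frac < 0) | (frac > 100)].iloc[0]
        raise ValueError(
            f"a_fraction outside [0, 100] at gene {bad['gene_id']!r}, sample {bad['sample_id']!r}"
        )
    if (frac > 1.0).any():
        nonzero = frac[frac > 0]
        if (nonzero < 1.0).any():
            raise ValueError(
                "ambiguous a_fraction scale: file mixes percent-scale (>1) and "
                "proportion-scale (<1) values"
            )
        logger.info("a_fraction detected as percent scale; dividing by 100")
        frac = frac / 100.0
    else:
        logger.info("a_fraction detected as proportion scale")
    return HomeologTable(raw.assign(a_fraction=frac)[need])


def _call_columns(calls: pd.DataFrame) -> tuple[str, ...]:
    if "pattern" in calls.columns:
        return CATEGORY_CALL_COLUMNS
    if "outcome" in calls.columns:
        return PARTITIONING_CALL_COLUMNS
    raise ValueError("unrecognized call table: expected a 'pattern' or 'outcome' column")


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write a call table deterministically (sorted, fixed columns, 6-decimal reals)."""
    cols = _call_columns(calls)
    missing = [c for c in cols if c not in calls.columns]
    if missing:
        raise ValueError(f"call table is missing columns {missing}")
    out = calls.loc[:, list(cols)].sort_values(
        ["tissue", "generation", "gene_id"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def read_calls(path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _call_columns(df)
    if list(df.columns) != list(cols):
        raise ValueError(f"call table columns must be {list(cols)}, got {list(df.columns)}")
    for c in df.columns:
        if c in ("mpv", "mix_mean_fraction", "poly_mean_fraction", "p_altered"):
            df[c] = pd.to_numeric(df[c]).astype(float)
        elif c in ("altered", "mix_biased", "poly_biased"):
            df[c] = df[c].map({"True": True, "False": False})
            if df[c].isna().any():
                raise ValueError(f"column {c!r} must contain True/False")
            df[c] = df[c].astype(bool)
    return df


def write_expression(dataset: ExpressionDataset, matrix_path, manifest_path) -> None:
    """Write an expression matrix + manifest (full float precision)."""
    out = dataset.values.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(matrix_path, sep="\t", index=False, lineterminator="\n")
    dataset.manifest.loc[:, list(MANIFEST_COLUMNS)].to_csv(
        manifest_path, sep="\t", index=False, lineterminator="\n"
    )


def write_homeolog(table: HomeologTable, path) -> None:
    """Write a homeolog fraction table (proportion scale, full precision)."""
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
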
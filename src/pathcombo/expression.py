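"""Expression-matrix I/O, quantile normalization and case-to-normal ratios.

The matrix holds non-negative linear-scale intensities (genes × samples)
together with per-sample metadata: cell line, drug, exposure timepoint in
weeks, and a control flag.  Controls are the drug-free cultures profiled
alongside the treated ones; a case sample's reference is the geometric
mean of all control samples of the same cell line ("pooled controls"),
pooling across control timepoints.

Processing order is quantile normalization first, then the case-to-normal
ratio (CNR).  Normalization and ratios operate on linear intensities; the
log10 happens downstream in the pathway score.  A configurable intensity
floor (default 1.0) is applied to both the case value and the pooled
control value so near-zero intensities cannot produce infinite log-ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pathway_model import normalize_gene_symbol

log = logging.getLogger(__name__)

METADATA_COLUMNS = ("cell_line", "drug", "timepoint_weeks", "is_control")


@dataclass
class ExpressionMatrix:
    """Genes × samples intensity matrix plus per-sample metadata.

    ``values``: DataFrame indexed by gene symbol, columns = sample ids.
    ``metadata``: DataFrame indexed by sample id with columns
    ``cell_line``, ``drug``, ``timepoint_weeks``, ``is_control``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = sorted(v.index[v.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene symbols: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            bad = v.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative intensity for gene {bad!r}")
        missing_meta = [s for s in v.columns if s not in self.metadata.index]
        if missing_meta:
            raise ValidationError(
                f"samples missing from metadata: {missing_meta}"
            )
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks column {col!r}")
        if not self.metadata.loc[list(v.columns), "is_control"].any():
            raise ValidationError("matrix has no control sample")

    @property
    def genes(self) -> Tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def samples(self) -> Tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def control_samples(self) -> Tuple[str, ...]:
        m = self.metadata.loc[list(self.values.columns)]
        return tuple(m.index[m["is_control"].astype(bool)])

    @property
    def case_samples(self) -> Tuple[str, ...]:
        m = self.metadata.loc[list(self.values.columns)]
        return tuple(m.index[~m["is_control"].astype(bool)])

    def condition_of(self, sample: str) -> Tuple[str, str, int]:
        row = self.metadata.loc[sample]
        return (
            str(row["cell_line"]),
            str(row["drug"]),
            int(row["timepoint_weeks"]),
        )


@dataclass(frozen=True)
class CnrVector:
    """Per-gene case-to-normal expression ratios for one case sample."""

    sample: str
    ratios: pd.Series  # gene -> positive finite ratio

    def __post_init__(self) -> None:
        r = self.ratios.to_numpy(dtype=float)
        if not np.isfinite(r).all() or (r <= 0).any():
            raise ValidationError(
                f"sample {self.sample!r}: CNR values must be finite and > 0"
            )

    def __getitem__(self, gene: str) -> float:
        return float(self.ratios[normalize_gene_symbol(gene)])

    def __len__(self) -> int:
        return len(self.ratios)


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        s = x.strip().lower()
        if s in {"1", "true", "yes", "y"}:
            return True
        if s in {"0", "false", "no", "n"}:
            return False
        raise ValidationError(f"cannot parse boolean {x!r}")
    return bool(x)


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read a genes × samples TSV plus its sample-metadata TSV.

    Gene symbols are uppercase-normalized; duplicate gene rows (multiple
    probes mapping to one symbol) are collapsed by the per-sample maximum
    intensity, with a warning.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = [normalize_gene_symbol(str(g)) for g in values.index]
    values.index.name = "gene"
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric expression values")
    if (arr < 0).any():
        bad = values.index[(values < 0).any(axis=1)][0]
        raise ValidationError(f"{path}: negative intensity for gene {bad!r}")
    if values.index.has_duplicates:
        dupes = sorted(values.index[values.index.duplicated()].unique())
        log.warning(
            "%s: collapsing %d duplicated gene symbol(s) by per-sample max "
            "(e.g. %s)", path, len(dupes), dupes[0],
        )
        values = values.groupby(level=0, sort=False).max()

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ValidationError(f"{metadata_path}: metadata lacks 'sample' column")
    meta = meta.set_index("sample")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"{metadata_path}: metadata lacks column {col!r}")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValidationError(
            f"{metadata_path}: no metadata for sample(s) {missing}"
        )
    meta = meta.loc[list(values.columns)].copy()
    meta["timepoint_weeks"] = meta["timepoint_weeks"].astype(int)
    meta["is_control"] = meta["is_control"].map(_parse_bool)
    return ExpressionMatrix(values.astype(float), meta)


def read_series_matrix(path) -> pd.DataFrame:
    """Convenience reader for GEO series-matrix text: skips '!' comment
    lines and returns the raw genes × samples table (no metadata)."""
    rows = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("!")
    ]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(rows)), sep="\t", index_col=0)
    df.index = [normalize_gene_symbol(str(g)) for g in df.index]
    return df


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to their common mean distribution.

    Every sample's sorted intensity vector becomes the across-sample mean
    of sorted vectors; within-sample rank order is preserved.  Ties within
    a sample receive the mean of the reference values at the tied ranks.
    """
    vals = m.values.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    if n_genes < 2:
        log.warning("quantile normalization skipped: single-gene matrix")
        return ExpressionMatrix(m.values.copy(), m.metadata.copy())
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n_genes)
        ranked[order] = reference
        # ties: replace each tied group's values with the group mean
        uniq, inverse, counts = np.unique(
            col, return_inverse=True, return_counts=True
        )
        if len(uniq) < n_genes:
            sums = np.bincount(inverse, weights=ranked)
            ranked = (sums / counts)[inverse]
        out[:, j] = ranked
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.metadata.copy())


def compute_cnr(
    m: ExpressionMatrix, case_sample: str, floor: float = 1.0
) -> CnrVector:
    """Case-to-normal ratio of one case sample against pooled controls.

    For each gene: ``max(case, floor) / max(geomean(controls), floor)``
    where the geometric mean pools every control sample of the case's
    cell line.  ``floor`` must be positive; it guards against zero
    intensities on either side of the ratio.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be positive, got {floor}")
    if case_sample not in m.values.columns:
        raise ValidationError(f"unknown sample {case_sample!r}")
    meta = m.metadata
    if _parse_bool(meta.loc[case_sample, "is_control"]):
        raise ValidationError(f"{case_sample!r} is a control sample")
    cell_line = meta.loc[case_sample, "cell_line"]
    controls = [
        s
        for s in m.control_samples
        if meta.loc[s, "cell_line"] == cell_line
    ]
    if not controls:
        raise ValidationError(
            f"no control samples for cell line {cell_line!r}"
        )
    ctrl = m.values[controls].to_numpy(dtype=float)
    # geometric mean per gene; any zero value makes the geomean zero
    with np.errstate(divide="ignore"):
        logs = np.log(ctrl)
    geomean = np.where(
        (ctrl == 0).any(axis=1), 0.0, np.exp(np.mean(logs, axis=1))
    )
    case = m.values[case_sample].to_numpy(dtype=float)
    ratios = np.maximum(case, floor) / np.maximum(geomean, floor)
    return CnrVector(
        case_sample, pd.Series(ratios, index=m.values.index, name=case_sample)
    )
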
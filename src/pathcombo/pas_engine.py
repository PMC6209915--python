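"""Pathway activation strength (PAS) scoring and dispersion summaries.

For a pathway *p* and a case sample, the score is

    PAS_p = Σ_n ARR_np × log10(CNR_n)

summed over member genes *n* measured in the sample.  A positive PAS means
the pathway is upregulated relative to the pooled controls, negative means
downregulated, and zero means no change.  Member genes absent from the
expression data contribute 0 (equivalent to CNR = 1), which keeps the
all-controls-equal case exactly at PAS 0; the fraction of members actually
measured is reported as per-pathway coverage.

The score is intentionally not normalized by pathway size; a
size-normalized variant is available behind ``size_normalize=True`` for
sensitivity analysis only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import CnrVector, ExpressionMatrix, compute_cnr
from .pathway_model import PathwayDB

log = logging.getLogger(__name__)

ConditionKey = Tuple[str, str, int]  # (cell_line, drug, timepoint_weeks)


@dataclass(frozen=True)
class PasProfile:
    """All pathway scores for one case sample, plus member coverage."""

    sample: str
    pas: pd.Series       # pathway name -> signed score
    coverage: pd.Series  # pathway name -> fraction of members measured

    def __post_init__(self) -> None:
        if not np.isfinite(self.pas.to_numpy(dtype=float)).all():
            raise ValidationError(f"sample {self.sample!r}: non-finite PAS")

    def __len__(self) -> int:
        return len(self.pas)


@dataclass(frozen=True)
class PasSummary:
    """Across-pathway dispersion of PAS for one condition."""

    condition: ConditionKey
    sd: float
    n_pathways: int


def compute_pas(
    db: PathwayDB, cnr: CnrVector, size_normalize: bool = False
) -> PasProfile:
    """Score every pathway in ``db`` against one sample's CNR vector."""
    log_cnr: Dict[str, float] = {
        gene: float(np.log10(v)) for gene, v in cnr.ratios.items()
    }
    pas: Dict[str, float] = {}
    coverage: Dict[str, float] = {}
    uncovered: List[str] = []
    for pathway in db:
        measured = 0
        total = 0.0
        for gene, weight in pathway.members.items():
            lv = log_cnr.get(gene)
            if lv is None:
                continue
            measured += 1
            total += weight * lv
        cov = measured / len(pathway)
        if measured == 0:
            uncovered.append(pathway.name)
        if size_normalize and measured:
            total /= len(pathway)
        pas[pathway.name] = total
        coverage[pathway.name] = cov
    if uncovered:
        log.warning(
            "sample %s: %d pathway(s) with no measured member (PAS=0), "
            "e.g. %s", cnr.sample, len(uncovered), uncovered[0],
        )
    names = list(db.names)
    return PasProfile(
        cnr.sample,
        pd.Series(pas, name=cnr.sample).reindex(names),
        pd.Series(coverage, name=cnr.sample).reindex(names),
    )


def pas_matrix(
    db: PathwayDB,
    m: ExpressionMatrix,
    floor: float = 1.0,
    size_normalize: bool = False,
) -> List[PasProfile]:
    """One :class:`PasProfile` per non-control sample, in column order."""
    return [
        compute_pas(db, compute_cnr(m, s, floor=floor), size_normalize)
        for s in m.case_samples
    ]


def pas_dispersion(
    profiles: Iterable[PasProfile],
    conditions: Union[ExpressionMatrix, Mapping[str, ConditionKey]],
) -> List[PasSummary]:
    """Across-pathway standard deviation of PAS per condition.

    Replicate samples of the same (cell line, drug, timepoint) are first
    averaged per pathway; the summary is then the sample standard
    deviation (n−1 denominator) over pathways.  A condition must provide
    at least two pathway values.
    """
    if isinstance(conditions, ExpressionMatrix):
        cond_of = {s: conditions.condition_of(s) for s in conditions.samples}
    else:
        cond_of = dict(conditions)
    groups: Dict[ConditionKey, List[pd.Series]] = {}
    order: List[ConditionKey] = []
    for prof in profiles:
        try:
            key = cond_of[prof.sample]
        except KeyError:
            raise ValidationError(
                f"no condition metadata for sample {prof.sample!r}"
            ) from None
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(prof.pas)
    out: List[PasSummary] = []
    for key in order:
        mean_pas = pd.concat(groups[key], axis=1).mean(axis=1)
        if len(mean_pas) < 2:
            raise ValidationError(
                f"condition {key}: need at least 2 PAS values, "
                f"got {len(mean_pas)}"
            )
        out.append(
            PasSummary(key, float(mean_pas.std(ddof=1)), len(mean_pas))
        )
    return out


def write_pas_table(profiles: Iterable[PasProfile], path) -> None:
    """Write profiles as TSV: pathway, sample, pas, coverage_fraction."""
    rows = []
    for prof in profiles:
        for pathway in prof.pas.index:
            rows.append(
                (
                    pathway,
                    prof.sample,
                    f"{prof.pas[pathway]:.10g}",
                    f"{prof.coverage[pathway]:.6g}",
                )
            )
    lines = ["pathway\tsample\tpas\tcoverage_fraction"]
    lines += ["\t".join(map(str, r)) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pas_table(path) -> List[PasProfile]:
    """Inverse of :func:`write_pas_table`."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        profiles.append(
            PasProfile(
                str(sample),
                pd.Series(grp["pas"].to_numpy(), index=grp["pathway"]),
                pd.Series(
                    grp["coverage_fraction"].to_numpy(), index=grp["pathway"]
                ),
            )
        )
    return profiles
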
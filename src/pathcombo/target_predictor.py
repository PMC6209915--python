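"""Top-decile pathway intersection and candidate-target ranking.

The prediction step behind combination selection: take the 10% of
pathways with the highest (signed) PAS for a condition, intersect their
member-gene lists, and rank genes by how many of the selected pathways
contain them.  Genes hitting the maximum number of selected pathways are
the candidate targets; any inhibitor whose target set covers a top-ranked
gene becomes a suggested combination partner for the condition's baseline
drug.

Occurrence counting is by bare membership — the ARR weight (even 0) does
not change whether a gene counts toward a pathway.  Selection uses signed
PAS (upregulation) by default; ``use_abs=True`` switches to |PAS| for
sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import ValidationError
from .pas_engine import ConditionKey, PasProfile
from .pathway_model import DrugTargetMap, PathwayDB, normalize_gene_symbol

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetRank:
    gene: str
    count: int
    pathways: Tuple[str, ...]  # supporting selected pathways


@dataclass
class TargetRanking:
    """Genes ranked by occurrence among the selected pathways."""

    ranked: List[TargetRank]
    selected_pathways: List[Tuple[str, float]]  # (name, pas)
    condition: Optional[ConditionKey] = None

    def __post_init__(self) -> None:
        counts = [r.count for r in self.ranked]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValidationError("ranking counts must be non-increasing")
        selected = {name for name, _ in self.selected_pathways}
        for r in self.ranked:
            if not (1 <= r.count <= len(selected)):
                raise ValidationError(
                    f"gene {r.gene!r}: count {r.count} outside [1, "
                    f"{len(selected)}]"
                )
            if not set(r.pathways) <= selected:
                raise ValidationError(
                    f"gene {r.gene!r}: supporting pathways not a subset "
                    "of the selection"
                )

    @property
    def candidates(self) -> List[str]:
        """The maximal-count stratum (the predicted targets)."""
        if not self.ranked:
            return []
        top = self.ranked[0].count
        return [r.gene for r in self.ranked if r.count == top]


@dataclass(frozen=True)
class CombinationSuggestion:
    partner_drug: str
    matched_targets: FrozenSet[str]
    rank_basis: int  # best occurrence count among matched targets
    condition: Optional[ConditionKey] = None


def select_top_pathways(
    profile: Union[PasProfile, pd.Series],
    fraction: float = 0.10,
    use_abs: bool = False,
) -> List[str]:
    """The ceil(fraction·P) pathway names with the largest PAS.

    Ties at the selection boundary are broken by pathway name
    (lexicographic) so the result is deterministic and independent of
    input order; the list comes back sorted by PAS descending.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    pas = profile.pas if isinstance(profile, PasProfile) else profile
    if len(pas) == 0:
        raise ValidationError("empty PAS profile")
    k = math.ceil(fraction * len(pas))
    key = pas.abs() if use_abs else pas
    ordered = sorted(pas.index, key=lambda name: (-float(key[name]), name))
    return ordered[:k]


def rank_targets(
    db: PathwayDB,
    selected: Sequence[str],
    pas: Optional[pd.Series] = None,
    condition: Optional[ConditionKey] = None,
) -> TargetRanking:
    """Rank genes by the number of selected pathways containing them.

    Ties are broken lexicographically; the full ranking is returned and
    the maximal-count stratum is exposed as ``candidates``.
    """
    if not selected:
        raise ValidationError("no pathways selected")
    support: Dict[str, List[str]] = {}
    for name in selected:
        pathway = db.get(name)  # raises on unknown name
        for gene in pathway.members:
            support.setdefault(gene, []).append(name)
    ranked = [
        TargetRank(gene, len(paths), tuple(paths))
        for gene, paths in support.items()
    ]
    ranked.sort(key=lambda r: (-r.count, r.gene))
    selected_with_pas = [
        (name, float(pas[name]) if pas is not None else float("nan"))
        for name in selected
    ]
    return TargetRanking(ranked, selected_with_pas, condition)


def suggest_combinations(
    ranking: TargetRanking,
    drugs: DrugTargetMap,
    baseline_drug: str,
    top_n: int = 5,
    aliases: Optional[Mapping[str, str]] = None,
) -> List[CombinationSuggestion]:
    """Partner drugs whose targets cover the top-ranked genes.

    For each of the ``top_n`` highest-ranked genes, every drug whose
    target set contains the gene (or its alias label, e.g. a protein
    family name) is suggested; matches are aggregated per drug.  The
    condition's own baseline drug is never suggested.  Suggestions are
    ordered by (best occurrence count, drug name).
    """
    if not ranking.ranked:
        raise ValidationError("empty target ranking")
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    alias = {
        normalize_gene_symbol(k): normalize_gene_symbol(v)
        for k, v in (aliases or {}).items()
    }
    per_drug: Dict[str, Dict[str, int]] = {}
    for rank in ranking.ranked[:top_n]:
        labels = {rank.gene}
        if rank.gene in alias:
            labels.add(alias[rank.gene])
        for drug, targets in drugs.entries.items():
            if drug.strip().lower() == baseline_drug.strip().lower():
                continue
            if labels & targets:
                per_drug.setdefault(drug, {})[rank.gene] = rank.count
    suggestions = [
        CombinationSuggestion(
            drug,
            frozenset(matched),
            max(matched.values()),
            ranking.condition,
        )
        for drug, matched in per_drug.items()
    ]
    suggestions.sort(key=lambda s: (-s.rank_basis, s.partner_drug))
    if not suggestions:
        log.info(
            "no drug in the map targets any of the top %d ranked genes",
            top_n,
        )
    return suggestions


def write_ranking_tsv(
    rankings: Sequence[TargetRanking],
    path,
    aliases: Optional[Mapping[str, str]] = None,
) -> None:
    """TSV report: condition, gene (with optional alias label), count,
    candidate flag, supporting pathways."""
    alias = {
        normalize_gene_symbol(k): v for k, v in (aliases or {}).items()
    }
    lines = [
        "cell_line\tdrug\ttimepoint_weeks\tgene\tlabel\tcount\t"
        "is_candidate\tsupporting_pathways"
    ]
    for ranking in rankings:
        cond = ranking.condition or ("", "", "")
        cands = set(ranking.candidates)
        for r in ranking.ranked:
            lines.append(
                "\t".join(
                    [
                        str(cond[0]),
                        str(cond[1]),
                        str(cond[2]),
                        r.gene,
                        alias.get(r.gene, r.gene),
                        str(r.count),
                        "1" if r.gene in cands else "0",
                        ",".join(r.pathways),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_suggestions_json(
    suggestions_by_condition: Mapping[str, Sequence[CombinationSuggestion]],
    path,
) -> None:
    payload = {
        key: [
            {
                "partner_drug": s.partner_drug,
                "matched_targets": sorted(s.matched_targets),
                "rank_basis": s.rank_basis,
            }
            for s in suggestions
        ]
        for key, suggestions in suggestions_by_condition.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_alias_table(path) -> Dict[str, str]:
    """2-column TSV ``gene<TAB>label`` mapping symbols to report labels."""
    out: Dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or (i == 1 and line.lower().startswith("gene\t")):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}:{i}: expected 2 tab-separated fields"
            )
        out[normalize_gene_symbol(fields[0])] = fields[1].strip()
    return out
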
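"""Pathway knowledge base and drug→target map: data model and I/O.

A pathway is a named gene set in which every member carries an
activator/repressor role (ARR) weight: +1 for an activator of pathway
excitation, −1 for a repressor, ±0.5 when the gene product leans one way
without being a clear-cut activator/repressor, and 0 when it can act as
both.  The weights feed the pathway activation score; bare membership
(weight included, even 0) feeds the occurrence counting used for target
ranking, so zero-weight members are retained.

Two on-disk dialects are supported for the knowledge base:

* a 3-column TSV ``pathway<TAB>gene<TAB>arr`` with a header line, which
  carries the ARR weights, and
* plain GMT (``name<TAB>description<TAB>gene...``), in which case every
  weight defaults to +1 and a warning is logged.

The drug→target map is a 2-column TSV ``drug<TAB>targets`` (targets
comma-separated), header required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterator, List, Mapping, Tuple

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

#: the only legal ARR weights
ARR_VALUES: Tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)

PATHWAY_TSV_HEADER = ("pathway", "gene", "arr")
DRUG_MAP_HEADER = ("drug", "targets")


def normalize_gene_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol (idempotent)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class Pathway:
    """A named gene set with per-gene ARR weights.

    Gene symbols are uppercase-normalized at construction; a pathway must
    have at least one member and every weight must be one of
    {−1, −0.5, 0, 0.5, 1}.
    """

    name: str
    members: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("pathway name must be non-empty")
        normalized: Dict[str, float] = {}
        for gene, weight in dict(self.members).items():
            sym = normalize_gene_symbol(str(gene))
            if not sym:
                raise ValidationError(
                    f"pathway {self.name!r}: empty gene symbol"
                )
            if sym in normalized:
                raise ValidationError(
                    f"pathway {self.name!r}: duplicate gene {sym!r} "
                    "after case normalization"
                )
            w = float(weight)
            if w not in ARR_VALUES:
                raise ValidationError(
                    f"pathway {self.name!r}, gene {sym!r}: ARR weight {w} "
                    f"not in {ARR_VALUES}"
                )
            normalized[sym] = w
        if not normalized:
            raise ValidationError(f"pathway {self.name!r} has no members")
        object.__setattr__(self, "members", normalized)

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset(self.members)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_symbol(gene) in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PathwayDB:
    """An ordered, name-unique collection of :class:`Pathway`."""

    pathways: List[Pathway]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValidationError("pathway database is empty")
        names = [p.name for p in self.pathways]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate pathway names: {dupes}")
        self._by_name = {p.name: p for p in self.pathways}

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(p.name for p in self.pathways)

    @property
    def gene_universe(self) -> FrozenSet[str]:
        out: set = set()
        for p in self.pathways:
            out.update(p.members)
        return frozenset(out)

    def get(self, name: str) -> Pathway:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown pathway {name!r}") from None

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return (
            [(p.name, dict(p.members)) for p in self.pathways]
            == [(p.name, dict(p.members)) for p in other.pathways]
        )


@dataclass(frozen=True)
class DrugTargetMap:
    """Mapping drug name → non-empty set of target gene/protein symbols."""

    entries: Mapping[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        clean: Dict[str, FrozenSet[str]] = {}
        for drug, targets in dict(self.entries).items():
            name = str(drug).strip()
            if not name:
                raise ValidationError("empty drug name")
            tset = frozenset(normalize_gene_symbol(t) for t in targets)
            if not tset or "" in tset:
                raise ValidationError(f"drug {name!r}: empty target set")
            clean[name] = tset
        if not clean:
            raise ValidationError("drug→target map is empty")
        object.__setattr__(self, "entries", clean)

    @property
    def drugs(self) -> Tuple[str, ...]:
        return tuple(self.entries)

    def targets_of(self, drug: str) -> FrozenSet[str]:
        try:
            return self.entries[drug]
        except KeyError:
            raise ValidationError(f"unknown drug {drug!r}") from None

    def drugs_for_target(self, symbol: str) -> Tuple[str, ...]:
        sym = normalize_gene_symbol(symbol)
        return tuple(d for d, ts in self.entries.items() if sym in ts)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# I/O


def _read_lines(path) -> List[str]:
    text = Path(path).read_text()
    return text.splitlines()


def read_pathway_db(path) -> PathwayDB:
    """Read a pathway knowledge base from TSV (with ARR) or GMT.

    The TSV dialect is detected by its mandatory ``pathway gene arr``
    header; anything else is parsed as GMT with all weights defaulting to
    +1 (a warning is logged, since GMT cannot carry repressor roles).
    """
    lines = _read_lines(path)
    nonblank = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not nonblank:
        raise ValidationError(f"{path}: empty pathway file")

    first = tuple(f.strip().lower() for f in nonblank[0][1].split("\t"))
    if first[: len(PATHWAY_TSV_HEADER)] == PATHWAY_TSV_HEADER:
        return _read_pathway_tsv(path, nonblank[1:])
    return _read_gmt(path, nonblank)


def _read_pathway_tsv(path, rows) -> PathwayDB:
    acc: Dict[str, Dict[str, float]] = {}
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, gene, raw_w = (f.strip() for f in fields)
        try:
            weight = float(raw_w)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: ARR weight {raw_w!r} is not a number"
            ) from None
        if weight not in ARR_VALUES:
            raise ValidationError(
                f"{path}:{lineno}: ARR weight {weight} not in {ARR_VALUES}"
            )
        sym = normalize_gene_symbol(gene)
        members = acc.setdefault(name, {})
        if sym in members and members[sym] != weight:
            raise ValidationError(
                f"{path}:{lineno}: conflicting ARR weights for "
                f"({name!r}, {sym!r}): {members[sym]} vs {weight}"
            )
        members[sym] = weight
    if not acc:
        raise ValidationError(f"{path}: no pathway rows")
    pathways = [Pathway(name, members) for name, members in acc.items()]
    return PathwayDB(pathways, source=str(path))


def _read_gmt(path, rows) -> PathwayDB:
    log.warning(
        "%s: GMT input carries no activator/repressor roles; "
        "all ARR weights default to +1",
        path,
    )
    pathways: List[Pathway] = []
    seen = set()
    for lineno, line in rows:
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs name, description and "
                "at least one gene"
            )
        name = fields[0].strip()
        if name in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate pathway {name!r}")
        seen.add(name)
        genes = [g for g in fields[2:] if g.strip()]
        if not genes:
            raise ValidationError(f"{path}:{lineno}: pathway {name!r} has no genes")
        pathways.append(Pathway(name, {g: 1.0 for g in genes}))
    return PathwayDB(pathways, source=str(path))


def write_pathway_db(db: PathwayDB, path) -> None:
    """Write a PathwayDB in the 3-column TSV dialect (round-trip safe)."""
    out = ["\t".join(PATHWAY_TSV_HEADER)]
    for p in db:
        for gene, w in p.members.items():
            out.append(f"{p.name}\t{gene}\t{w:g}")
    Path(path).write_text("\n".join(out) + "\n")


def read_drug_target_map(path) -> DrugTargetMap:
    """Read a 2-column ``drug<TAB>targets`` TSV (comma-separated targets)."""
    lines = _read_lines(path)
    nonblank = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not nonblank:
        raise ValidationError(f"{path}: empty drug map")
    header = tuple(f.strip().lower() for f in nonblank[0][1].split("\t"))
    if header[: len(DRUG_MAP_HEADER)] != DRUG_MAP_HEADER:
        raise ParseError(
            f"{path}:1: expected header 'drug<TAB>targets', got {nonblank[0][1]!r}"
        )
    entries: Dict[str, FrozenSet[str]] = {}
    for lineno, line in nonblank[1:]:
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated fields, "
                f"got {len(fields)}"
            )
        drug = fields[0].strip()
        if drug in entries:
            raise ValidationError(f"{path}:{lineno}: duplicate drug {drug!r}")
        targets = [t for t in (s.strip() for s in fields[1].split(",")) if t]
        if not targets:
            raise ValidationError(f"{path}:{lineno}: drug {drug!r} has no targets")
        entries[drug] = frozenset(normalize_gene_symbol(t) for t in targets)
    return DrugTargetMap(entries)


def write_drug_target_map(dmap: DrugTargetMap, path) -> None:
    out = ["\t".join(DRUG_MAP_HEADER)]
    for drug, targets in dmap.entries.items():
        out.append(f"{drug}\t{','.join(sorted(targets))}")
    Path(path).write_text("\n".join(out) + "\n")
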
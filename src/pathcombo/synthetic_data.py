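"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the analysis modules expect:
drug-exposed cell cultures profiled every four weeks against drug-free
controls (five biological replicates per cell line), an ARR-annotated
pathway knowledge base, and MTT dose–response plates on the standard
eight-point µM grid in quadruplicate.

Ground truth is planted and recoverable: a configurable set of "planted"
pathways is upregulated in case samples (activators up, repressors down,
by a known log10 effect size), and a designated hub gene is a member of
every planted pathway with ARR +1 — the quantity the end-to-end pipeline
must recover as its top candidate target.  Dose–response combinations are
synthesized under the Bliss-independence null plus a known injected
excess, then renormalized by the partner-alone viability exactly the way
the lab reports them, so the analysis must invert that renormalization to
score them correctly.

All randomness flows from ``GeneratorSpec.seed`` through
``numpy.random.default_rng``; distinct sub-streams per generator keep the
outputs independent of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import ExpressionMatrix
from .pathway_model import ARR_VALUES, Pathway, PathwayDB
from .synergy_lab import (
    STANDARD_GRID,
    ComboExperiment,
    DoseResponse,
    four_pl,
)

DEFAULT_ARR_FREQUENCIES: Dict[float, float] = {
    1.0: 0.40,
    0.5: 0.15,
    0.0: 0.10,
    -0.5: 0.15,
    -1.0: 0.20,
}


@dataclass(frozen=True)
class DoseSpec:
    """4PL parameters of a drug's true dose–response curve."""

    ic50: float  # µM
    hill: float = 1.5
    top: float = 1.0
    bottom: float = 0.0

    def ic(self, level: float) -> float:
        """Exact concentration at ``level`` inhibition of this curve."""
        target = 1.0 - level
        if not self.bottom < target < self.top:
            raise ValidationError(
                f"level {level} not reachable by curve {self}"
            )
        return self.ic50 * (
            (self.top - target) / (target - self.bottom)
        ) ** (1.0 / self.hill)


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic study, with defaults = study conditions."""

    seed: int = 0
    n_genes: int = 400
    n_pathways: int = 60
    pathway_size_range: Tuple[int, int] = (5, 20)
    n_planted: int = 6
    planted_effect: float = 0.5  # mean log10 fold-change per member gene
    hub_gene: str = "HUB1"
    noise_sd: float = 0.2        # log10-scale gaussian sd
    baseline_log10_mean: float = 2.0
    baseline_log10_sd: float = 0.25
    control_replicates: int = 5
    case_timepoints: Tuple[int, ...] = (4, 8, 12, 16)
    cell_line: str = "SKOV-3"
    drug: str = "DRUG-A"
    arr_frequencies: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_ARR_FREQUENCIES)
    )
    effect_timecourse: Optional[Mapping[int, float]] = None  # timepoint -> multiplier
    dose_specs: Mapping[str, DoseSpec] = field(
        default_factory=lambda: {
            "DRUG-A": DoseSpec(ic50=9.6, hill=1.5),
            "DRUG-B": DoseSpec(ic50=17.0, hill=1.2),
        }
    )
    noise_cv: float = 0.05       # multiplicative viability noise
    injected_bliss_excess: float = 0.0  # per-dose additive inhibition excess
    dose_replicates: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValidationError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ValidationError(
                f"pathway_size_range {self.pathway_size_range} exceeds "
                f"n_genes {self.n_genes}"
            )
        if self.noise_sd < 0 or self.noise_cv < 0:
            raise ValidationError("noise levels must be >= 0")
        if not 0 < self.n_planted <= self.n_pathways:
            raise ValidationError("n_planted must be in (0, n_pathways]")
        freqs = dict(self.arr_frequencies)
        if set(freqs) - set(ARR_VALUES) or not np.isclose(
            sum(freqs.values()), 1.0
        ):
            raise ValidationError("arr_frequencies must sum to 1 over ARR values")

    @property
    def planted_pathways(self) -> Tuple[str, ...]:
        return tuple(f"PLANTED_{i + 1:02d}" for i in range(self.n_planted))

    @property
    def gene_universe(self) -> Tuple[str, ...]:
        names = [f"G{i + 1:04d}" for i in range(self.n_genes - 1)]
        return tuple([self.hub_gene] + names)

    def effect_multiplier(self, timepoint: int) -> float:
        if self.effect_timecourse is None:
            return 1.0
        return float(self.effect_timecourse.get(timepoint, 1.0))


def _rng(spec: GeneratorSpec, *labels: str) -> np.random.Generator:
    stream = [spec.seed % 2 ** 31] + [
        zlib.crc32(lab.encode()) % 2 ** 31 for lab in labels
    ]
    return np.random.default_rng(stream)


def generate_pathway_db(spec: GeneratorSpec) -> PathwayDB:
    """Random ARR-annotated gene sets with the hub planted (ARR +1) in
    every planted pathway.  Deterministic per seed."""
    rng = _rng(spec, "pathway_db")
    genes = np.array(spec.gene_universe)
    weights = np.array(sorted(spec.arr_frequencies))
    probs = np.array([spec.arr_frequencies[w] for w in weights])
    lo, hi = spec.pathway_size_range
    planted = set(spec.planted_pathways)
    pathways = []
    for i in range(spec.n_pathways):
        name = (
            spec.planted_pathways[i]
            if i < spec.n_planted
            else f"BG_{i - spec.n_planted + 1:03d}"
        )
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        arr = rng.choice(weights, size=size, p=probs)
        mem = {g: float(w) for g, w in zip(members, arr)}
        if name in planted:
            mem[spec.hub_gene] = 1.0  # hub is an activator of every planted pathway
        pathways.append(Pathway(name, mem))
    return PathwayDB(pathways, source=f"synthetic(seed={spec.seed})")


def _planted_effects(spec: GeneratorSpec, db: PathwayDB) -> Dict[str, float]:
    """Per-gene log10 shift: sum of ARR × effect over planted pathways
    containing the gene (activators up, repressors down)."""
    effects: Dict[str, float] = {}
    planted = set(spec.planted_pathways)
    for pathway in db:
        if pathway.name not in planted:
            continue
        for gene, w in pathway.members.items():
            effects[gene] = effects.get(gene, 0.0) + w * spec.planted_effect
    return effects


def generate_expression(spec: GeneratorSpec, db: PathwayDB) -> ExpressionMatrix:
    """Lognormal-baseline expression with planted case upregulation.

    Controls: one drug-free replicate per control timepoint (default
    five, at 0/4/8/12/16 weeks).  Cases: one sample per case timepoint
    with ARR-signed planted effects (scaled by the per-timepoint
    multiplier) plus gaussian log10 noise.
    """
    rng = _rng(spec, "expression")
    genes = list(spec.gene_universe)
    idx = {g: i for i, g in enumerate(genes)}
    mu = rng.normal(spec.baseline_log10_mean, spec.baseline_log10_sd, len(genes))
    effects = _planted_effects(spec, db)
    effect_vec = np.zeros(len(genes))
    for gene, e in effects.items():
        if gene in idx:
            effect_vec[idx[gene]] = e

    columns: Dict[str, np.ndarray] = {}
    meta_rows = []
    control_timepoints = (0, 4, 8, 12, 16)
    for k in range(spec.control_replicates):
        t = control_timepoints[k % len(control_timepoints)]
        sid = f"{spec.cell_line}_control_w{t}_r{k + 1}"
        columns[sid] = 10 ** (mu + rng.normal(0, spec.noise_sd, len(genes)))
        meta_rows.append((sid, spec.cell_line, "none", t, True))
    for t in spec.case_timepoints:
        sid = f"{spec.cell_line}_{spec.drug}_w{t}"
        shift = effect_vec * spec.effect_multiplier(t)
        columns[sid] = 10 ** (
            mu + shift + rng.normal(0, spec.noise_sd, len(genes))
        )
        meta_rows.append((sid, spec.cell_line, spec.drug, t, False))

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "cell_line", "drug", "timepoint_weeks", "is_control"],
    ).set_index("sample")
    return ExpressionMatrix(values, meta)


def _noisy(rng, clean: np.ndarray, cv: float, n_rep: int) -> np.ndarray:
    reps = np.tile(clean[:, None], (1, n_rep))
    if cv > 0:
        reps = reps * (1.0 + rng.normal(0, cv, reps.shape))
    reps[0, :] = 1.0  # untreated wells are the normalization reference
    return np.clip(reps, 0.0, None)


def generate_dose_response(
    spec: GeneratorSpec, drug: str, partner: Optional[str] = None
):
    """Quadruplicate 4PL viabilities on the standard grid.

    Without a partner, returns a :class:`DoseResponse`.  With one,
    returns a :class:`ComboExperiment`: the combination is synthesized
    under the Bliss null plus ``injected_bliss_excess`` inhibition per
    dose, then divided by the partner-alone viability (the reported,
    renormalized form).
    """
    if drug not in spec.dose_specs:
        raise ValidationError(f"no dose spec for drug {drug!r}")
    rng = _rng(spec, "dose_response", drug, partner or "")
    grid = np.array(STANDARD_GRID)
    ds = spec.dose_specs[drug]
    clean = four_pl(grid, ds.top, ds.bottom, ds.ic50, ds.hill)
    alone = DoseResponse(
        drug,
        spec.cell_line,
        grid,
        _noisy(rng, clean, spec.noise_cv, spec.dose_replicates),
    )
    if partner is None:
        return alone
    if partner not in spec.dose_specs:
        raise ValidationError(f"no dose spec for partner {partner!r}")
    pspec = spec.dose_specs[partner]
    ic20 = pspec.ic(0.20)
    y2 = float(1.0 - four_pl(np.array([ic20]), pspec.top, pspec.bottom,
                             pspec.ic50, pspec.hill)[0])
    y1 = np.clip(1.0 - clean, 0.0, 1.0)
    bliss_inhibition = y1 + y2 - y1 * y2
    observed = np.where(grid > 0, bliss_inhibition + spec.injected_bliss_excess,
                        y2)  # partner alone already acts at dose 0
    v_abs = np.clip(1.0 - observed, 0.0, None)
    v_renorm = v_abs / (1.0 - y2)
    combo_curve = DoseResponse(
        drug,
        spec.cell_line,
        grid,
        _noisy(rng, v_renorm, spec.noise_cv, spec.dose_replicates),
    )
    return ComboExperiment(
        titrated=combo_curve,
        partner_drug=partner,
        partner_inhibition=y2,
        titrated_alone=alone,
    )


def with_seed(spec: GeneratorSpec, seed: int) -> GeneratorSpec:
    """A copy of ``spec`` with a different seed (kept below 2**31)."""
    return replace(spec, seed=seed % 2 ** 31)
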
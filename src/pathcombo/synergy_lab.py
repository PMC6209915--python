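"""Dose–response and Bliss-independence synergy analytics.

Companion analytics for the MTT viability experiments that validate
predicted combinations: viability from optical densities, IC20/IC50 from
four-parameter logistic (4PL) dose–response fits, Bliss scoring of the
fixed-IC20 combination design, and the predicted-vs-random group
comparison.

The combination design titrates one drug over the standard concentration
grid while the partner is held at its IC20.  The lab reports the
combination curve renormalized by the partner-alone viability; Bliss
requires absolute effects, so scoring first un-normalizes the combination
(multiplies by 1 − partner inhibition), converts viabilities to
inhibitions clamped to [0, 1] ("without baseline correction" — no further
rescaling), and compares with the independence null

    Y_bliss = Y1 + Y2 − Y1·Y2 .

The score is 100 × the mean per-dose excess over the null across nonzero
doses; a combination is synergistic if the score exceeds +5, antagonistic
below −5, and additive otherwise (the boundaries themselves are additive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import ComputationError, ValidationError

log = logging.getLogger(__name__)

#: standard concentration grid, µM
STANDARD_GRID: Tuple[float, ...] = (0.0, 0.8, 1.56, 3.1, 6.25, 12.5, 25.0, 50.0)

SYNERGISTIC = "synergistic"
ADDITIVE = "additive"
ANTAGONISTIC = "antagonistic"


@dataclass
class DoseResponse:
    """Viability fractions over a concentration grid, with replicates.

    ``viability`` has shape (n_concentrations, n_replicates); the grid
    must start at 0 (the untreated reference, viability 1 by
    construction) and increase strictly.
    """

    drug: str
    cell_line: str
    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        viab = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if viab.shape[0] != conc.shape[0] and viab.shape[1] == conc.shape[0]:
            viab = viab.T
        if conc.ndim != 1 or conc[0] != 0 or (np.diff(conc) <= 0).any():
            raise ValidationError(
                "concentrations must start at 0 and increase strictly"
            )
        if viab.shape[0] != conc.shape[0]:
            raise ValidationError("viability/concentration shape mismatch")
        if not np.isfinite(viab).all() or (viab < 0).any():
            raise ValidationError("viabilities must be finite and >= 0")
        self.concentrations = conc
        self.viability = viab

    @property
    def mean_viability(self) -> np.ndarray:
        return self.viability.mean(axis=1)

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[1]


@dataclass
class ComboExperiment:
    """Fixed-IC20 combination: titrated drug ± partner at constant dose.

    ``titrated`` holds the combination curve as the lab reports it —
    renormalized by the viability under the partner alone; ``titrated_alone``
    is the single-agent curve; ``partner_inhibition`` is the absolute
    effect fraction of the fixed partner dose by itself.
    """

    titrated: DoseResponse
    partner_drug: str
    partner_inhibition: float
    titrated_alone: DoseResponse

    def __post_init__(self) -> None:
        if not 0 <= self.partner_inhibition < 1:
            raise ValidationError(
                f"partner inhibition must be in [0, 1), "
                f"got {self.partner_inhibition}"
            )
        if self.titrated.cell_line != self.titrated_alone.cell_line:
            raise ValidationError("combo and single-agent cell lines differ")
        if not np.array_equal(
            self.titrated.concentrations, self.titrated_alone.concentrations
        ):
            raise ValidationError(
                "combo and single-agent concentration grids differ"
            )


@dataclass(frozen=True)
class SynergyResult:
    bliss_score: float  # percentage-point scale
    klass: str
    per_dose_excess: Tuple[float, ...]
    doses: Tuple[float, ...]


@dataclass(frozen=True)
class IcEstimate:
    """An inhibitory concentration, possibly right-censored at the grid."""

    concentration: float  # µM
    level: float          # e.g. 0.5 for IC50
    method: str           # "4pl" | "interpolation" | "censored"
    censored: bool = False
    extrapolated: bool = False
    params: Optional[Tuple[float, float, float, float]] = None  # top,bottom,ic50,hill

    def __str__(self) -> str:
        if self.censored:
            return f">={self.concentration:g}"
        return f"{self.concentration:g}"


def classify_bliss(score: float) -> str:
    """±5 rule: strictly above +5 synergistic, strictly below −5
    antagonistic, additive otherwise (boundaries are additive)."""
    if score > 5:
        return SYNERGISTIC
    if score < -5:
        return ANTAGONISTIC
    return ADDITIVE


def viability_from_od(
    od_treated: Sequence[float],
    od_control: Sequence[float],
    od_blank: Sequence[float],
) -> np.ndarray:
    """Per-replicate viability fractions from MTT optical densities:
    (OD_treated − mean OD_blank) / (mean OD_control − mean OD_blank)."""
    treated = np.asarray(od_treated, dtype=float)
    blank = float(np.mean(od_blank))
    control = float(np.mean(od_control))
    if control <= blank:
        raise ValidationError(
            f"assay failure: mean control OD {control:g} <= "
            f"mean blank OD {blank:g}"
        )
    return (treated - blank) / (control - blank)


def four_pl(conc, top, bottom, ic50, hill):
    """Four-parameter logistic viability curve on concentration."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, conc / ic50, 0.0)
    return bottom + (top - bottom) / (1.0 + np.power(ratio, hill))


def _fit_four_pl(conc, viab_mean):
    p0 = [
        float(np.max(viab_mean)),
        float(max(np.min(viab_mean), 0.0)),
        float(np.median(conc[conc > 0])),
        1.0,
    ]
    lower = [0.2, 0.0, 1e-6, 0.1]
    upper = [1.5, min(1.0, p0[0]), 1e6, 10.0]
    p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, lower, upper)]
    popt, _ = optimize.curve_fit(
        four_pl, conc, viab_mean, p0=p0, bounds=(lower, upper),
        maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return tuple(float(x) for x in popt)


def _interpolate_ic(conc, viab_mean, target):
    """Monotone log-linear interpolation at the first downward crossing."""
    nz = conc > 0
    c, v = conc[nz], viab_mean[nz]
    for i in range(len(c) - 1):
        v1, v2 = v[i], v[i + 1]
        if v1 >= target >= v2 and v1 != v2:
            frac = (v1 - target) / (v1 - v2)
            logc = np.log10(c[i]) + frac * (np.log10(c[i + 1]) - np.log10(c[i]))
            return float(10 ** logc), False
    if v[0] < target:  # crossing happens below the first nonzero dose
        return float(c[0]), True
    raise ComputationError("no downward crossing of the target viability")


def fit_ic(
    dr: DoseResponse, level: float = 0.5, method: str = "auto"
) -> IcEstimate:
    """Estimate the concentration giving ``level`` inhibition (IC-level).

    Fits a 4PL on the replicate-mean curve and inverts it at viability
    1 − level; falls back to monotone log-linear interpolation when the
    fit fails or cannot reach the target.  If the measured curve never
    drops below 1 − level the estimate is right-censored at the maximum
    grid concentration (reported as "≥ max"), mirroring the convention
    used for inactive drugs.
    """
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if method not in {"auto", "4pl", "interp"}:
        raise ValidationError(f"unknown method {method!r}")
    target = 1.0 - level
    conc = dr.concentrations
    mean_v = dr.mean_viability
    if mean_v[conc > 0].min() > target:
        return IcEstimate(
            float(conc.max()), level, "censored", censored=True
        )
    if method in {"auto", "4pl"}:
        try:
            top, bottom, ic50, hill = _fit_four_pl(conc, mean_v)
            if bottom < target < top:
                c = ic50 * ((top - target) / (target - bottom)) ** (1.0 / hill)
                if np.isfinite(c) and c > 0:
                    return IcEstimate(
                        float(c),
                        level,
                        "4pl",
                        extrapolated=bool(c > conc.max() or c < conc[1]),
                        params=(top, bottom, ic50, hill),
                    )
        except (RuntimeError, ValueError) as exc:
            if method == "4pl":
                raise ComputationError(f"4PL fit failed: {exc}") from exc
            log.warning("4PL fit failed (%s); falling back to interpolation", exc)
    c, extrapolated = _interpolate_ic(conc, mean_v, target)
    return IcEstimate(c, level, "interpolation", extrapolated=extrapolated)


def bliss_score(combo: ComboExperiment) -> SynergyResult:
    """Bliss-independence score for a fixed-IC20 combination experiment.

    Per nonzero dose d: Y1 is the mean single-agent inhibition, Y2 the
    partner's fixed-dose inhibition; the observed combination inhibition
    is recovered from the renormalized curve by multiplying viability by
    (1 − Y2).  The score is 100 × mean(observed − (Y1 + Y2 − Y1·Y2)).
    """
    y2 = combo.partner_inhibition
    conc = combo.titrated.concentrations
    nz = conc > 0
    if not nz.any():
        raise ValidationError("combination needs at least one nonzero dose")
    v_alone = combo.titrated_alone.mean_viability[nz]
    v_renorm = combo.titrated.mean_viability[nz]
    y1 = np.clip(1.0 - v_alone, 0.0, 1.0)
    observed = np.clip(1.0 - v_renorm * (1.0 - y2), 0.0, 1.0)
    expected = y1 + y2 - y1 * y2
    excess = observed - expected
    score = float(100.0 * excess.mean())
    return SynergyResult(
        score,
        classify_bliss(score),
        tuple(float(e) for e in excess),
        tuple(float(c) for c in conc[nz]),
    )


# ---------------------------------------------------------------------------
# Plate-table I/O
#
# One TSV row per well:
#   cell_line  drug  partner_drug  concentration_uM  replicate  od  role
# with role in {treated, control, blank, partner_alone}; partner_drug is "-"
# for single-agent titrations.  Blank wells contain no cells; control wells
# are untreated; partner_alone wells carry only the partner at its fixed
# dose (they supply both the combination's renormalization reference and
# the partner inhibition Y2).

DOSE_TABLE_HEADER = (
    "cell_line",
    "drug",
    "partner_drug",
    "concentration_uM",
    "replicate",
    "od",
    "role",
)


def _pivot_viability(rows, od_control, od_blank):
    """(concentrations, viability matrix) from treated-well rows."""
    by_conc = {}
    for conc, od in rows:
        by_conc.setdefault(float(conc), []).append(float(od))
    concs = sorted(by_conc)
    n_rep = {len(v) for v in by_conc.values()}
    if len(n_rep) != 1:
        raise ValidationError("ragged replicate counts across concentrations")
    viab = np.vstack(
        [viability_from_od(by_conc[c], od_control, od_blank) for c in concs]
    )
    if concs and concs[0] != 0.0:
        concs = [0.0] + concs
        v0 = viability_from_od(od_control, od_control, od_blank)
        n = viab.shape[1]
        row0 = np.resize(np.asarray(v0, dtype=float), n)
        viab = np.vstack([row0, viab])
    return np.asarray(concs), viab


def read_dose_table(path):
    """Parse a plate TSV into single-agent curves and combinations.

    Returns ``(singles, combos)``: ``singles`` maps (cell_line, drug) →
    :class:`DoseResponse`; ``combos`` maps (cell_line, drug, partner) →
    :class:`ComboExperiment`.  A combination requires the matching
    single-agent titration in the same file.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(DOSE_TABLE_HEADER) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    groups = {}
    for key, grp in df.groupby(["cell_line", "drug", "partner_drug"], sort=False):
        groups[tuple(map(str, key))] = grp

    def _ods(grp, role):
        return grp.loc[grp["role"] == role, "od"].astype(float).tolist()

    # blanks may be shared per cell line
    blank_by_cell = {
        str(cell): sub.loc[sub["role"] == "blank", "od"].astype(float).tolist()
        for cell, sub in df.groupby("cell_line", sort=False)
    }

    singles, combos = {}, {}
    for (cell, drug, partner), grp in groups.items():
        od_blank = _ods(grp, "blank") or blank_by_cell.get(cell, [])
        od_control = _ods(grp, "control")
        if not od_blank or not od_control:
            raise ValidationError(
                f"{path}: group ({cell}, {drug}, {partner}) lacks "
                "blank or control wells"
            )
        treated = grp[grp["role"] == "treated"]
        rows = list(
            zip(treated["concentration_uM"].astype(float), treated["od"])
        )
        concs, viab = _pivot_viability(rows, od_control, od_blank)
        if partner == "-":
            singles[(cell, drug)] = DoseResponse(drug, cell, concs, viab)
        else:
            v_partner = np.mean(
                viability_from_od(_ods(grp, "partner_alone"), od_control, od_blank)
            )
            if not 0 < v_partner <= 1.2:
                raise ValidationError(
                    f"{path}: implausible partner-alone viability {v_partner:g}"
                )
            y2 = float(np.clip(1.0 - v_partner, 0.0, 0.999))
            renorm = viab / v_partner
            renorm[0, :] = 1.0
            combos[(cell, drug, partner)] = (
                DoseResponse(drug, cell, concs, renorm),
                partner,
                y2,
            )
    out_combos = {}
    for (cell, drug, partner), (curve, pname, y2) in combos.items():
        try:
            alone = singles[(cell, drug)]
        except KeyError:
            raise ValidationError(
                f"{path}: combination ({cell}, {drug}+{partner}) has no "
                "matching single-agent titration"
            ) from None
        out_combos[(cell, drug, partner)] = ComboExperiment(
            titrated=curve,
            partner_drug=pname,
            partner_inhibition=y2,
            titrated_alone=alone,
        )
    return singles, out_combos


def write_dose_table(path, singles, combos=(), od_blank=0.1, od_control=1.1):
    """Write curves/combos as a plate TSV, synthesizing ODs.

    Viability fractions are mapped back to optical densities via
    ``od = blank + v × (control − blank)``; combinations are written on
    the absolute scale (renormalization undone) together with their
    partner_alone wells, so :func:`read_dose_table` must reconstruct the
    renormalized form.
    """
    from pathlib import Path

    span = od_control - od_blank
    lines = ["\t".join(DOSE_TABLE_HEADER)]

    def _emit(cell, drug, partner, conc, rep, od, role):
        lines.append(
            f"{cell}\t{drug}\t{partner}\t{conc:g}\t{rep}\t{od:.10g}\t{role}"
        )

    def _plate(dr, cell, drug, partner, scale=1.0):
        for rep in range(dr.n_replicates):
            _emit(cell, drug, partner, 0.0, rep + 1, od_control, "control")
            _emit(cell, drug, partner, 0.0, rep + 1, od_blank, "blank")
        for i, conc in enumerate(dr.concentrations):
            if conc == 0:
                continue
            for rep in range(dr.n_replicates):
                v = dr.viability[i, rep] * scale
                _emit(
                    cell, drug, partner, conc, rep + 1,
                    od_blank + v * span, "treated",
                )

    for (cell, drug), dr in dict(singles).items():
        _plate(dr, cell, drug, "-")
    for (cell, drug, partner), combo in dict(combos).items():
        scale = 1.0 - combo.partner_inhibition
        _plate(combo.titrated, cell, drug, partner, scale=scale)
        for rep in range(combo.titrated.n_replicates):
            _emit(
                cell, drug, partner, 0.0, rep + 1,
                od_blank + scale * span, "partner_alone",
            )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class WelchReport:
    statistic: float
    df: float
    pvalue: float
    mean_predicted: float
    mean_random: float


def compare_predicted_vs_random(
    predicted_scores: Sequence[float], random_scores: Sequence[float]
) -> WelchReport:
    """Two-sided Welch t-test of predicted vs random Bliss scores."""
    a = np.asarray(predicted_scores, dtype=float)
    b = np.asarray(random_scores, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 scores")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchReport(
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        float(a.mean()),
        float(b.mean()),
    )
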
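"""Dose-response arm: control normalization, robust 4PL fitting, AUC and IC50.

Viabilities are normalized so the DMSO control median is 100% and the
bortezomib control median is 0%.  Curves follow the four-parameter logistic

    v(c) = bottom + (top - bottom) / (1 + (c / ac50) ** hill)

with ``hill > 0`` giving a decreasing (viability) curve; increasing
(activation) data is represented after canonicalization by ``top >= bottom``
and a negative ``hill``.  Fitting is a coarse grid over (log10 ac50, hill)
with top/bottom solved by bounded least squares at each node, an L1 node
loss, local refinement, and one round of 3xMAD residual masking.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import WellMeasurement

log = logging.getLogger(__name__)

PARAM_BOX = (-20.0, 120.0)  # bounds for top and bottom (%)
HILL_BOUNDS = (0.3, 5.0)


# ---------------------------------------------------------------------------
# model and design
# ---------------------------------------------------------------------------

def four_pl(conc, top: float, bottom: float, ac50: float, hill: float):
    """Four-parameter logistic response at concentration(s) ``conc``."""
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ac50) ** hill)


def dilution_series(top_conc: float, ratio: float = 3.0, n_points: int = 11) -> np.ndarray:
    """Descending 1:``ratio`` dilution series starting at ``top_conc``."""
    if top_conc <= 0 or ratio <= 1 or n_points < 1:
        raise ValueError("need top_conc > 0, ratio > 1, n_points >= 1")
    return top_conc / ratio ** np.arange(n_points, dtype=float)


def normalize_dose_viability(
    wells: Iterable[WellMeasurement],
) -> dict[tuple[str, tuple[int, int]], float]:
    """Percent viability per library well, anchored to plate control medians.

    ``v = 100 * (x - median(bortezomib)) / (median(dmso) - median(bortezomib))``.
    Each plate needs >= 2 DMSO and >= 2 bortezomib wells; inverted controls
    are a hard error.
    """
    by_plate: dict[str, list[WellMeasurement]] = defaultdict(list)
    for w in wells:
        by_plate[w.plate_id].append(w)
    out: dict[tuple[str, tuple[int, int]], float] = {}
    for plate_id, plate_wells in by_plate.items():
        dmso = [w.signal for w in plate_wells if w.role == "dmso"]
        bz = [w.signal for w in plate_wells if w.role == "bortezomib"]
        if len(dmso) < 2 or len(bz) < 2:
            raise ValueError(
                f"plate {plate_id!r}: need >= 2 DMSO and >= 2 bortezomib wells "
                f"(got {len(dmso)}, {len(bz)})"
            )
        md, mb = float(np.median(dmso)), float(np.median(bz))
        if md <= mb:
            raise ValueError(
                f"plate {plate_id!r}: inverted controls (median(dmso)={md} <= "
                f"median(bortezomib)={mb})"
            )
        for w in plate_wells:
            if w.role == "library":
                out[(plate_id, w.well)] = 100.0 * (w.signal - mb) / (md - mb)
    return out


# ---------------------------------------------------------------------------
# robust grid 4PL fit
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    top: float
    bottom: float
    ac50: float
    hill: float
    loss: float
    converged: bool


def _solve_top_bottom(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares top/bottom for fixed logistic profile ``g``, box-constrained."""
    lo, hi = PARAM_BOX
    u, w = g, 1.0 - g
    suu, sww, suw = float(u @ u), float(w @ w), float(u @ w)
    suy, swy = float(u @ y), float(w @ y)
    det = suu * sww - suw * suw
    if det > 1e-12 * max(suu * sww, 1e-30):
        t = (suy * sww - swy * suw) / det
        b = (swy * suu - suy * suw) / det
    else:  # nearly constant profile: fall back to a flat line
        t = b = float(np.mean(y))
    # project into the box with one coordinate-descent pass
    t = min(max(t, lo), hi)
    if sww > 0:
        b = min(max((swy - t * suw) / sww, lo), hi)
    if suu > 0:
        t = min(max((suy - b * suw) / suu, lo), hi)
    return t, b


def _l1_loss(lac: float, hill: float, logc: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    g = 1.0 / (1.0 + 10.0 ** ((logc - lac) * hill))
    t, b = _solve_top_bottom(g, y)
    resid = y - (b + (t - b) * g)
    return float(np.sum(np.abs(resid))), t, b


def _grid_refine(
    logc: np.ndarray,
    y: np.ndarray,
    lac_range: tuple[float, float],
    grid_step: float,
    n_hill: int,
) -> tuple[float, float, float, float, float]:
    """Coarse grid over (log10 ac50, hill) followed by Nelder-Mead refinement."""
    lacs = np.arange(lac_range[0], lac_range[1] + grid_step / 2, grid_step)
    hills = np.geomspace(HILL_BOUNDS[0], HILL_BOUNDS[1], n_hill)
    best = (math.inf, lacs[0], hills[0])
    for lac in lacs:
        for h in hills:
            loss, _, _ = _l1_loss(lac, h, logc, y)
            if loss < best[0]:
                best = (loss, lac, h)

    log_h_lo, log_h_hi = math.log(HILL_BOUNDS[0]), math.log(HILL_BOUNDS[1])

    def objective(params):
        lac = min(max(params[0], lac_range[0]), lac_range[1])
        h = math.exp(min(max(params[1], log_h_lo), log_h_hi))
        return _l1_loss(lac, h, logc, y)[0]

    res = optimize.minimize(
        objective,
        x0=[best[1], math.log(best[2])],
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 600},
    )
    lac = min(max(float(res.x[0]), lac_range[0]), lac_range[1])
    hill = math.exp(min(max(float(res.x[1]), log_h_lo), log_h_hi))
    loss, t, b = _l1_loss(lac, hill, logc, y)
    return loss, lac, hill, t, b


def fit_4pl_grid(
    concentrations: Sequence[float],
    viability_pct: Sequence[float],
    ac50_pad_decades: float = 1.0,
    grid_step: float = 0.25,
    n_hill: int = 12,
    mad_multiplier: float = 3.0,
) -> tuple[FourPLFit, np.ndarray]:
    """Robust grid-based 4PL fit; returns the fit and the outlier mask.

    Needs >= 5 points with >= 4 distinct concentrations.  ``converged`` is
    False when the refined fit does not beat the best flat-line (constant)
    model, in which case no IC50 should be derived.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(viability_pct, dtype=float)
    if c.size != y.size:
        raise ValueError("concentrations and viabilities differ in length")
    if c.size < 5 or np.unique(c).size < 4:
        raise ValueError(
            f"need >= 5 points with >= 4 distinct concentrations "
            f"(got {c.size} points, {np.unique(c).size} distinct)"
        )
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    logc = np.log10(c)
    lac_range = (float(logc.min()) - ac50_pad_decades, float(logc.max()) + ac50_pad_decades)

    loss, lac, hill, t, b = _grid_refine(logc, y, lac_range, grid_step, n_hill)

    # one round of outlier masking at 3 x MAD of the residuals
    resid = y - four_pl(c, t, b, 10.0**lac, hill)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    mask = np.zeros(c.size, dtype=bool)
    if mad > 1e-9:
        mask = np.abs(resid) > mad_multiplier * mad
        if mask.any() and (~mask).sum() >= 5 and np.unique(c[~mask]).size >= 4:
            loss, lac, hill, t, b = _grid_refine(logc[~mask], y[~mask], lac_range, grid_step, n_hill)
        else:
            mask[:] = False

    kept = y[~mask]
    flat_loss = float(np.sum(np.abs(kept - np.median(kept))))
    converged = loss < flat_loss - 1e-9

    top, bottom = t, b
    if top < bottom:  # canonical orientation: top >= bottom, hill sign flips
        top, bottom, hill = bottom, top, -hill
    return (
        FourPLFit(top=top, bottom=bottom, ac50=10.0**lac, hill=hill, loss=loss, converged=converged),
        mask,
    )


def fit_4pl_least_squares(
    concentrations: Sequence[float], viability_pct: Sequence[float]
) -> FourPLFit:
    """Plain (non-robust) least-squares 4PL fit, used as a comparison reference."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(viability_pct, dtype=float)
    logc = np.log10(c)

    def resid(params):
        t, b, lac, h = params
        return four_pl(c, t, b, 10.0**lac, h) - y

    x0 = [
        float(np.clip(y.max(), *PARAM_BOX)),
        float(np.clip(y.min(), *PARAM_BOX)),
        float(np.median(logc)),
        1.0,
    ]
    res = optimize.least_squares(
        x0=x0,
        fun=resid,
        bounds=(
            [PARAM_BOX[0], PARAM_BOX[0], logc.min() - 1, HILL_BOUNDS[0]],
            [PARAM_BOX[1], PARAM_BOX[1], logc.max() + 1, HILL_BOUNDS[1]],
        ),
    )
    t, b, lac, h = res.x
    if t < b:
        t, b, h = b, t, -h
    return FourPLFit(
        top=float(t),
        bottom=float(b),
        ac50=float(10.0**lac),
        hill=float(h),
        loss=float(np.sum(np.abs(res.fun))),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# curve summaries
# ---------------------------------------------------------------------------

def normalized_auc(
    fit: FourPLFit | None,
    concentrations: Sequence[float],
    mode: str = "fit",
    viability_pct: Sequence[float] | None = None,
    n_grid: int = 256,
) -> float:
    """Area under the viability curve over log10 concentration, in percent.

    Normalized so a flat 100%-viability response scores 100 and a fully
    lethal response scores 0 (values above 100 indicate growth stimulation).
    ``fit`` mode integrates the fitted curve; ``points`` mode (also the
    fallback when no converged fit exists) integrates the raw responses.
    """
    c = np.asarray(concentrations, dtype=float)
    lo, hi = float(np.log10(c.min())), float(np.log10(c.max()))
    if hi <= lo:
        raise ValueError("need a nonzero concentration range")
    if mode == "fit" and (fit is None or not fit.converged):
        log.warning("no converged fit; normalized AUC falls back to raw points")
        mode = "points"
    if mode == "fit":
        lg = np.linspace(lo, hi, n_grid)
        vals = four_pl(10.0**lg, fit.top, fit.bottom, fit.ac50, fit.hill)
    elif mode == "points":
        if viability_pct is None:
            raise ValueError("points mode requires the raw viabilities")
        order = np.argsort(c)
        lg = np.log10(c[order])
        vals = np.asarray(viability_pct, dtype=float)[order]
    else:
        raise ValueError(f"unknown AUC mode {mode!r}")
    auc = float(np.trapezoid(vals, lg)) / (hi - lo)
    return max(auc, 0.0)


def ic50_absolute(fit: FourPLFit) -> float | None:
    """Concentration where the fitted curve crosses 50%; None if it never does."""
    if fit is None or not fit.converged:
        return None
    if not (fit.bottom < 50.0 < fit.top) or fit.hill == 0:
        return None
    ratio = (fit.top - 50.0) / (50.0 - fit.bottom)
    c = fit.ac50 * ratio ** (1.0 / fit.hill)
    return float(c) if math.isfinite(c) and c > 0 else None


def ec50_relative(fit: FourPLFit) -> float | None:
    """Half-max inflection concentration (the fitted ac50)."""
    if fit is None or not fit.converged:
        return None
    return float(fit.ac50)


@dataclass
class DoseResponseCurve:
    """One compound x cell-line dose-response record."""

    compound: str
    cell_line: str
    concentrations: tuple
    viability_pct: tuple
    fit: FourPLFit | None = None
    n_auc: float | None = None
    ic50_abs: float | None = None
    ec50_rel: float | None = None
    outlier_mask: tuple = ()


def curves_from_wells(
    wells: Iterable[WellMeasurement],
    cell_line: str = "",
    top_conc: float = 38.3e-6,
    ratio: float = 3.0,
    auc_mode: str = "fit",
) -> list[DoseResponseCurve]:
    """Normalize dose plates and fit one curve per compound.

    Within a compound, library wells are ordered by (plate, row, column) and
    assigned the descending dilution series from ``top_conc``.
    """
    wells = list(wells)
    viability = normalize_dose_viability(wells)
    by_compound: dict[str, list[WellMeasurement]] = defaultdict(list)
    for w in wells:
        if w.role == "library":
            by_compound[w.sirna_or_compound_id].append(w)

    curves = []
    for compound in sorted(by_compound):
        cw = sorted(by_compound[compound], key=lambda w: (w.plate_id, w.well))
        conc = dilution_series(top_conc, ratio=ratio, n_points=len(cw))
        vi = np.array([viability[(w.plate_id, w.well)] for w in cw])
        fit, mask = fit_4pl_grid(conc, vi)
        curves.append(
            DoseResponseCurve(
                compound=compound,
                cell_line=cell_line,
                concentrations=tuple(float(x) for x in conc),
                viability_pct=tuple(float(x) for x in vi),
                fit=fit,
                n_auc=normalized_auc(fit, conc, mode=auc_mode, viability_pct=vi),
                ic50_abs=ic50_absolute(fit),
                ec50_rel=ec50_relative(fit),
                outlier_mask=tuple(bool(m) for m in mask),
            )
        )
    return curves


def class_summary(
    curves: Sequence[DoseResponseCurve], class_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-class mean normalized AUC and median of the defined absolute IC50s."""
    missing = {c.cell_line for c in curves} - set(class_map)
    if missing:
        raise ValueError(f"cell lines without class assignment: {sorted(missing)}")
    rows = []
    for cls in sorted(set(class_map.values())):
        members = [c for c in curves if class_map[c.cell_line] == cls]
        if not members:
            raise ValueError(f"class {cls!r} has no curves")
        aucs = [c.n_auc for c in members if c.n_auc is not None]
        ic50s = [c.ic50_abs for c in members if c.ic50_abs is not None]
        rows.append(
            {
                "class": cls,
                "n_curves": len(members),
                "mean_n_auc": float(np.mean(aucs)),
                "median_ic50": float(np.median(ic50s)) if ic50s else math.nan,
                "n_ic50_defined": len(ic50s),
                "n_ic50_undefined": len(members) - len(ic50s),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def tumor_volume(long_axis: float, short_axis: float) -> float:
    """Caliper tumor volume in mm^3: ``long * short**2 / 2``.

    Axes given in the wrong order are swapped with a warning; negative
    inputs are a hard error.
    """
    if long_axis < 0 or short_axis < 0:
        raise ValueError("axes must be nonnegative")
    if short_axis > long_axis:
        log.warning("short axis %s > long axis %s; swapping", short_axis, long_axis)
        long_axis, short_axis = short_axis, long_axis
    return long_axis * short_axis**2 / 2.0
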
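"""Plate-effect correction and robust scoring of screen signals.

Discovery-screen signals are first divided by the per-plate median of the
reference wells (non-transfected by default), then robust Z-scored across
the whole screen of one cell line.  Verification plates are normalized
against their positive (lethal) and negative (non-silencing) controls.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import WellMeasurement

log = logging.getLogger(__name__)

#: Scale factor making the MAD a consistent estimator of the normal SD.
MAD_SCALE = 1.4826


@dataclass
class ActivityScore:
    """Per-siRNA activity: raw signal, plate-normalized ratio, robust Z."""

    sirna_id: str
    cell_line: str = ""
    raw_signal: float = math.nan
    plate_normalized: float = math.nan
    robust_z: float = math.nan


def plate_normalize(
    wells: Iterable[WellMeasurement],
    reference_role: str = "non_transfected",
    cell_line: str = "",
) -> list[ActivityScore]:
    """Divide each library well by the median reference signal of its plate.

    Every plate must carry at least two wells of ``reference_role``; a plate
    without them raises a :class:`ValueError` naming the plate.
    """
    wells = list(wells)
    by_plate: dict[str, list[WellMeasurement]] = defaultdict(list)
    for w in wells:
        by_plate[w.plate_id].append(w)

    ref_median: dict[str, float] = {}
    for plate_id, plate_wells in by_plate.items():
        refs = [w.signal for w in plate_wells if w.role == reference_role]
        if len(refs) < 2:
            raise ValueError(
                f"plate {plate_id!r} has {len(refs)} wells of reference role "
                f"{reference_role!r}; need at least 2"
            )
        med = float(np.median(refs))
        if med <= 0:
            raise ValueError(f"plate {plate_id!r}: non-positive reference median {med}")
        ref_median[plate_id] = med

    scores = []
    for w in wells:
        if w.role != "library":
            continue
        scores.append(
            ActivityScore(
                sirna_id=w.sirna_or_compound_id,
                cell_line=cell_line,
                raw_signal=w.signal,
                plate_normalized=w.signal / ref_median[w.plate_id],
            )
        )
    return scores


def robust_z(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Robust Z-scores: ``(x - median) / (MAD_SCALE * MAD)``.

    Requires at least 3 finite values and a strictly positive MAD (a zero
    MAD indicates a degenerate screen and is a hard error).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"robust_z needs >= 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("robust_z: non-finite values in input")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("robust_z: MAD is zero (degenerate screen)")
    return (x - med) / (MAD_SCALE * mad)


def robust_z_scores(
    scores: Sequence[ActivityScore], log_transform: bool = True
) -> list[ActivityScore]:
    """Fill ``robust_z`` from ``plate_normalized`` across a whole screen.

    Plate effects are multiplicative, so the default scores the natural log
    of the normalized ratio (ranks are unaffected; tails become symmetric).
    """
    vals = np.array([s.plate_normalized for s in scores], dtype=float)
    if log_transform:
        if np.any(vals <= 0):
            raise ValueError("log transform requires strictly positive normalized values")
        vals = np.log(vals)
    z = robust_z(vals)
    for s, zi in zip(scores, z):
        s.robust_z = float(zi)
    return list(scores)


def normalize_verification(
    wells: Iterable[WellMeasurement], formula: str = "literal"
) -> dict[str, float]:
    """Relative viability per siRNA on verification plates.

    ``literal`` (default): ``v = (x - median(pos)) / median(neg)``;
    ``span``: ``v = (x - median(pos)) / (median(neg) - median(pos))``.
    Medians are per plate; replicate wells of one siRNA are averaged.
    Inverted controls (``median(neg) <= median(pos)``) are a hard error.
    """
    if formula not in ("literal", "span"):
        raise ValueError(f"unknown verification formula {formula!r}")
    by_plate: dict[str, list[WellMeasurement]] = defaultdict(list)
    for w in wells:
        by_plate[w.plate_id].append(w)

    acc: dict[str, list[float]] = defaultdict(list)
    for plate_id, plate_wells in by_plate.items():
        pos = [w.signal for w in plate_wells if w.role == "positive_control"]
        neg = [w.signal for w in plate_wells if w.role == "negative_control"]
        if not pos or not neg:
            raise ValueError(
                f"plate {plate_id!r} lacks positive and/or negative control wells"
            )
        mpos, mneg = float(np.median(pos)), float(np.median(neg))
        if mneg <= mpos:
            raise ValueError(
                f"plate {plate_id!r}: inverted controls "
                f"(median(neg)={mneg} <= median(pos)={mpos})"
            )
        denom = mneg if formula == "literal" else mneg - mpos
        for w in plate_wells:
            if w.role != "library":
                continue
            acc[w.sirna_or_compound_id].append((w.signal - mpos) / denom)

    return {sid: float(np.mean(vs)) for sid, vs in acc.items()}
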
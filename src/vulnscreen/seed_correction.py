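"""Seed-group median correction of siRNA activities (modified common seed analysis).

siRNAs are grouped by the exact seed string (guide positions 2-7 by
default); each member's activity is corrected by subtracting the median
activity of its group.  Groups below ``min_group_size`` fall back to
subtracting the library-wide median so unique-seed siRNAs are not zeroed
by self-subtraction.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import SirnaRecord
from .normalization import ActivityScore

DEFAULT_SEED_START = 2
DEFAULT_SEED_LENGTH = 6


@dataclass
class SeedGroup:
    """All siRNAs sharing one seed hexamer (or heptamer)."""

    seed: str
    members: list[str] = field(default_factory=list)
    median_activity: float = math.nan


@dataclass
class CorrectedActivity:
    """Seed-corrected activity of one siRNA."""

    sirna_id: str
    corrected: float
    group_size: int


def extract_seed(
    guide: str, start: int = DEFAULT_SEED_START, length: int = DEFAULT_SEED_LENGTH
) -> str:
    """1-based substring of the guide, positions ``start..start+length-1``."""
    if start < 1 or length < 1:
        raise ValueError("seed start and length must be >= 1")
    if len(guide) < start + length - 1:
        raise ValueError(
            f"guide of length {len(guide)} too short for seed positions "
            f"{start}..{start + length - 1}"
        )
    return guide[start - 1 : start - 1 + length]


def group_by_seed(
    library: Iterable[SirnaRecord],
    start: int = DEFAULT_SEED_START,
    length: int = DEFAULT_SEED_LENGTH,
) -> list[SeedGroup]:
    """Partition the library into exact-string seed groups.

    Records whose ``seed`` field is unset get it filled here.
    """
    groups: dict[str, SeedGroup] = {}
    for rec in library:
        if rec.seed is None or len(rec.seed) != length:
            rec.seed = extract_seed(rec.guide_sequence, start, length)
        g = groups.get(rec.seed)
        if g is None:
            g = groups[rec.seed] = SeedGroup(seed=rec.seed)
        g.members.append(rec.sirna_id)
    return list(groups.values())


def _as_mapping(scores) -> dict[str, float]:
    if isinstance(scores, Mapping):
        return dict(scores)
    out = {}
    for s in scores:
        if isinstance(s, ActivityScore):
            out[s.sirna_id] = s.robust_z
        else:  # (sirna_id, value) pairs
            out[s[0]] = float(s[1])
    return out


def median_seed_correct(
    scores,
    groups: Sequence[SeedGroup],
    min_group_size: int = 3,
    leave_one_out: bool = False,
) -> list[CorrectedActivity]:
    """Subtract the seed-group median activity from each member.

    ``scores`` may be a mapping ``sirna_id -> activity`` or a collection of
    :class:`~vulnscreen.normalization.ActivityScore`.  Groups smaller than
    ``min_group_size`` are corrected by the library-wide median instead.
    With ``leave_one_out`` the member itself is excluded from its group
    median (only for groups of size > ``min_group_size``).
    """
    values = _as_mapping(scores)
    global_median = float(np.median(list(values.values())))

    corrected: list[CorrectedActivity] = []
    seen: set[str] = set()
    for group in groups:
        member_vals = np.array([values[m] for m in group.members if m in values])
        size = member_vals.size
        if size == 0:
            continue
        group.median_activity = float(np.median(member_vals))
        for m in group.members:
            if m not in values:
                continue
            seen.add(m)
            if size >= min_group_size:
                if leave_one_out and size > min_group_size:
                    others = member_vals[
                        np.array([x for x in group.members if x in values]) != m
                    ]
                    ref = float(np.median(others))
                else:
                    ref = group.median_activity
            else:
                ref = global_median
            corrected.append(
                CorrectedActivity(sirna_id=m, corrected=values[m] - ref, group_size=size)
            )

    missing = set(values) - seen
    if missing:
        raise ValueError(
            f"{len(missing)} scored siRNAs have no seed group (e.g. "
            f"{sorted(missing)[:3]})"
        )
    return corrected
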
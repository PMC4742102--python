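"""Ground-truth simulators for every pipeline stage.

All simulators are pure functions of their configuration and RNG seed:
identical inputs yield identical outputs.  Plate effects are multiplicative
(log-normal) and phenotype effects are log-additive, matching the
ratio-based plate normalization applied downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dose_response import four_pl
from .io_formats import SirnaRecord, WellMeasurement
from .seed_correction import DEFAULT_SEED_LENGTH, DEFAULT_SEED_START, extract_seed

_RNA = np.array(list("ACGU"))
_DNA = "ACGT"
_RNA_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")


@dataclass
class SimulationTruth:
    """Everything a recovery test needs to score a simulated screen."""

    hit_genes: dict[str, float] = field(default_factory=dict)
    toxic_seeds: dict[str, float] = field(default_factory=dict)
    plate_effects: dict[str, float] = field(default_factory=dict)
    curve_params: dict = field(default_factory=dict)
    utr_sites: dict[str, int] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(e >= 0 for e in self.hit_genes.values()):
            raise ValueError("hit effect sizes must be negative")
        if any(m <= 0 for m in self.plate_effects.values()):
            raise ValueError("plate multipliers must be positive")


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def gen_library(
    n_genes: int, sirnas_per_gene: int = 2, rng_seed: int = 0, guide_length: int = 21
) -> list[SirnaRecord]:
    """Random siRNA library: ``n_genes`` genes x ``sirnas_per_gene`` guides."""
    if n_genes < 1 or sirnas_per_gene < 1:
        raise ValueError("need n_genes >= 1 and sirnas_per_gene >= 1")
    rng = np.random.default_rng(rng_seed)
    records = []
    for gi in range(n_genes):
        gene = f"G{gi + 1:05d}"
        for si in range(sirnas_per_gene):
            guide = "".join(rng.choice(_RNA, size=guide_length))
            rec = SirnaRecord(
                sirna_id=f"{gene}_s{si + 1}", gene=gene, guide_sequence=guide
            )
            rec.seed = extract_seed(guide, DEFAULT_SEED_START, DEFAULT_SEED_LENGTH)
            records.append(rec)
    return records


def plant_seed_effects(
    library: Sequence[SirnaRecord],
    n_seeds: int = 10,
    members_per_seed: int = 6,
    effect: float = -2.0,
    exclude_genes: set[str] | frozenset = frozenset(),
    rng_seed: int = 0,
) -> tuple[list[SirnaRecord], dict[str, float], list[str]]:
    """Rewrite guides so each toxic seed is shared by ``members_per_seed`` siRNAs.

    Each seed covers all siRNAs of one "victim" gene (so the gene mimics an
    on-target hit when uncorrected) plus single siRNAs of other genes.
    Returns the modified library copy, the seed->effect map and the victim
    gene list.
    """
    rng = np.random.default_rng(rng_seed)
    by_gene: dict[str, list[int]] = {}
    for i, rec in enumerate(library):
        by_gene.setdefault(rec.gene, []).append(i)
    eligible = sorted(g for g in by_gene if g not in exclude_genes)
    victims = list(rng.choice(eligible, size=n_seeds, replace=False))

    new_lib = [replace(rec) for rec in library]
    used: set[int] = set()
    toxic: dict[str, float] = {}
    pool = [g for g in eligible if g not in victims]
    for v in victims:
        seed = "".join(rng.choice(_RNA, size=DEFAULT_SEED_LENGTH))
        while seed in toxic:
            seed = "".join(rng.choice(_RNA, size=DEFAULT_SEED_LENGTH))
        toxic[seed] = effect
        member_idx = list(by_gene[v])
        n_extra = max(members_per_seed - len(member_idx), 0)
        extra_genes = rng.choice(pool, size=n_extra, replace=False)
        for g in extra_genes:
            candidates = [i for i in by_gene[g] if i not in used]
            member_idx.append(candidates[0] if candidates else by_gene[g][0])
        for i in member_idx:
            used.add(i)
            rec = new_lib[i]
            guide = rec.guide_sequence
            s0 = DEFAULT_SEED_START - 1
            rec.guide_sequence = guide[:s0] + seed + guide[s0 + DEFAULT_SEED_LENGTH :]
            rec.seed = seed
    return new_lib, toxic, victims


def make_discovery_truth(
    hit_genes: Mapping[str, float],
    toxic_seeds: Mapping[str, float],
    n_plates: int,
    plate_effect_sd: float = 0.2,
    rng_seed: int = 0,
) -> SimulationTruth:
    """Assemble a discovery-screen truth with log-normal plate effects."""
    rng = np.random.default_rng(rng_seed)
    plate_effects = {
        f"P{i + 1:03d}": float(np.exp(rng.normal(0.0, plate_effect_sd)))
        for i in range(n_plates)
    }
    return SimulationTruth(
        hit_genes=dict(hit_genes),
        toxic_seeds=dict(toxic_seeds),
        plate_effects=plate_effects,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def _plate_layout(n_plates: int, n_library: int, controls_per_plate: int, plate_size: int):
    capacity = plate_size - controls_per_plate
    needed = math.ceil(n_library / capacity)
    if needed > n_plates:
        raise ValueError(
            f"{n_library} library wells need {needed} plates of capacity {capacity}, "
            f"truth provides {n_plates}"
        )
    return capacity


def _addr(i: int, n_cols: int = 24) -> tuple[int, int]:
    return (i // n_cols + 1, i % n_cols + 1)


def simulate_discovery(
    library: Sequence[SirnaRecord],
    truth: SimulationTruth,
    noise_sd: float = 1.0,
    controls_per_plate: int = 16,
    plate_size: int = 384,
    baseline_rlu: float = 1000.0,
    rng_seed: int | None = None,
) -> list[WellMeasurement]:
    """Discovery screen: log signal = baseline + plate + gene + seed + noise.

    Reference (non-transfected) wells carry the plate effect and noise but
    no gene or seed effect.  Signals are exponentiated to RLU.
    """
    rng = np.random.default_rng(truth.rng_seed if rng_seed is None else rng_seed)
    plates = sorted(truth.plate_effects)
    capacity = _plate_layout(len(plates), len(library), controls_per_plate, plate_size)
    log_base = math.log(baseline_rlu)

    wells: list[WellMeasurement] = []
    for pi, plate_id in enumerate(plates):
        chunk = library[pi * capacity : (pi + 1) * capacity]
        if not chunk and pi * capacity >= len(library):
            break
        log_plate = math.log(truth.plate_effects[plate_id])
        for wi, rec in enumerate(chunk):
            eff = truth.hit_genes.get(rec.gene, 0.0) + truth.toxic_seeds.get(rec.seed, 0.0)
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            wells.append(
                WellMeasurement(
                    plate_id=plate_id,
                    well=_addr(wi),
                    role="library",
                    sirna_or_compound_id=rec.sirna_id,
                    signal=math.exp(log_base + log_plate + eff + noise),
                )
            )
        for ci in range(controls_per_plate):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            wells.append(
                WellMeasurement(
                    plate_id=plate_id,
                    well=_addr(capacity + ci),
                    role="non_transfected",
                    sirna_or_compound_id="",
                    signal=math.exp(log_base + log_plate + noise),
                )
            )
    return wells


def simulate_verification(
    library: Sequence[SirnaRecord],
    truth: SimulationTruth,
    noise_sd: float = 0.3,
    controls_per_plate: int = 16,
    plate_size: int = 384,
    baseline_rlu: float = 10000.0,
    positive_fraction: float = 0.02,
    rng_seed: int | None = None,
) -> list[WellMeasurement]:
    """Verification screen with per-plate positive (lethal) and negative controls."""
    rng = np.random.default_rng((truth.rng_seed + 1) if rng_seed is None else rng_seed)
    n_controls = 2 * controls_per_plate
    plates = sorted(truth.plate_effects)
    capacity = _plate_layout(len(plates), len(library), n_controls, plate_size)
    log_base = math.log(baseline_rlu)

    wells: list[WellMeasurement] = []
    for pi, plate_id in enumerate(plates):
        chunk = library[pi * capacity : (pi + 1) * capacity]
        if not chunk and pi * capacity >= len(library):
            break
        log_plate = math.log(truth.plate_effects[plate_id])
        for wi, rec in enumerate(chunk):
            eff = truth.hit_genes.get(rec.gene, 0.0) + truth.toxic_seeds.get(rec.seed, 0.0)
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            wells.append(
                WellMeasurement(
                    plate_id=plate_id,
                    well=_addr(wi),
                    role="library",
                    sirna_or_compound_id=rec.sirna_id,
                    signal=math.exp(log_base + log_plate + eff + noise),
                )
            )
        for ci in range(controls_per_plate):
            for off, (role, level) in enumerate(
                [("negative_control", 1.0), ("positive_control", positive_fraction)]
            ):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                wells.append(
                    WellMeasurement(
                        plate_id=plate_id,
                        well=_addr(capacity + 2 * ci + off),
                        role=role,
                        sirna_or_compound_id="",
                        signal=math.exp(log_base + log_plate + math.log(level) + noise),
                    )
                )
    return wells


# ---------------------------------------------------------------------------
# UTRs
# ---------------------------------------------------------------------------

def simulate_utrs(
    genes: Sequence[str],
    length: int = 300,
    planted: Mapping[str, str] | None = None,
    rng_seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Random DNA UTRs with reverse-complement sites of planted seeds inserted.

    Returns the gene->sequence mapping and the recorded insertion positions.
    """
    planted = dict(planted or {})
    rng = np.random.default_rng(rng_seed)
    utrs: dict[str, str] = {}
    positions: dict[str, int] = {}
    for gene in genes:
        seq = "".join(_DNA[i] for i in rng.integers(0, 4, size=length))
        if gene in planted:
            seed = planted[gene]
            site = seed.translate(_RNA_DNA_COMPLEMENT)[::-1]
            pos = int(rng.integers(0, length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site) :]
            positions[gene] = pos
        utrs[gene] = seq
    return utrs, positions


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

def simulate_dose_plate(
    curve_params: Mapping[tuple[str, str], tuple[float, float, float, float]],
    concentrations: Sequence[float],
    noise_sd_pct: float = 0.0,
    outlier_rate: float = 0.0,
    rng_seed: int = 0,
    n_control: int = 16,
    gain_sd: float = 0.2,
    dmso_rlu: float = 10000.0,
    bortezomib_rlu: float = 200.0,
) -> list[WellMeasurement]:
    """qHTS plates: 4PL viabilities with noise, outliers and a per-plate gain.

    ``curve_params`` maps (compound, cell_line) -> (top, bottom, ac50, hill);
    one plate is generated per cell line (plate id = cell line).  Outlier
    wells are replaced by uniform(0, 120)% viability.  Control wells sit at
    their defining levels exactly, so normalization recovers 100/0 by
    construction.
    """
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(rng_seed)
    by_line: dict[str, list[tuple[str, tuple]]] = {}
    for (compound, cell_line), params in sorted(curve_params.items()):
        by_line.setdefault(cell_line, []).append((compound, params))

    wells: list[WellMeasurement] = []
    for cell_line in sorted(by_line):
        gain = float(np.exp(rng.normal(0.0, gain_sd))) if gain_sd > 0 else 1.0
        span = dmso_rlu - bortezomib_rlu
        wi = 0
        for compound, (top, bottom, ac50, hill) in by_line[cell_line]:
            v = four_pl(conc, top, bottom, ac50, hill)
            if noise_sd_pct > 0:
                v = v + rng.normal(0.0, noise_sd_pct, size=conc.size)
            if outlier_rate > 0:
                out = rng.random(conc.size) < outlier_rate
                v = np.where(out, rng.uniform(0.0, 120.0, size=conc.size), v)
            for k in range(conc.size):
                rlu = gain * (bortezomib_rlu + v[k] / 100.0 * span)
                wells.append(
                    WellMeasurement(
                        plate_id=cell_line,
                        well=_addr(wi, n_cols=48),
                        role="library",
                        sirna_or_compound_id=compound,
                        signal=max(rlu, 0.0),
                    )
                )
                wi += 1
        for role, level in [("dmso", dmso_rlu), ("bortezomib", bortezomib_rlu)]:
            for _ in range(n_control):
                wells.append(
                    WellMeasurement(
                        plate_id=cell_line,
                        well=_addr(wi, n_cols=48),
                        role=role,
                        sirna_or_compound_id="",
                        signal=gain * level,
                    )
                )
                wi += 1
    return wells
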
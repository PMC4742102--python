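"""Readers and writers for plate tables, siRNA libraries, UTR FASTA and result reports.

This module is the pipeline's only I/O boundary.  Plate tables and library
annotations are delimited text (TSV by default, CSV accepted by sniffing);
3'-UTR sequences are plain FASTA.  Well addresses are accepted either in
letter-number form (``A01``, ``AF48``) or as ``row,col`` / ``row:col``
integer pairs and stored canonically as 1-based ``(row, col)`` tuples.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Closed vocabulary of well roles.
ROLES = frozenset(
    {
        "library",
        "non_transfected",
        "negative_control",
        "positive_control",
        "dmso",
        "bortezomib",
    }
)

_WELL_ALPHA = re.compile(r"^([A-Za-z]+)(\d+)$")
_WELL_NUM = re.compile(r"^(\d+)[,:](\d+)$")
_RNA = re.compile(r"^[ACGU]+$")
_DNA = re.compile(r"^[ACGTN]+$")


# ---------------------------------------------------------------------------
# well addresses
# ---------------------------------------------------------------------------

def parse_well(text: str) -> tuple[int, int]:
    """Parse a well address into a canonical 1-based ``(row, col)`` tuple."""
    text = str(text).strip()
    m = _WELL_ALPHA.match(text)
    if m:
        letters, digits = m.group(1).upper(), m.group(2)
        row = 0
        for ch in letters:  # bijective base-26, A=1 .. Z=26, AA=27
            row = row * 26 + (ord(ch) - 64)
        col = int(digits)
        if row < 1 or col < 1:
            raise ValueError(f"invalid well address {text!r}")
        return (row, col)
    m = _WELL_NUM.match(text)
    if m:
        row, col = int(m.group(1)), int(m.group(2))
        if row < 1 or col < 1:
            raise ValueError(f"invalid well address {text!r}")
        return (row, col)
    raise ValueError(f"cannot parse well address {text!r}")


def format_well(well: tuple[int, int]) -> str:
    """Format a canonical ``(row, col)`` tuple as ``A01``-style text."""
    row, col = well
    if row < 1 or col < 1:
        raise ValueError(f"invalid well tuple {well!r}")
    letters = ""
    r = row
    while r > 0:
        r, rem = divmod(r - 1, 26)
        letters = chr(65 + rem) + letters
    return f"{letters}{col:02d}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class WellMeasurement:
    """One well's raw luminescence signal (RLU) together with its role."""

    plate_id: str
    well: tuple[int, int]
    role: str
    sirna_or_compound_id: str = ""
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r}; expected one of {sorted(ROLES)}"
            )
        self.well = (int(self.well[0]), int(self.well[1]))
        self.signal = float(self.signal)
        if not math.isfinite(self.signal) or self.signal < 0:
            raise ValueError(
                f"signal must be a nonnegative finite number, got {self.signal!r}"
            )


@dataclass
class SirnaRecord:
    """One siRNA library entry.

    The guide sequence is stored as upper-case RNA (T mapped to U at parse
    time).  ``seed`` is left unset by the reader and filled by the seed
    correction stage.
    """

    sirna_id: str
    gene: str
    guide_sequence: str
    seed: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"siRNA {self.sirna_id!r} has an empty gene symbol")
        if not _RNA.match(self.guide_sequence):
            raise ValueError(
                f"siRNA {self.sirna_id!r}: guide contains non-ACGU characters: "
                f"{self.guide_sequence!r}"
            )
        if not 19 <= len(self.guide_sequence) <= 23:
            raise ValueError(
                f"siRNA {self.sirna_id!r}: guide length "
                f"{len(self.guide_sequence)} outside [19, 23]"
            )


@dataclass
class ExpressionRecord:
    """Per-gene expression level (FPKM, optionally with the expected count)."""

    gene: str
    fpkm: float
    expected_count: float | None = None
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.fpkm = float(self.fpkm)
        if self.fpkm < 0:
            raise ValueError(f"gene {self.gene!r}: negative FPKM {self.fpkm}")


# ---------------------------------------------------------------------------
# delimited-table helpers
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_table(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    """Read a delimited file with a header; returns a list of row dicts."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file, expected a header line")
    delim = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(delim)]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header={header}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in ln.split(delim)]
        if len(parts) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        row = dict(zip(header, parts))
        row["__lineno__"] = str(lineno)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_plate_table(path: str | Path) -> list[WellMeasurement]:
    """Read a plate table with columns ``plate, well, role, id, signal``."""
    rows = _read_table(path, required=["plate", "well", "role", "id", "signal"])
    records: list[WellMeasurement] = []
    seen: set[tuple[str, tuple[int, int]]] = set()
    for row in rows:
        lineno = row["__lineno__"]
        role = row["role"]
        if role not in ROLES:
            raise ValueError(f"{path}:{lineno}: unknown role {role!r}")
        try:
            signal = float(row["signal"])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: non-numeric signal {row['signal']!r}"
            ) from exc
        rec = WellMeasurement(
            plate_id=row["plate"],
            well=parse_well(row["well"]),
            role=role,
            sirna_or_compound_id=row["id"],
            signal=signal,
        )
        key = (rec.plate_id, rec.well)
        if key in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate well {format_well(rec.well)} "
                f"on plate {rec.plate_id}"
            )
        seen.add(key)
        records.append(rec)
    if not records:
        log.warning("%s: header-only plate table, no wells read", path)
    return records


def read_library(path: str | Path) -> list[SirnaRecord]:
    """Read an siRNA library annotation (``sirna_id, gene, guide_sequence``).

    Guides are upper-cased and DNA T is mapped to RNA U so downstream seed
    matching is alphabet-stable.  The ``seed`` field is left unset.
    """
    rows = _read_table(path, required=["sirna_id", "gene", "guide_sequence"])
    records: list[SirnaRecord] = []
    seen: set[str] = set()
    for row in rows:
        lineno = row["__lineno__"]
        sid = row["sirna_id"]
        if sid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate sirna_id {sid!r}")
        seen.add(sid)
        guide = row["guide_sequence"].upper().replace("T", "U")
        try:
            records.append(SirnaRecord(sirna_id=sid, gene=row["gene"], guide_sequence=guide))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read a gene-expression table (``gene, fpkm`` plus optional columns)."""
    rows = _read_table(path, required=["gene", "fpkm"])
    records = []
    for row in rows:
        lineno = row["__lineno__"]
        try:
            fpkm = float(row["fpkm"])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric fpkm {row['fpkm']!r}") from exc
        ec = row.get("expected_count", "")
        records.append(
            ExpressionRecord(
                gene=row["gene"],
                fpkm=fpkm,
                expected_count=float(ec) if ec not in ("", None) else None,
                cell_line=row.get("cell_line", ""),
            )
        )
    return records


def read_fasta_utrs(path: str | Path) -> dict[str, str]:
    """Read 3'-UTR sequences from FASTA; header token = gene symbol.

    Sequences are upper-cased DNA over {A,C,G,T,N}.  A duplicated gene header
    keeps the longest record and logs a warning.
    """
    utrs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = record.id
        seq = str(record.seq).upper()
        if seq and not _DNA.match(seq):
            raise ValueError(f"{path}: UTR for {gene!r} contains non-ACGTN characters")
        if gene in utrs:
            log.warning(
                "%s: duplicate FASTA header %r; keeping the longest record", path, gene
            )
            if len(seq) <= len(utrs[gene]):
                continue
        utrs[gene] = seq
    return utrs


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return _FLOAT_FMT % value
    return str(value)


def _parse_opt_float(text: str) -> float | None:
    return None if text == "" else float(text)


def write_plate_table(records: Iterable[WellMeasurement], path: str | Path) -> Path:
    path = Path(path)
    lines = ["plate\twell\trole\tid\tsignal"]
    for rec in records:
        lines.append(
            "\t".join(
                [
                    rec.plate_id,
                    format_well(rec.well),
                    rec.role,
                    rec.sirna_or_compound_id,
                    _fmt(rec.signal),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_library(records: Iterable[SirnaRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = ["sirna_id\tgene\tguide_sequence"]
    for rec in records:
        lines.append("\t".join([rec.sirna_id, rec.gene, rec.guide_sequence]))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_expression(records: Iterable[ExpressionRecord], path: str | Path) -> Path:
    path = Path(path)
    lines = ["gene\tfpkm\texpected_count\tcell_line"]
    for rec in records:
        lines.append(
            "\t".join([rec.gene, _fmt(rec.fpkm), _fmt(rec.expected_count), rec.cell_line])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fasta(utrs: Mapping[str, str], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    chunks = []
    for gene, seq in utrs.items():
        chunks.append(f">{gene}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    path.write_text("\n".join(chunks) + "\n")
    return path


_GENE_RESULT_COLUMNS = [
    "gene",
    "cell_line",
    "rsa_log10p",
    "best_activity",
    "n_sirnas",
    "is_hit",
    "is_verified",
    "passes_expression",
    "log2_fpkm",
]

_CURVE_COLUMNS = [
    "compound",
    "cell_line",
    "concentrations",
    "viability_pct",
    "top",
    "bottom",
    "ac50",
    "hill",
    "loss",
    "converged",
    "n_auc",
    "ic50_abs",
    "ec50_rel",
    "outlier_mask",
]


def write_results(records: Sequence, path: str | Path) -> Path:
    """Write gene results or dose-response curves to a deterministic TSV.

    The record type is dispatched on shape; the matching reader
    (:func:`read_gene_results` / :func:`read_curves`) round-trips the file.
    An empty collection produces a gene-result header-only file.
    """
    path = Path(path)
    records = list(records)
    if records and hasattr(records[0], "compound"):
        return _write_curves(records, path)
    return _write_gene_results(records, path)


def _write_gene_results(records: Sequence, path: Path) -> Path:
    lines = ["\t".join(_GENE_RESULT_COLUMNS)]
    for rec in records:
        lines.append("\t".join(_fmt(getattr(rec, col)) for col in _GENE_RESULT_COLUMNS))
    path.write_text("\n".join(lines) + "\n")
    return path


def _write_curves(records: Sequence, path: Path) -> Path:
    lines = ["\t".join(_CURVE_COLUMNS)]
    for rec in records:
        fit = rec.fit
        row = [
            rec.compound,
            rec.cell_line,
            ";".join(_fmt(c) for c in rec.concentrations),
            ";".join(_fmt(v) for v in rec.viability_pct),
            _fmt(fit.top if fit else None),
            _fmt(fit.bottom if fit else None),
            _fmt(fit.ac50 if fit else None),
            _fmt(fit.hill if fit else None),
            _fmt(fit.loss if fit else None),
            _fmt(fit.converged if fit else None),
            _fmt(rec.n_auc),
            _fmt(rec.ic50_abs),
            _fmt(rec.ec50_rel),
            ";".join("1" if m else "0" for m in rec.outlier_mask),
        ]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gene_results(path: str | Path) -> list:
    """Read back a gene-result TSV written by :func:`write_results`."""
    from .hit_calling import GeneResult

    rows = _read_table(path, required=_GENE_RESULT_COLUMNS)
    out = []
    for row in rows:
        out.append(
            GeneResult(
                gene=row["gene"],
                cell_line=row["cell_line"],
                rsa_log10p=float(row["rsa_log10p"]),
                best_activity=float(row["best_activity"]),
                n_sirnas=int(row["n_sirnas"]),
                is_hit=row["is_hit"] == "true",
                is_verified=row["is_verified"] == "true",
                passes_expression=row["passes_expression"] == "true",
                log2_fpkm=float(row["log2_fpkm"]),
            )
        )
    return out


def read_curves(path: str | Path) -> list:
    """Read back a dose-response TSV written by :func:`write_results`."""
    from .dose_response import DoseResponseCurve, FourPLFit

    rows = _read_table(path, required=_CURVE_COLUMNS)
    out = []
    for row in rows:
        fit = None
        if row["top"] != "":
            fit = FourPLFit(
                top=float(row["top"]),
                bottom=float(row["bottom"]),
                ac50=float(row["ac50"]),
                hill=float(row["hill"]),
                loss=float(row["loss"]),
                converged=row["converged"] == "true",
            )
        out.append(
            DoseResponseCurve(
                compound=row["compound"],
                cell_line=row["cell_line"],
                concentrations=tuple(float(x) for x in row["concentrations"].split(";")),
                viability_pct=tuple(float(x) for x in row["viability_pct"].split(";")),
                fit=fit,
                n_auc=_parse_opt_float(row["n_auc"]),
                ic50_abs=_parse_opt_float(row["ic50_abs"]),
                ec50_rel=_parse_opt_float(row["ec50_rel"]),
                outlier_mask=tuple(x == "1" for x in row["outlier_mask"].split(";")),
            )
        )
    return out
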
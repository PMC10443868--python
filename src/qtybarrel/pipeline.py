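"""End-to-end orchestration: sequences + topologies (+ structures) to a
summary table with one row per protein.

For each protein the pipeline applies the QTY transform, computes pI,
MW and GRAVY for native and variant, the TM/overall variation
statistics, and — when a native structure and a variant model are
supplied — the CA superposition RMSD.  Failures are collected per
protein; remaining proteins still run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

from . import physchem, structure_compare
from .qty_engine import QTYResult, qty_transform, round_half_up
from .sequence_io import ProteinRecord, Topology

logger = logging.getLogger("qtybarrel")

REPORT_COLUMNS = (
    "protein_id", "variant_id", "pI_nat", "pI_qty", "MW_kDa_nat", "MW_kDa_qty",
    "TM_variation", "overall_variation", "RMSD_A",
)


@dataclass(frozen=True)
class RunConfig:
    """Resolved run configuration (file values overridden by CLI flags)."""

    kd_window: int = 9
    pairing: str = "by_number"
    trim: bool = False
    trim_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if self.kd_window < 1 or self.kd_window % 2 == 0:
            raise ValueError(f"kd_window must be odd and positive, got {self.kd_window}")
        if self.pairing not in ("by_number", "by_order"):
            raise ValueError(f"pairing must be by_number or by_order, got {self.pairing!r}")
        if self.trim_cutoff <= 0:
            raise ValueError("trim_cutoff must be positive")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a JSON config file and apply keyword overrides.

    Unknown keys raise a ``ValueError`` listing the valid ones.
    """
    valid = {f.name for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        values.update(data)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(
            f"unknown config overrides {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    values.update(overrides)
    config = RunConfig(**values)
    logger.info("config resolved: %s", config)
    return config


@dataclass
class ReportRow:
    """One protein's summary record (Table-style)."""

    protein_id: str
    variant_id: str
    pI_native: float
    pI_variant: float
    mw_kda_native: float
    mw_kda_variant: float
    tm_percent: float
    tm_changed: int
    tm_total: int
    overall_percent: float
    rmsd_A: float | None = None
    qty: QTYResult | None = field(default=None, repr=False)

    def to_tsv_fields(self) -> list[str]:
        tm_cell = f"{self.tm_percent:.2f} ({self.tm_changed}/{self.tm_total})"
        return [
            self.protein_id,
            self.variant_id,
            f"{self.pI_native:.2f}",
            f"{self.pI_variant:.2f}",
            f"{self.mw_kda_native:.2f}",
            f"{self.mw_kda_variant:.2f}",
            tm_cell,
            f"{self.overall_percent:.2f}",
            "" if self.rmsd_A is None else f"{self.rmsd_A:.3f}",
        ]


def _audit_row(row: ReportRow) -> None:
    # Self-audit before writing: the printed percentage must reproduce
    # from the printed counts under the same rounding rule.
    if row.tm_total:
        expected = round_half_up(100.0 * row.tm_changed / row.tm_total)
        if expected != row.tm_percent:
            raise AssertionError(
                f"{row.protein_id}: TM percent {row.tm_percent} inconsistent "
                f"with counts {row.tm_changed}/{row.tm_total} (expect {expected})"
            )


def run_report(
    records: Sequence[ProteinRecord],
    topologies: Sequence[Topology],
    structures: dict | None = None,
    config: RunConfig | None = None,
) -> tuple[list[ReportRow], dict]:
    """Run the full per-protein analysis.

    ``structures`` optionally maps protein id to a tuple
    ``(native_pdb, native_chain, model_pdb, model_chain)``.  Returns the
    report rows and a dict of per-protein failure messages (empty when
    everything succeeded).
    """
    if not records:
        raise ValueError("run_report: no input records")
    config = config or RunConfig()
    topo_by_id = {t.protein_id: t for t in topologies}
    structures = structures or {}
    rows: list[ReportRow] = []
    failures: dict = {}
    for record in records:
        t0 = time.perf_counter()
        try:
            topology = topo_by_id.get(record.id)
            if topology is None:
                raise ValueError(f"no topology provided for {record.id!r}")
            result = qty_transform(record, topology)
            rep_nat = physchem.physchem_report(record.sequence)
            rep_var = physchem.physchem_report(result.variant.sequence)
            rmsd = None
            if record.id in structures:
                native_pdb, native_chain, model_pdb, model_chain = structures[record.id]
                fixed = structure_compare.read_pdb_ca(native_pdb, native_chain)
                mobile = structure_compare.read_pdb_ca(model_pdb, model_chain)
                sup, _ = structure_compare.superpose_models(
                    fixed, mobile, pairing=config.pairing,
                    trim=config.trim, trim_cutoff=config.trim_cutoff,
                )
                rmsd = sup.rmsd
            row = ReportRow(
                protein_id=record.id,
                variant_id=result.variant.id,
                pI_native=rep_nat.pI,
                pI_variant=rep_var.pI,
                mw_kda_native=rep_nat.mw_kda,
                mw_kda_variant=rep_var.mw_kda,
                tm_percent=result.stats.tm_percent,
                tm_changed=result.stats.tm_changed,
                tm_total=result.stats.tm_total,
                overall_percent=result.stats.overall_percent,
                rmsd_A=rmsd,
                qty=result,
            )
            _audit_row(row)
            rows.append(row)
            logger.info(
                "protein=%s stage=report elapsed=%.3fs tm=%s overall=%.2f",
                record.id, time.perf_counter() - t0,
                result.stats.tm_cell(), result.stats.overall_percent,
            )
        except Exception as exc:  # per-protein isolation; pipeline continues
            failures[record.id] = str(exc)
            logger.error("protein=%s stage=report failed: %s", record.id, exc)
    return rows, failures


def format_report_tsv(rows: Sequence[ReportRow]) -> str:
    """Deterministic TSV rendering: identical inputs give identical bytes."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for row in rows:
        lines.append("\t".join(row.to_tsv_fields()))
    return "\n".join(lines) + "\n"
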
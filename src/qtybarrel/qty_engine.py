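"""The QTY substitution engine.

The QTY code converts the lipid-facing hydrophobic surface of a
transmembrane segment into a hydrophilic one by a fixed residue map —
leucine to glutamine, isoleucine and valine to threonine, phenylalanine
to tyrosine — chosen so that each replacement pair shares an electron
density envelope of very similar shape.  Here the code is applied to
every L/I/V/F inside annotated transmembrane beta-strands; loops and any
alpha-helices are never touched, however hydrophobic.

The engine also computes the two headline variation statistics of a
design: the TM variation (changed residues over all residues in TM
strands) and the overall variation (changed residues over the whole
sequence), and renders a pairwise alignment of native against variant in
the conventional ``|``/``*`` marker style with the strand annotation
drawn above the sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .sequence_io import ProteinRecord, Topology, VARIANT_SUFFIX

#: The QTY code: the only substitutions the design ever makes.
QTY_MAP = {"L": "Q", "I": "T", "V": "T", "F": "Y"}

HYDROPHOBIC_SOURCE = frozenset(QTY_MAP)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (what a printed table does), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Substitution:
    """One residue replacement, 1-based position."""

    position: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if QTY_MAP.get(self.from_aa) != self.to_aa:
            raise ValueError(
                f"invalid QTY substitution {self.from_aa}->{self.to_aa} "
                f"at position {self.position}; the code is "
                + ", ".join(f"{k}->{v}" for k, v in QTY_MAP.items())
            )
        if self.position < 1:
            raise ValueError("substitution position must be >= 1")


@dataclass(frozen=True)
class VariationStats:
    """Changed-residue counts and percentages, TM-restricted and overall."""

    tm_changed: int
    tm_total: int
    overall_changed: int
    overall_total: int

    @property
    def tm_percent(self) -> float:
        if self.tm_total == 0:
            return 0.0
        return round_half_up(100.0 * self.tm_changed / self.tm_total)

    @property
    def overall_percent(self) -> float:
        if self.overall_total == 0:
            return 0.0
        return round_half_up(100.0 * self.overall_changed / self.overall_total)

    def tm_cell(self) -> str:
        """Table cell in the ``P (c/t)`` style, e.g. ``27.22 (49/180)``."""
        return f"{self.tm_percent:.2f} ({self.tm_changed}/{self.tm_total})"


@dataclass(frozen=True)
class QTYResult:
    """A native record, its QTY variant, and the explicit substitution list."""

    native: ProteinRecord
    variant: ProteinRecord
    substitutions: tuple
    stats: VariationStats


def qty_transform(record: ProteinRecord, topology: Topology) -> QTYResult:
    """Apply the QTY code to ``record`` within its TM strands.

    Every L/I/V/F whose position lies inside a ``tm_strand`` segment is
    replaced per :data:`QTY_MAP`; all other residues are untouched.  The
    transform is idempotent: Q/T/Y are not in the source set, so applying
    it to its own output makes no further change.
    """
    base_id = (
        record.id[: -len(VARIANT_SUFFIX)]
        if record.id.endswith(VARIANT_SUFFIX)
        else record.id
    )
    if topology.protein_id not in (record.id, base_id):
        raise ValueError(
            f"topology {topology.protein_id!r} does not belong to record {record.id!r}"
        )
    if topology.max_end() > len(record):
        raise ValueError(
            f"{topology.protein_id}: segment end {topology.max_end()} beyond "
            f"sequence length {len(record)}"
        )
    tm = topology.tm_positions()
    chars = list(record.sequence)
    substitutions = []
    for pos in sorted(tm):
        aa = chars[pos - 1]
        if aa in QTY_MAP:
            chars[pos - 1] = QTY_MAP[aa]
            substitutions.append(Substitution(pos, aa, QTY_MAP[aa]))
    variant_seq = "".join(chars)
    variant_id = (
        record.id if record.id.endswith(VARIANT_SUFFIX) else record.id + VARIANT_SUFFIX
    )
    variant = ProteinRecord(
        id=variant_id,
        description=(record.description + " QTY variant").strip(),
        sequence=variant_seq,
        source=record.source,
    )
    stats = variation_stats(record.sequence, variant_seq, topology)
    return QTYResult(
        native=record,
        variant=variant,
        substitutions=tuple(substitutions),
        stats=stats,
    )


def variation_stats(native: str, variant: str, topology: Topology) -> VariationStats:
    """Positionwise change counts restricted to the TM set and overall.

    TM variation is the number of changed residues inside tm_strand
    segments over the total number of TM-strand residues; overall
    variation uses the full sequence length as denominator.
    """
    if len(native) != len(variant):
        raise ValueError(
            f"variation_stats: unequal lengths ({len(native)} vs {len(variant)})"
        )
    tm = topology.tm_positions()
    tm_changed = sum(1 for pos in tm if native[pos - 1] != variant[pos - 1])
    overall_changed = sum(1 for a, b in zip(native, variant) if a != b)
    return VariationStats(
        tm_changed=tm_changed,
        tm_total=len(tm),
        overall_changed=overall_changed,
        overall_total=len(native),
    )


def render_alignment(
    native: ProteinRecord,
    variant: ProteinRecord,
    topology: Topology,
    width: int = 60,
) -> str:
    """Render a blockwise pairwise alignment of native against variant.

    Per block of ``width`` columns: a strand-annotation line (``E`` over
    tm_strand columns), the native line, a marker line (``|`` identical,
    ``*`` different), and the variant line; sequence lines end with the
    1-based index of their last shown residue.
    """
    if len(native.sequence) != len(variant.sequence):
        raise ValueError("render_alignment: sequences have unequal lengths")
    if width < 10:
        raise ValueError("render_alignment: width must be >= 10")

    n = len(native.sequence)
    strand_track = "".join("E" if topology.is_tm(i) else " " for i in range(1, n + 1))
    markers = "".join(
        "|" if a == b else "*" for a, b in zip(native.sequence, variant.sequence)
    )
    label_w = max(len(native.id), len(variant.id), 6) + 2

    blocks = []
    for start in range(0, n, width):
        stop = min(start + width, n)
        pad = " " * label_w
        blocks.append(
            "\n".join(
                [
                    pad + strand_track[start:stop],
                    f"{native.id:<{label_w}}" + native.sequence[start:stop] + f"  {stop}",
                    pad + markers[start:stop],
                    f"{variant.id:<{label_w}}" + variant.sequence[start:stop] + f"  {stop}",
                ]
            )
        )
    return "\n\n".join(blocks) + "\n"
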
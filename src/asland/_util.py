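"""Sequence and rounding helpers used throughout the package."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) (0-based half-open), uppercase.

    Accepts either a plain mapping of chromosome name -> sequence string or
    a pyfaidx.Fasta-like object whose slices stringify to the sequence.
    """
    record = genome[chrom]
    if isinstance(record, str):
        return record[start:end].upper()
    return str(record[start:end]).upper()


def chrom_length(genome, chrom: str) -> int:
    record = genome[chrom]
    return len(record)


def pct(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator rounded half-away-from-zero to 1 decimal.

    This is the single rounding rule used for every reported percentage,
    matching the convention of one-decimal printed tables.
    """
    if denominator == 0:
        raise ZeroDivisionError("pct() denominator is zero")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def write_fasta(records: Mapping[str, str], path, width: int = 70) -> None:
    """Write sequences to a FASTA file with deterministic record order."""
    with open(path, "w") as fh:
        for name in records:
            seq = records[name]
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
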
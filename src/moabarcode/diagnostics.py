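"""Diagnostic-SNP discovery and classification.

A diagnostic SNP is an alignment column fixed for one unambiguous base in
group A and a different unambiguous base in group B (a strict fixed
difference). Ambiguity codes, N and gaps never break fixation; they only
reduce the supporting counts — conservative for degraded ancient DNA, where
an IUPAC Y compatible with a fixed C is still treated as missing rather
than as support. Positions are reported in reference-genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from moabarcode.seqio import Alignment, UNAMBIGUOUS, column_to_ref, ref_to_column


class CoverageError(ValueError):
    """A group or sequence has no usable observation where one is required."""


@dataclass(frozen=True)
class DiagnosticSNP:
    """A fixed difference between two named sample groups.

    ``n_a``/``n_b`` count the unambiguous observations supporting fixation.
    """

    ref_position: int
    allele_a: str
    allele_b: str
    group_a_name: str
    group_b_name: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("alleles must differ")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("each group needs at least one supporting sample")


def _fixed_base(bases: Iterable[str]) -> Optional[tuple[str, int]]:
    """(base, count) if all unambiguous observations agree; None otherwise."""
    seen = [b for b in bases if b in UNAMBIGUOUS]
    if not seen:
        return None
    if len(set(seen)) != 1:
        return None
    return seen[0], len(seen)


def find_diagnostic_snps(
    alignment: Alignment,
    groups: dict[str, str],
    min_per_group: int = 1,
) -> list[DiagnosticSNP]:
    """Scan every column for strict fixed differences between two groups.

    ``groups`` maps sample_id to a group name; exactly two distinct names
    must be present (decompose multi-group designs into one-vs-rest scans).
    A column qualifies when each group is fixed for a different unambiguous
    base with at least ``min_per_group`` unambiguous observations.
    """
    if min_per_group < 1:
        raise ValueError("min_per_group must be >= 1")
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"exactly 2 groups required, got {names}")
    name_a, name_b = names
    idx_a = [i for i, sid in enumerate(alignment.sample_ids) if groups.get(sid) == name_a]
    idx_b = [i for i, sid in enumerate(alignment.sample_ids) if groups.get(sid) == name_b]
    if not idx_a or not idx_b:
        raise ValueError("each group must contain at least one aligned sample")
    seqs = alignment.sequences

    any_cov_a = any(
        seqs[i][c] in UNAMBIGUOUS for i in idx_a for c in range(alignment.length)
    )
    any_cov_b = any(
        seqs[i][c] in UNAMBIGUOUS for i in idx_b for c in range(alignment.length)
    )
    out: list[DiagnosticSNP] = []
    for col in range(1, alignment.length + 1):
        fa = _fixed_base(seqs[i][col - 1] for i in idx_a)
        fb = _fixed_base(seqs[i][col - 1] for i in idx_b)
        if fa is None or fb is None:
            continue
        (base_a, n_a), (base_b, n_b) = fa, fb
        if base_a != base_b and n_a >= min_per_group and n_b >= min_per_group:
            out.append(
                DiagnosticSNP(
                    ref_position=column_to_ref(alignment, col),
                    allele_a=base_a,
                    allele_b=base_b,
                    group_a_name=name_a,
                    group_b_name=name_b,
                    n_a=n_a,
                    n_b=n_b,
                )
            )
    if not any_cov_a:
        raise CoverageError(f"group {name_a!r} has no unambiguous observation at any site")
    if not any_cov_b:
        raise CoverageError(f"group {name_b!r} has no unambiguous observation at any site")
    return out


def classify_by_snp(sequence: str, alignment: Alignment, snp: DiagnosticSNP) -> str:
    """Assign a sequence to ``group_a``/``group_b``/``unknown`` by one SNP.

    The sequence must be laid out on the same coordinate system as
    ``alignment`` (same ref_start and length). A base matching neither
    fixed allele, or an ambiguous/missing base, yields ``"unknown"``.
    """
    if len(sequence) != alignment.length:
        raise CoverageError(
            f"sequence length {len(sequence)} does not match alignment length {alignment.length}"
        )
    col = ref_to_column(alignment, snp.ref_position)
    base = sequence[col - 1].upper()
    if base == snp.allele_a:
        return "group_a"
    if base == snp.allele_b:
        return "group_b"
    return "unknown"


def snp_segregation_table(
    calls: list[tuple[str, str, str]],
) -> tuple[list[list[int]], list[str]]:
    """2x2 counts of eggshell class I/II by island.

    ``calls`` holds (sample_id, class, island) with class in {"I", "II"} and
    island in {"NorthIsland", "SouthIsland"}. Returns the count table
    ``[[NI-I, NI-II], [SI-I, SI-II]]`` and a list of notes; a zero cell
    yields a note flagging perfect island fixation of that class.
    """
    table = [[0, 0], [0, 0]]
    for sample, cls, island in calls:
        if cls not in ("I", "II"):
            raise ValueError(f"sample {sample!r}: class must be I or II, got {cls!r}")
        if island not in ("NorthIsland", "SouthIsland"):
            raise ValueError(f"sample {sample!r}: bad island {island!r}")
        table[0 if island == "NorthIsland" else 1][0 if cls == "I" else 1] += 1
    notes = []
    labels = [("NorthIsland", "I"), ("NorthIsland", "II"), ("SouthIsland", "I"), ("SouthIsland", "II")]
    if calls:
        for (isl, cls), v in zip(labels, [table[0][0], table[0][1], table[1][0], table[1][1]]):
            if v == 0:
                notes.append(f"no class {cls} samples on {isl}: perfect island fixation")
    return table, notes


def write_snp_panel(snps: list[DiagnosticSNP], ref_name: str, path: str | Path) -> None:
    """Export the SNP panel as TSV."""
    with open(path, "w") as fh:
        fh.write("ref_name\tref_position\tallele_a\tallele_b\tgroup_a\tgroup_b\tn_a\tn_b\n")
        for s in snps:
            fh.write(
                f"{ref_name}\t{s.ref_position}\t{s.allele_a}\t{s.allele_b}\t"
                f"{s.group_a_name}\t{s.group_b_name}\t{s.n_a}\t{s.n_b}\n"
            )
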
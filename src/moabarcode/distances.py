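"""Kimura 2-parameter divergences under complete- or pairwise-deletion masking.

The K2P distance separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q):

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

Complete deletion removes every alignment column containing any gap,
ambiguity code or N before counting, so all pairs share one site mask; this
mirrors the convention used for barcode divergence tables. Pairwise deletion
keeps, for each pair, the columns where both members are unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from moabarcode.seqio import Alignment, UNAMBIGUOUS

TRANSITION_PAIRS = frozenset({frozenset("AG"), frozenset("CT")})


class DegenerateDataError(ValueError):
    """No usable site survives masking."""


class SaturationError(ValueError):
    """Substitution proportions outside the K2P formula's domain."""


@dataclass(frozen=True)
class SiteMask:
    """Ordered set of kept 1-based alignment columns."""

    kept_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        cols = self.kept_columns
        if any(c2 <= c1 for c1, c2 in zip(cols, cols[1:])):
            raise ValueError("kept_columns must be strictly increasing")
        if cols and cols[0] < 1:
            raise ValueError("columns are 1-based")

    def __len__(self) -> int:
        return len(self.kept_columns)


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion proportions over the compared sites."""

    n_sites: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise DegenerateDataError("n_sites must be >= 1")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid proportions P={self.P}, Q={self.Q}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise divergence matrix with its provenance mask.

    Undefined (saturated) pairs hold ``nan`` in ``d``; ``mask`` is None in
    pairwise-deletion mode where no single shared mask exists.
    """

    sample_ids: tuple[str, ...]
    d: np.ndarray
    mask: Optional[SiteMask]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.d[i, j])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if math.isnan(self.d[i, j]):
                    out.append((self.sample_ids[i], self.sample_ids[j]))
        return out

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(tuple(sample_ids), self.d[np.ix_(idx, idx)], self.mask)

    def to_tsv(self, path: str | Path, percent: bool = False) -> None:
        """Write as square TSV with id header row/column.

        With ``percent=True`` entries are divergence x 100 rounded to two
        decimals (report convention); the stored values stay unrounded.
        """
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.sample_ids) + "\n")
            for i, sid in enumerate(self.sample_ids):
                cells = []
                for j in range(self.n):
                    v = self.d[i, j]
                    if math.isnan(v):
                        cells.append("NA")
                    elif percent:
                        cells.append(f"{100 * v:.2f}")
                    else:
                        cells.append(f"{v:.8f}")
                fh.write(sid + "\t" + "\t".join(cells) + "\n")


def complete_deletion_mask(alignment: Alignment) -> SiteMask:
    """Columns where every sample has an unambiguous base in {A,C,G,T}."""
    kept = []
    seqs = alignment.sequences
    for col in range(alignment.length):
        if all(seq[col] in UNAMBIGUOUS for seq in seqs):
            kept.append(col + 1)
    if not kept:
        raise DegenerateDataError("complete deletion removed every column")
    return SiteMask(tuple(kept))


def pairwise_deletion_mask(a: str, b: str) -> SiteMask:
    """Columns where both of two sequences are unambiguous."""
    kept = tuple(
        i + 1 for i, (x, y) in enumerate(zip(a, b)) if x in UNAMBIGUOUS and y in UNAMBIGUOUS
    )
    if not kept:
        raise DegenerateDataError("no shared unambiguous site between the pair")
    return SiteMask(kept)


def count_pair(a: str, b: str, mask: SiteMask) -> PairCounts:
    """Tally transition and transversion proportions over masked columns."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    n = len(mask)
    if n == 0:
        raise DegenerateDataError("empty site mask")
    ts = tv = 0
    for col in mask.kept_columns:
        x, y = a[col - 1], b[col - 1]
        if x == y:
            continue
        if frozenset((x, y)) in TRANSITION_PAIRS:
            ts += 1
        else:
            tv += 1
    return PairCounts(n_sites=n, P=ts / n, Q=tv / n)


def k2p_distance(counts: PairCounts) -> float:
    """Evaluate the K2P closed form; exact 0 for identical sequences."""
    P, Q = counts.P, counts.Q
    if P == 0 and Q == 0:
        return 0.0
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined for P={P}, Q={Q}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def distance_matrix(alignment: Alignment, deletion: str = "complete") -> DistanceMatrix:
    """All-pairs K2P matrix.

    ``deletion`` is ``"complete"`` (one shared mask; the default) or
    ``"pairwise"`` (per-pair masks). Saturated pairs are flagged ``nan``
    rather than aborting the matrix.
    """
    if alignment.length < 1 or len(alignment.records) < 2:
        raise ValueError("need at least 2 sequences")
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    ids = tuple(alignment.sample_ids)
    seqs = alignment.sequences
    n = len(ids)
    d = np.zeros((n, n))
    shared_mask = complete_deletion_mask(alignment) if deletion == "complete" else None
    for i in range(n):
        for j in range(i + 1, n):
            try:
                mask = shared_mask if shared_mask is not None else pairwise_deletion_mask(seqs[i], seqs[j])
                dij = k2p_distance(count_pair(seqs[i], seqs[j], mask))
            except (SaturationError, DegenerateDataError):
                dij = math.nan
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids, d, shared_mask)
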
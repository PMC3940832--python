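"""Threshold grouping of samples and concordance with reference taxonomy.

Samples are grouped at a percent-divergence cut-off: under single linkage
(the default) any below-threshold pairwise distance chains two samples into
the same group, i.e. groups are the connected components of the graph with
an edge wherever d < t. Complete linkage (every within-group pair below t)
is offered for sensitivity analysis. Thresholds are strict: "<0.8%" means
d < 0.008 exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from moabarcode.distances import DistanceMatrix


class LinkageError(ValueError):
    """Undefined distances among the samples to be grouped."""


class LabelingError(ValueError):
    """A sample lacks a reference taxon label."""


@dataclass(frozen=True)
class Partition:
    """A grouping of samples at a divergence threshold.

    Groups are frozensets of sample ids; they are disjoint and cover every
    grouped sample. Groups are kept in a canonical order (by smallest member)
    so identical partitions compare equal.
    """

    threshold: float
    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        seen: set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError("groups overlap")
            seen |= g

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset().union(*self.groups) if self.groups else frozenset()

    def group_of(self, sample_id: str) -> frozenset[str]:
        for g in self.groups:
            if sample_id in g:
                return g
        raise KeyError(sample_id)

    def refines(self, other: "Partition") -> bool:
        """True if every group here is a subset of some group of *other*."""
        return all(any(g <= h for h in other.groups) for g in self.groups)

    def to_rows(self) -> list[tuple[str, int, float]]:
        """(sample_id, group_index, threshold) rows for report export."""
        rows = []
        for idx, g in enumerate(self.groups):
            for sid in sorted(g):
                rows.append((sid, idx, self.threshold))
        return rows


@dataclass(frozen=True)
class ConcordanceReport:
    """How a partition agrees with reference taxon labels.

    A taxon split across >= 2 groups is a false negative; a group containing
    >= 2 taxa is a false positive; a taxon is concordant when its members
    share one group and that group holds no other taxon.
    """

    false_negatives: int
    false_positives: int
    concordant_taxa: int


def _canonical_groups(members: list[list[str]]) -> tuple[frozenset[str], ...]:
    return tuple(sorted((frozenset(g) for g in members), key=lambda g: min(g)))


def group_at_threshold(
    D: DistanceMatrix,
    t: float,
    linkage_mode: str = "single",
    on_undefined: str = "error",
) -> Partition:
    """Partition samples at divergence threshold *t* (a fraction, e.g. 0.0125).

    ``on_undefined="error"`` raises naming the offending pairs;
    ``"exclude"`` drops any sample with an undefined distance, with a warning.
    """
    if not t > 0:
        raise ValueError("threshold must be > 0")
    ids = list(D.sample_ids)
    d = D.d.copy()
    bad = D.undefined_pairs()
    if bad:
        if on_undefined == "error":
            raise LinkageError(f"undefined distances for pairs: {bad}")
        drop = {s for pair in bad for s in pair}
        warnings.warn(f"excluding samples with undefined distances: {sorted(drop)}", stacklevel=2)
        keep = [i for i, s in enumerate(ids) if s not in drop]
        ids = [ids[i] for i in keep]
        d = d[np.ix_(keep, keep)]
    n = len(ids)
    if n == 0:
        return Partition(t, ())
    if n == 1:
        return Partition(t, (frozenset(ids),))
    if linkage_mode == "single":
        labels = connected_components(d < t, directed=False)[1]
    elif linkage_mode == "complete":
        # strict "<t": merge heights equal to t must NOT join, hence t - eps
        z = linkage(squareform(d, checks=False), method="complete")
        labels = fcluster(z, t * (1 - 1e-12), criterion="distance")
    else:
        raise ValueError(f"unknown linkage mode {linkage_mode!r}")
    members: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        members.setdefault(int(lab), []).append(sid)
    return Partition(t, _canonical_groups(list(members.values())))


def concordance(partition: Partition, taxon_labels: dict[str, str]) -> ConcordanceReport:
    """Compare a partition against reference taxon labels."""
    for sid in partition.sample_ids:
        if not taxon_labels.get(sid):
            raise LabelingError(f"sample {sid!r} has no taxon label")
    taxa = sorted({taxon_labels[s] for s in partition.sample_ids})
    fn = fp = concordant = 0
    group_taxa = [ {taxon_labels[s] for s in g} for g in partition.groups ]
    for g_taxa in group_taxa:
        if len(g_taxa) >= 2:
            fp += 1
    for taxon in taxa:
        occupied = [i for i, g in enumerate(partition.groups)
                    if any(taxon_labels[s] == taxon for s in g)]
        if len(occupied) >= 2:
            fn += 1
        elif len(occupied) == 1 and group_taxa[occupied[0]] == {taxon}:
            concordant += 1
    return ConcordanceReport(false_negatives=fn, false_positives=fp, concordant_taxa=concordant)


def intergroup_divergence(
    D: DistanceMatrix, set_a: set[str], set_b: set[str]
) -> tuple[float, float, float]:
    """(min, mean, max) divergence over all cross pairs of two disjoint sets."""
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("both sample sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"sample sets overlap: {sorted(set_a & set_b)}")
    ia = [D.sample_ids.index(s) for s in sorted(set_a)]
    ib = [D.sample_ids.index(s) for s in sorted(set_b)]
    cross = D.d[np.ix_(ia, ib)].ravel()
    if np.isnan(cross).any():
        raise LinkageError("undefined distances among cross pairs")
    return float(cross.min()), float(cross.mean()), float(cross.max())


def partition_table(partitions: list[Partition], path: str | Path) -> None:
    """Write per-threshold group membership as TSV."""
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup_index\tthreshold\n")
        for p in partitions:
            for sid, idx, t in p.to_rows():
                fh.write(f"{sid}\t{idx}\t{t}\n")


def concordance_table(
    partitions: list[Partition], taxon_labels: dict[str, str], path: str | Path
) -> None:
    """One concordance summary row per threshold, as TSV."""
    with open(path, "w") as fh:
        fh.write("threshold\tn_groups\tfalse_negatives\tfalse_positives\tconcordant_taxa\n")
        for p in partitions:
            r = concordance(p, taxon_labels)
            fh.write(
                f"{p.threshold}\t{len(p.groups)}\t{r.false_negatives}\t"
                f"{r.false_positives}\t{r.concordant_taxa}\n"
            )
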
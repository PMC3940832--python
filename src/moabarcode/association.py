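"""Eggshell/genotype association and morphometric classification.

The thickness association uses an exact one-sided sign test: under the null
that each of the k extreme eggshells carries the focal class independently
with probability 1/2, observing k_matching of k is scored by the binomial
tail P(X >= k_matching). When all k extremes match, p = 0.5^k — e.g. the
eight thinnest shells all thin-class gives p = 0.5^8 = 0.0039. A
hypergeometric alternative conditioning on the observed class frequencies
is provided as an option; it yields smaller p-values.

Bone measurements are compared to published subspecies leg-bone limits
(femur and tibiotarsus ranges in mm), with inclusive boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from scipy.stats import binom, hypergeom


class TieError(ValueError):
    """Thickness tie across the k-th selection boundary."""


class SizeError(ValueError):
    """k exceeds the number of usable samples."""


@dataclass(frozen=True)
class MorphLimits:
    """Published leg-bone length limits for a subspecies, in mm."""

    subspecies: str
    femur_range: tuple[float, float]
    tibiotarsus_range: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.femur_range, self.tibiotarsus_range):
            if not lo < hi:
                raise ValueError(f"range min must be < max, got ({lo}, {hi})")


#: Limits for the small North Island subspecies E. curtus curtus.
CURTUS_LIMITS = MorphLimits("E. curtus curtus", (150.0, 225.0), (240.0, 380.0))
#: Limits for the large subspecies E. curtus gravis.
GRAVIS_LIMITS = MorphLimits("E. curtus gravis", (215.0, 340.0), (405.0, 600.0))


@dataclass(frozen=True)
class SignTestResult:
    """Outcome of the extreme-eggshell sign test."""

    k: int
    k_matching: int
    p_value: float
    tail: str
    focal_class: str

    def __post_init__(self) -> None:
        if not 0 <= self.k_matching <= self.k:
            raise ValueError("k_matching out of range")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")


def extreme_class_sign_test(
    thickness: list[tuple[str, float]],
    classes: dict[str, str],
    k: int,
    tail: str = "thinnest",
    focal_class: str = "II",
    null: str = "sign",
) -> SignTestResult:
    """Exact test that the k extreme eggshells carry the focal class.

    Parameters
    ----------
    thickness
        (sample_id, thickness_mm) pairs.
    classes
        sample_id -> "I" or "II". Samples missing from this map are dropped.
    k
        How many extremes to examine.
    tail
        "thinnest" or "thickest".
    focal_class
        The class whose enrichment among the extremes is tested.
    null
        "sign" (default): each extreme matches with probability 1/2,
        p = P(Binomial(k, 1/2) >= k_matching).
        "hypergeometric": condition on the observed class counts,
        p = P(Hypergeom >= k_matching).

    A thickness tie spanning the k-th selection boundary is an error: which
    tied sample enters the extreme set changes p by a factor of two, so the
    caller must resolve it explicitly (e.g. exclude the doubtful record).
    """
    if tail not in ("thinnest", "thickest"):
        raise ValueError(f"tail must be 'thinnest' or 'thickest', got {tail!r}")
    if focal_class not in ("I", "II"):
        raise ValueError(f"focal_class must be 'I' or 'II', got {focal_class!r}")
    usable = [(sid, t) for sid, t in thickness if classes.get(sid) in ("I", "II")]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(usable):
        raise SizeError(f"k={k} but only {len(usable)} samples have thickness and class")
    usable.sort(key=lambda st: st[1], reverse=(tail == "thickest"))
    if k < len(usable) and usable[k - 1][1] == usable[k][1]:
        raise TieError(
            f"thickness tie at the selection boundary ({usable[k - 1][1]} mm): "
            "resolve explicitly by excluding or including the tied samples"
        )
    extremes = usable[:k]
    k_matching = sum(1 for sid, _ in extremes if classes[sid] == focal_class)
    if null == "sign":
        p = float(binom.sf(k_matching - 1, k, 0.5))
    elif null == "hypergeometric":
        n_focal = sum(1 for sid, _ in usable if classes[sid] == focal_class)
        p = float(hypergeom.sf(k_matching - 1, len(usable), n_focal, k))
    else:
        raise ValueError(f"unknown null {null!r}")
    return SignTestResult(k=k, k_matching=k_matching, p_value=p, tail=tail, focal_class=focal_class)


def _verdict(value: Optional[float], lo: float, hi: float) -> Optional[str]:
    if value is None:
        return None
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "within"


def classify_morphometrics(
    femur: Optional[float],
    tibiotarsus: Optional[float],
    limits: list[MorphLimits],
) -> dict[str, str]:
    """Compare available leg-bone measurements to each subspecies' limits.

    Returns a verdict per subspecies: "within" (all available measurements
    inside the range, boundaries inclusive), "below"/"above" (any
    measurement outside; "above" wins when measurements disagree in
    direction, since an oversize bone rules out the subspecies regardless),
    or "not_evaluable" when both measurements are missing.
    """
    out: dict[str, str] = {}
    for lim in limits:
        fv = _verdict(femur, *lim.femur_range)
        tv = _verdict(tibiotarsus, *lim.tibiotarsus_range)
        verdicts = [v for v in (fv, tv) if v is not None]
        if not verdicts:
            out[lim.subspecies] = "not_evaluable"
        elif all(v == "within" for v in verdicts):
            out[lim.subspecies] = "within"
        elif "above" in verdicts:
            out[lim.subspecies] = "above"
        else:
            out[lim.subspecies] = "below"
    return out


def write_association_report(results: list[SignTestResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tail\tfocal_class\tk\tk_matching\tp_value\n")
        for r in results:
            fh.write(f"{r.tail}\t{r.focal_class}\t{r.k}\t{r.k_matching}\t{r.p_value:.6g}\n")


def write_morphometric_report(
    rows: list[tuple[str, Optional[float], Optional[float]]],
    limits: list[MorphLimits],
    path: str | Path,
) -> None:
    """Per-sample, per-subspecies verdict table from (id, femur, tibiotarsus) rows."""
    with open(path, "w") as fh:
        fh.write("sample_id\tsubspecies\tverdict\n")
        for sid, femur, tbt in rows:
            for sub, verdict in classify_morphometrics(femur, tbt, limits).items():
                fh.write(f"{sid}\t{sub}\t{verdict}\n")
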
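"""Synthetic alignments and phenotypes with the structure the analysis assumes.

The generator emulates the empirical situation the pipeline was built for:
three geographic moa populations — Far North of the North Island, a central
group spanning both islands, and the far south of the South Island — whose
inter-population COI divergences straddle the 0.8/1.25/1.6% barcode
cut-offs; a handful of diagnostic sites fixed between populations; bimodal
eggshell thickness tied to a control-region genotype; and leg-bone lengths
drawn inside (or deliberately outside) published subspecies limits.

Sequences evolve down a fixed 3-population split ((FarNorth, Central),
FarSouth) under the two-parameter substitution model (transition rate kappa
times the transversion rate), using the exact per-site substitution
probabilities at each branch's expected divergence rather than
event-by-event simulation, so realized divergences are exactly calibrated
to the configured branch heights. Runs are byte-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from moabarcode.association import CURTUS_LIMITS, GRAVIS_LIMITS, MorphLimits
from moabarcode.seqio import (
    Alignment,
    COI_REF_START,
    CONTROL_REGION_REF_START,
    DEFAULT_REF_NAME,
    SampleMetadata,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

POPULATIONS = ("FarNorth", "Central", "FarSouth")

#: Default branch heights (expected substitutions/site) on the fixed split
#: ((FarNorth, Central), FarSouth). Chosen so the Far North / far south
#: divergence is ~2% (beyond the 1.6% cut-off), Far North / Central ~1.1%
#: (between the 0.8% and 1.25% cut-offs), and within-population divergence
#: ~0.3%.
DEFAULT_TREE_HEIGHTS = {
    "stem_far_north": 0.004,
    "stem_central": 0.004,
    "stem_internal": 0.005,  # root -> (FarNorth, Central) ancestor
    "stem_far_south": 0.008,
    "tip": 0.0015,  # population ancestor -> each sample
}

#: Diagnostic sites implanted by default: the four COI fixed differences
#: (Far North C>T at 7213; far south C>T/G>A/C>T at 7155/7278/7512) on the
#: COI fragment anchored at 6996.
DEFAULT_COI_IMPLANTS = (
    (7155, {"FarSouth": "T", "FarNorth": "C", "Central": "C"}),
    (7213, {"FarNorth": "T", "Central": "C", "FarSouth": "C"}),
    (7278, {"FarSouth": "A", "FarNorth": "G", "Central": "G"}),
    (7512, {"FarSouth": "T", "FarNorth": "C", "Central": "C"}),
)

#: The control-region C/T variant at reference position 557 separating the
#: class II (T, North Island thin-shell) haplotype from class I (C).
DEFAULT_CONTROL_REGION_IMPLANTS = (
    (557, {"FarNorth": "T", "Central": "C", "FarSouth": "C"}),
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for the alignment simulator.

    Defaults emulate the shape of the real COI dataset: 37 sequences (2 Far
    North, 29 central, 6 far south), a 624 bp fragment anchored at reference
    position 6996, kappa = 2, 2% missing cells.
    """

    n_per_population: tuple[int, ...] = (2, 29, 6)
    population_names: tuple[str, ...] = POPULATIONS
    tree_heights: dict = field(default_factory=lambda: dict(DEFAULT_TREE_HEIGHTS))
    kappa: float = 2.0
    seq_length: int = 624
    ref_start: int = COI_REF_START
    ref_name: str = DEFAULT_REF_NAME
    implant_snps: tuple = DEFAULT_COI_IMPLANTS
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_population) != len(self.population_names):
            raise ConfigError("n_per_population and population_names length mismatch")
        unknown = set(self.population_names) - set(POPULATIONS)
        if unknown:
            raise ConfigError(f"unknown populations {sorted(unknown)}; choose from {POPULATIONS}")
        if any(n < 1 for n in self.n_per_population):
            raise ConfigError("each population needs >= 1 sample")
        if any(h < 0 for h in self.tree_heights.values()):
            raise ConfigError("branch heights must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        hi = self.ref_start + self.seq_length - 1
        for pos, _ in self.implant_snps:
            if not self.ref_start <= pos <= hi:
                raise ConfigError(
                    f"implant position {pos} outside reference span {self.ref_start}..{hi}"
                )


def control_region_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config for the 27 bp control-region fragment (bases 554–580) carrying
    the 557 C/T variant."""
    defaults = dict(
        seq_length=27,
        ref_start=CONTROL_REGION_REF_START,
        implant_snps=DEFAULT_CONTROL_REGION_IMPLANTS,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass(frozen=True)
class PhenotypeConfig:
    """Parameters for eggshell thickness and leg-bone generation.

    Class means straddle the observed thin/thick split: class I (thick,
    large E. c. gravis birds) 1.15 mm, class II (thin, small E. c. curtus)
    0.90 mm, sd 0.10 mm. Bone lengths are uniform within the subspecies
    limits, with an optional fraction of outliers beyond them.
    """

    class_means: dict = field(default_factory=lambda: {"I": 1.15, "II": 0.90})
    class_sds: dict = field(default_factory=lambda: {"I": 0.10, "II": 0.10})
    morph_ranges: dict = field(
        default_factory=lambda: {"I": GRAVIS_LIMITS, "II": CURTUS_LIMITS}
    )
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.class_sds.values()):
            raise ConfigError("class sds must be > 0")
        if any(m <= 0 for m in self.class_means.values()):
            raise ConfigError("class means must be > 0")
        if not 0 <= self.outlier_fraction <= 1:
            raise ConfigError("outlier_fraction must be in [0, 1]")


def k2p_substitution_probs(d: float, kappa: float) -> tuple[float, float]:
    """Exact per-site (transition, per-transversion) probabilities after an
    expected divergence of *d* substitutions/site under the two-parameter
    model with transition/transversion rate ratio *kappa*.

    Closed form of the model's matrix exponential:
        p_transition   = 1/4 + 1/4 e^{-4d/(k+2)} - 1/2 e^{-2d(k+1)/(k+2)}
        p_transversion = 1/4 - 1/4 e^{-4d/(k+2)}   (each of the two targets)
    """
    if d < 0:
        raise ValueError("divergence must be >= 0")
    e1 = math.exp(-4 * d / (kappa + 2))
    e2 = math.exp(-2 * d * (kappa + 1) / (kappa + 2))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def expected_PQ(d: float, kappa: float) -> tuple[float, float]:
    """Expected observed transition (P) and transversion (Q) difference
    proportions between two sequences separated by path length *d*."""
    p_ts, p_tv = k2p_substitution_probs(d, kappa)
    return p_ts, 2 * p_tv


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer-coded sequence along a branch of height *d*."""
    if d == 0:
        return seq.copy()
    p_ts, p_tv = k2p_substitution_probs(d, kappa)
    u = rng.random(seq.shape[0])
    out = seq.copy()
    # fates: [0, p_ts) -> transition; [p_ts, p_ts+p_tv) -> transversion 1;
    # [p_ts+p_tv, p_ts+2p_tv) -> transversion 2; rest -> unchanged
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    # integer coding A=0,C=1,G=2,T=3: transition flips A<->G (xor 2) and
    # C<->T (xor 2); the two transversion targets are the two bases of the
    # other purine/pyrimidine class
    out[ts] ^= 2
    # transversion targets: for A(0)/G(2) -> C(1) or T(3); for C(1)/T(3) -> A(0) or G(2)
    is_purine = (seq % 2) == 0
    out[tv1] = np.where(is_purine[tv1], 1, 0)
    out[tv2] = np.where(is_purine[tv2], 3, 2)
    return out


def simulate_alignment(config: SimulationConfig) -> tuple[Alignment, dict[str, str]]:
    """Simulate an anchored alignment down the fixed 3-population split.

    Returns the alignment and a map sample_id -> population name. Implanted
    SNPs overwrite the simulated base in every member of the stated
    population; missingness (cells masked to N) is applied last.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    h = config.tree_heights
    kappa = config.kappa

    root = rng.integers(0, 4, size=L)
    internal = _evolve(root, h.get("stem_internal", 0.0), kappa, rng)
    pop_anc = {
        "FarNorth": _evolve(internal, h.get("stem_far_north", 0.0), kappa, rng),
        "Central": _evolve(internal, h.get("stem_central", 0.0), kappa, rng),
        "FarSouth": _evolve(root, h.get("stem_far_south", 0.0), kappa, rng),
    }

    records: list[tuple[str, str]] = []
    assignment: dict[str, str] = {}
    tip_h = h.get("tip", 0.0)
    for pop_name, n in zip(config.population_names, config.n_per_population):
        anc = pop_anc[pop_name]
        for i in range(n):
            tip = _evolve(anc, tip_h, kappa, rng)
            chars = list("".join(BASES[b] for b in tip))
            sid = f"{pop_name}_{i + 1:02d}"
            records.append((sid, chars))
            assignment[sid] = pop_name

    # implant diagnostic sites
    for pos, alleles in config.implant_snps:
        col = pos - config.ref_start  # 0-based
        for sid, chars in records:
            pop = assignment[sid]
            if pop in alleles:
                chars[col] = alleles[pop]

    # missingness last, so it can also hit implanted sites
    final: list[tuple[str, str]] = []
    for sid, chars in records:
        if config.missing_rate > 0:
            miss = rng.random(L) < config.missing_rate
            chars = ["N" if m else c for c, m in zip(chars, miss)]
        final.append((sid, "".join(chars)))

    aln = Alignment(tuple(final), ref_start=config.ref_start, ref_name=config.ref_name)
    return aln, assignment


def simulate_phenotypes(
    assignments: dict[str, str],
    config: PhenotypeConfig,
    islands: Optional[dict[str, str]] = None,
) -> list[SampleMetadata]:
    """Draw eggshell thicknesses and leg-bone lengths per eggshell class.

    ``assignments`` maps sample_id -> eggshell class ("I" or "II").
    Thickness ~ Normal(class mean, class sd) truncated at 0; femur and
    tibiotarsus are uniform within the class's subspecies limits, except a
    configurable fraction of outliers drawn just outside them.
    """
    rng = np.random.default_rng(config.seed)
    out: list[SampleMetadata] = []
    for sid in assignments:
        cls = assignments[sid]
        if cls not in config.class_means:
            raise ConfigError(f"unknown eggshell class {cls!r} for sample {sid!r}")
        mean, sd = config.class_means[cls], config.class_sds[cls]
        thick = rng.normal(mean, sd)
        while thick <= 0:
            thick = rng.normal(mean, sd)
        lim: MorphLimits = config.morph_ranges[cls]
        is_outlier = rng.random() < config.outlier_fraction
        if is_outlier:
            # outliers overshoot the upper limit by up to 25% of the range
            f_lo, f_hi = lim.femur_range
            t_lo, t_hi = lim.tibiotarsus_range
            femur = f_hi + rng.uniform(0, 0.25) * (f_hi - f_lo)
            tbt = t_hi + rng.uniform(0, 0.25) * (t_hi - t_lo)
        else:
            femur = rng.uniform(*lim.femur_range)
            tbt = rng.uniform(*lim.tibiotarsus_range)
        out.append(
            SampleMetadata(
                sample_id=sid,
                island=(islands or {}).get(sid, "unknown"),
                eggshell_thickness=float(thick),
                femur_length=float(femur),
                tibiotarsus_length=float(tbt),
                eggshell_class=cls,
            )
        )
    return out


def symmetric_population_config(
    intra: float = 0.003,
    inter: float = 0.02,
    n: int = 6,
    populations: tuple[str, ...] = POPULATIONS,
    seq_length: int = 624,
    missing_rate: float = 0.0,
    implant_snps: tuple = (),
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Config in which every inter-population divergence equals *inter* and
    within-population divergence equals *intra* (both expected
    substitutions/site between a pair of samples).

    Achieved with a star-like split: tip height intra/2, each population
    stem (inter - intra)/2, and a zero-length internal branch.
    """
    if not 0 <= intra <= inter:
        raise ConfigError("need 0 <= intra <= inter")
    tip = intra / 2
    stem = (inter - intra) / 2
    heights = {
        "stem_far_north": stem,
        "stem_central": stem,
        "stem_internal": 0.0,
        "stem_far_south": stem,
        "tip": tip,
    }
    return SimulationConfig(
        n_per_population=(n,) * len(populations),
        population_names=populations,
        tree_heights=heights,
        seq_length=seq_length,
        missing_rate=missing_rate,
        implant_snps=implant_snps,
        seed=seed,
        **overrides,
    )


def implant_only_config(
    implant_snps: tuple,
    n_per_population: tuple[int, ...] = (6, 25, 6),
    missing_rate: float = 0.02,
    seq_length: int = 624,
    ref_start: int = COI_REF_START,
    seed: int = 0,
) -> SimulationConfig:
    """Config with all branch heights zero: the implanted sites are the only
    differences between samples (plus missingness). Used to verify that a
    diagnostic-SNP scan recovers exactly the implanted positions."""
    heights = {k: 0.0 for k in DEFAULT_TREE_HEIGHTS}
    return SimulationConfig(
        n_per_population=n_per_population,
        tree_heights=heights,
        seq_length=seq_length,
        ref_start=ref_start,
        implant_snps=implant_snps,
        missing_rate=missing_rate,
        seed=seed,
    )


def sprinkle_missing_columns(alignment: Alignment, n_columns: int, seed: int = 0) -> Alignment:
    """Return a copy with one random sample masked to N in each of
    *n_columns* distinct randomly chosen columns (so complete deletion
    removes exactly those columns from an otherwise clean alignment)."""
    rng = np.random.default_rng(seed)
    L = alignment.length
    if n_columns > L:
        raise ConfigError("n_columns exceeds alignment length")
    cols = rng.choice(L, size=n_columns, replace=False)
    rows = [list(seq) for _, seq in alignment.records]
    for c in cols:
        rows[int(rng.integers(0, len(rows)))][c] = "N"
    records = tuple(
        (sid, "".join(chars)) for (sid, _), chars in zip(alignment.records, rows)
    )
    return Alignment(records, alignment.ref_start, alignment.ref_name)


def eggshell_study_fixture(
    seed: int = 0,
    n_thin: int = 8,
    n_thick: int = 27,
) -> tuple[list[tuple[str, float]], dict[str, str]]:
    """Thickness records echoing the eggshell study design: the *n_thin*
    thinnest shells all class II and the *n_thick* thickest all class I.

    Thicknesses are drawn from the class distributions and then separated
    at the midpoint so the class split is exact and tie-free; returns
    (thickness list, class map) ready for the sign test.
    """
    rng = np.random.default_rng(seed)
    thin = sorted(rng.normal(0.90, 0.07, size=n_thin))
    thick = sorted(rng.normal(1.15, 0.07, size=n_thick))
    shift = max(0.0, thin[-1] - thick[0] + 0.01)  # guarantee strict separation
    thickness: list[tuple[str, float]] = []
    classes: dict[str, str] = {}
    for i, t in enumerate(thin):
        sid = f"thin_{i + 1:02d}"
        thickness.append((sid, float(t)))
        classes[sid] = "II"
    for i, t in enumerate(thick):
        sid = f"thick_{i + 1:02d}"
        thickness.append((sid, float(t + shift)))
        classes[sid] = "I"
    return thickness, classes
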
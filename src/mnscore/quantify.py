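"""Frequency readouts, QC gating, subsampling CV and tumor-volume utilities.

The central readouts are percentages of micronucleus-positive cells within
the evaluable red-cell population:

    MN+RBCs (%) = 100 * N(MN+RBC) / (N(MN-RBC) + N(MN+RBC))

and the analogous MN+NCE / MN+RET percentages within each subpopulation.
White cells, platelets and debris never enter a denominator.  A sample with
fewer than 10,000 evaluable RBCs fails QC and its frequencies are withheld.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedFrequencyError

QC_PASS = "pass"
QC_EXCLUDED_LOW_COUNT = "excluded_low_count"
MIN_EVALUABLE_RBC = 10_000

#: labels excluded from every RBC denominator
NON_RBC_LABELS = frozenset({"WBC", "PLATELET", "DEBRIS"})


@dataclass
class SampleCounts:
    """Per-class tallies for one sample."""

    counts: dict[str, int] = dc_field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.counts.items():
            if v < 0:
                raise ConfigError(f"negative tally for {k}")

    def get(self, label: str) -> int:
        return int(self.counts.get(label, 0))

    @property
    def evaluable_rbc(self) -> int:
        """All cells except WBCs, platelets and debris."""
        return sum(int(v) for k, v in self.counts.items()
                   if k not in NON_RBC_LABELS)

    @classmethod
    def from_records(cls, records) -> "SampleCounts":
        labels = [r.label.label for r in records]
        tally: dict[str, int] = {}
        for lab in labels:
            tally[lab] = tally.get(lab, 0) + 1
        return cls(counts=tally)


@dataclass
class FrequencyResult:
    numerator: int
    denominator: int
    value_percent: float
    population: str
    qc_status: str = QC_PASS


@dataclass
class SubsampleCurve:
    """CV of the MN+ frequency as a function of cells subsampled."""

    points: list[tuple[int, float, int]]   # (n_cells, cv_percent, n_replicates)
    mode: str
    seed: int

    @property
    def n_values(self) -> list[int]:
        return [p[0] for p in self.points]

    @property
    def cv_values(self) -> list[float]:
        return [p[1] for p in self.points]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points,
                            columns=["n_cells", "cv_percent", "n_replicates"])


def frequency(pos: int, neg: int, population: str) -> FrequencyResult:
    """Percentage of positives among ``pos + neg`` cells."""
    if pos < 0 or neg < 0:
        raise ConfigError("counts must be >= 0")
    if pos + neg == 0:
        raise UndefinedFrequencyError(
            f"{population}: frequency undefined with zero denominator")
    return FrequencyResult(
        numerator=pos, denominator=pos + neg,
        value_percent=100.0 * pos / (pos + neg),
        population=population)


def qc_evaluable(counts: SampleCounts,
                 min_rbc: int = MIN_EVALUABLE_RBC) -> str:
    """QC gate: at least ``min_rbc`` evaluable RBCs, else the sample is
    excluded and not reported."""
    return QC_PASS if counts.evaluable_rbc >= min_rbc else QC_EXCLUDED_LOW_COUNT


def multi_mn_frequency(records) -> FrequencyResult:
    """Fraction of evaluable RBCs carrying two or more micronuclear foci."""
    rbc = [r for r in records if r.label.label not in NON_RBC_LABELS]
    if not rbc:
        raise UndefinedFrequencyError("no evaluable RBCs for multi-MN frequency")
    multi = sum(1 for r in rbc if r.mn_count >= 2)
    return FrequencyResult(numerator=multi, denominator=len(rbc),
                           value_percent=100.0 * multi / len(rbc),
                           population="multi-MN")


def subsample_cv(mn_positive: np.ndarray, n_values: list[int],
                 n_replicates: int = 100, mode: str = "without_replacement",
                 seed: int = 0) -> SubsampleCurve:
    """Subsampling precision analysis of the MN+ frequency.

    ``mn_positive`` is a boolean (or 0/1) array over the evaluable RBCs of
    one sample.  For each ``n`` the MN+ percentage is recomputed on
    ``n_replicates`` random subsamples and its coefficient of variation
    (100·sd/mean, sample sd) reported.  A draw population whose subsample
    means are all zero yields ``cv = nan`` (undefined, flagged by NaN).
    """
    flags = np.asarray(mn_positive).astype(bool)
    n_total = len(flags)
    if sorted(n_values) != list(n_values) or len(set(n_values)) != len(n_values):
        raise ConfigError("n_values must be strictly increasing")
    if mode not in ("with_replacement", "without_replacement"):
        raise ConfigError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    points = []
    for n in n_values:
        if mode == "without_replacement" and n > n_total:
            raise ConfigError(
                f"cannot draw {n} of {n_total} cells without replacement")
        freqs = np.empty(n_replicates)
        for j in range(n_replicates):
            if mode == "with_replacement":
                idx = rng.integers(0, n_total, size=n)
            else:
                idx = rng.choice(n_total, size=n, replace=False)
            freqs[j] = flags[idx].mean()
        mean = freqs.mean()
        if mean == 0:
            cv = float("nan")
        else:
            cv = 100.0 * freqs.std(ddof=1) / mean
        points.append((int(n), float(cv), int(n_replicates)))
    return SubsampleCurve(points=points, mode=mode, seed=seed)


def binomial_cv_percent(p: float, n: int) -> float:
    """Closed-form CV (%) of a binomial proportion: 100·sqrt((1-p)/(n·p))."""
    if not (0 < p <= 1) or n <= 0:
        raise ConfigError("need 0 < p <= 1 and n > 0")
    return 100.0 * math.sqrt((1.0 - p) / (n * p))


def fold_change(treated_freq: float, control_freq: float) -> float:
    """Ratio of treated to control frequency (both on the percent scale)."""
    if control_freq <= 0:
        raise UndefinedFrequencyError("fold change undefined for zero control")
    return treated_freq / control_freq


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume: length × width² × π/6 (mm³).

    Length is the longest diameter; if the arguments arrive swapped they
    are reordered (with a warning) rather than rejected.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ConfigError("tumor dimensions must be positive")
    if width_mm > length_mm:
        import warnings
        warnings.warn("width > length; swapping so length is the longest "
                      "diameter", stacklevel=2)
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 * math.pi / 6.0


def relative_tumor_volume(tv_day_x: float, tv_day_0: float) -> float:
    """RTV: volume at day x over volume at randomisation."""
    if tv_day_0 <= 0:
        raise ConfigError("baseline tumor volume must be > 0")
    return tv_day_x / tv_day_0
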
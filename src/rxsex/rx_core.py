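"""The sex-ratio statistic: per-autosome ratios, CI, call, coverage check.

For each autosome ``i`` with mapped count ``m_i`` and length ``L_i`` and the
shared sex chromosome with ``m_X`` and ``L_X``, the ratio term is

    r_i = (m_X / L_X) / (m_i / L_i)

i.e. the length-normalized depth of the sex chromosome relative to each
autosome. The statistic is the mean of the ``r_i``; its standard error is
the sample standard deviation over autosomes divided by sqrt(n). With two
copies of the sex chromosome the expectation is 1.0, with one copy 0.5.
This direct form is algebraically identical to normalizing both numerator
and denominator by any common read and length totals, since those cancel.

A sample is called heterogametic (XY male / ZW female) when the CI upper
bound falls strictly below the lower threshold (default 0.60), homogametic
(XX female / ZZ male) when the CI lower bound is strictly above the upper
threshold (default 0.80), and unassigned otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from rxsex.errors import ConfigurationError, InsufficientDataError
from rxsex.karyo_io import JoinedCounts, Role

logger = logging.getLogger(__name__)


class Call(str, Enum):
    """Classification outcome in copy-number terms."""

    HOMOGAMETIC = "homogametic"  # two copies of the shared sex chromosome
    HETEROGAMETIC = "heterogametic"  # one copy
    UNASSIGNED = "unassigned"


#: Sex labels by system: (heterogametic label, homogametic label).
_LABELS = {"XY": ("male", "female"), "ZW": ("female", "male")}


@dataclass(frozen=True)
class ClassifierConfig:
    """CI multiplier and decision thresholds.

    Defaults: z = 1.96 (95% CI), call heterogametic below 0.60 and
    homogametic above 0.80, with strict inequalities.
    """

    z: float = 1.96
    lower_threshold: float = 0.60
    upper_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ConfigurationError(f"z must be positive, got {self.z}")
        if not (0 < self.lower_threshold < self.upper_threshold):
            raise ConfigurationError(
                "thresholds must satisfy 0 < lower < upper, got "
                f"{self.lower_threshold} and {self.upper_threshold}"
            )


@dataclass(frozen=True)
class RxResult:
    """The statistic for one sample: ratios, mean, CI and call."""

    sample_id: str
    ratios: tuple[float, ...]
    rx: float
    se: float
    ci_low: float
    ci_high: float
    n_autosomes: int
    call: Call
    call_label: str
    dropped_autosomes: tuple[str, ...] = ()

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


@dataclass(frozen=True)
class CoverageCheck:
    """Result of the coverage-sufficiency regression (counts vs. length)."""

    slope: float
    intercept: float
    f_stat: float
    p_value: float
    sufficient: bool
    alpha: float = 0.001


def autosome_ratios(joined: JoinedCounts) -> list[float]:
    """Per-autosome ratio terms r_i = (m_X/L_X) / (m_i/L_i).

    Autosomes with zero mapped reads are dropped (callers can recover their
    names via :func:`dropped_autosome_names`). Raises
    :class:`InsufficientDataError` when the sex chromosome has no reads or
    fewer than two autosomes are usable.
    """
    x = joined.shared_sex_record
    if x.mapped <= 0:
        raise InsufficientDataError(
            f"sample {joined.sample_id!r}: no reads on shared sex chromosome {x.name}"
        )
    x_depth = x.mapped / x.length
    ratios = [
        x_depth / (a.mapped / a.length)
        for a in joined.autosome_records
        if a.mapped > 0
    ]
    if len(ratios) < 2:
        raise InsufficientDataError(
            f"sample {joined.sample_id!r}: only {len(ratios)} autosomes with reads; "
            "need at least 2"
        )
    return ratios


def dropped_autosome_names(joined: JoinedCounts) -> tuple[str, ...]:
    """Names of autosomes excluded from the ratio for having zero reads."""
    return tuple(a.name for a in joined.autosome_records if a.mapped <= 0)


def classify(
    ci_low: float,
    ci_high: float,
    system: str = "XY",
    config: ClassifierConfig | None = None,
) -> tuple[Call, str]:
    """Classify a confidence interval into a call and a sex label.

    Strict inequalities: an interval whose upper bound equals the lower
    threshold (or lower bound equals the upper threshold) stays unassigned.
    """
    if config is None:
        config = ClassifierConfig()
    if ci_low > ci_high:
        raise ValueError(f"ci_low {ci_low} > ci_high {ci_high}")
    if system not in _LABELS:
        raise ConfigurationError(f"system must be 'XY' or 'ZW', got {system!r}")
    hetero_label, homo_label = _LABELS[system]
    if ci_high < config.lower_threshold:
        return Call.HETEROGAMETIC, hetero_label
    if ci_low > config.upper_threshold:
        return Call.HOMOGAMETIC, homo_label
    return Call.UNASSIGNED, "unassigned"


def compute_rx(
    joined: JoinedCounts, config: ClassifierConfig | None = None
) -> RxResult:
    """Compute the statistic, its CI and the sex call for one sample.

    rx is the mean of the per-autosome ratios; SE is the sample (n-1)
    standard deviation of the ratios divided by sqrt(n); the CI is
    rx +/- z*SE.
    """
    if config is None:
        config = ClassifierConfig()
    ratios = autosome_ratios(joined)
    dropped = dropped_autosome_names(joined)
    if dropped:
        logger.warning(
            "sample %r: autosomes with zero reads dropped: %s",
            joined.sample_id, ", ".join(dropped),
        )
    arr = np.asarray(ratios, dtype=float)
    n = arr.size
    rx = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n))
    ci_low = rx - config.z * se
    ci_high = rx + config.z * se
    call, label = classify(ci_low, ci_high, joined.system, config)
    return RxResult(
        sample_id=joined.sample_id,
        ratios=tuple(float(r) for r in ratios),
        rx=rx,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_autosomes=n,
        call=call,
        call_label=label,
        dropped_autosomes=dropped,
    )


def coverage_regression(joined: JoinedCounts, alpha: float = 0.001) -> CoverageCheck:
    """Check coverage adequacy by regressing mapped counts on length.

    Ordinary least squares of per-autosome mapped read count against
    chromosome length (autosomes only, so sex-chromosome dosage cannot
    confound the check). The regression F statistic (the squared slope
    t statistic of the simple regression) and its p-value decide
    sufficiency: coverage is deemed sufficient when p < alpha.
    """
    autosomes = joined.autosome_records
    if len(autosomes) < 3:
        raise InsufficientDataError(
            f"sample {joined.sample_id!r}: insufficient chromosomes for regression "
            f"({len(autosomes)} < 3)"
        )
    lengths = np.array([a.length for a in autosomes], dtype=float)
    counts = np.array([a.mapped for a in autosomes], dtype=float)
    res = stats.linregress(lengths, counts)
    r2 = res.rvalue**2
    dof = len(autosomes) - 2
    if not math.isfinite(r2) or r2 == 0.0:  # constant counts: no relationship
        f_stat, p_value = 0.0, 1.0
    elif math.isclose(r2, 1.0):
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = r2 / (1 - r2) * dof
        p_value = float(stats.f.sf(f_stat, 1, dof))
    return CoverageCheck(
        slope=float(res.slope),
        intercept=float(res.intercept),
        f_stat=float(f_stat),
        p_value=float(p_value),
        sufficient=bool(p_value < alpha),
        alpha=alpha,
    )
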
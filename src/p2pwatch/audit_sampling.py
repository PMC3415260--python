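"""Binomial audit sampling of discarded files.

A scan discards most of a harvest as non-PHI; its false-negative rate is
bounded by manually reviewing random samples of the discarded files. With a
binomial model — each file independently contains PHI with probability θ —
the probability of seeing at least one PHI file in a sample of n is

    P = 1 − (1 − θ)^n                      (detection probability)

so the smallest sample that reaches a target detection probability P is

    n = ⌈ln(1 − P) / ln(1 − θ)⌉.           (sample size)

At θ = 1% and P = 95% this gives n = 299 (≈298.07 before rounding); audits
commonly round up to a convenient 300. Samples are drawn independently from
strata of discarded files; the default strata group the discard stages as
(1) title filter + text extractor + language identifier, (2) content
filter, (3) PII detector + health detector.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from p2pwatch.pipeline import ScanReport

__all__ = [
    "DEFAULT_STRATA",
    "SamplingPlan",
    "detection_probability",
    "sample_size",
    "default_strata",
    "draw_stratified_sample",
]

#: Stratum label -> discard stages it covers.
DEFAULT_STRATA: dict[str, tuple[str, ...]] = {
    "group1_shallow": ("title_filter", "text_extractor", "language_id"),
    "group2_content": ("content_filter",),
    "group3_deep": ("pii_detector", "health_detector"),
}


def detection_probability(n: int, theta: float) -> float:
    """Probability of detecting at least one PHI file in ``n`` independent
    draws when the underlying PHI rate is ``theta``: ``1 − (1−θ)^n``."""
    if not 0 <= theta < 1:
        raise ValueError(f"theta must be in [0, 1), got {theta}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return 1.0 - (1.0 - theta) ** n


def sample_size(theta: float, power: float, round_up_to: int | None = None) -> int:
    """Smallest integer n with ``detection_probability(n, theta) >= power``.

    ``round_up_to`` optionally rounds the result up to a convenient figure
    (e.g. 300 where the exact answer is 299); by default the exact minimal
    n is returned. Boundary values of theta or power are domain errors.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    if not 0 < power < 1:
        raise ValueError(f"power must be in (0, 1), got {power}")
    n = math.ceil(math.log(1.0 - power) / math.log(1.0 - theta))
    # guard the ceiling against floating-point edge cases
    while detection_probability(n, theta) < power:
        n += 1
    while n > 1 and detection_probability(n - 1, theta) >= power:
        n -= 1
    if round_up_to is not None and n < round_up_to:
        n = round_up_to
    return n


@dataclass
class SamplingPlan:
    """Stratified sampling plan for a false-negative audit.

    ``per_stratum_n`` defaults to ``sample_size(theta, power)``; a stratum
    smaller than that is sampled exhaustively.
    """

    theta: float
    power: float
    strata: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STRATA)
    )
    per_stratum_n: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_stratum_n is None:
            self.per_stratum_n = sample_size(self.theta, self.power)
        if self.per_stratum_n < 1:
            raise ValueError("per_stratum_n must be >= 1")


def default_strata(report: ScanReport) -> dict[str, list[str]]:
    """Discarded file paths per default stratum, in sorted order."""
    return {
        label: sorted(
            p
            for stage in stages
            for p in report.discarded_by_stage(stage)
        )
        for label, stages in DEFAULT_STRATA.items()
    }


def draw_stratified_sample(
    report: ScanReport, plan: SamplingPlan
) -> dict[str, list[str]]:
    """Draw a reproducible uniform sample without replacement per stratum.

    Each stratum collects the files discarded by its stages; a stratum with
    at most ``per_stratum_n`` files is returned whole. Sampling is seeded
    from ``plan.seed`` and output paths are sorted, so the same report,
    plan and seed always give the same manifest. A stratum stage absent
    from the report's stage counts is an error naming the label.
    """
    known_stages = set(report.stage_counts)
    out: dict[str, list[str]] = {}
    rng = random.Random(plan.seed)
    for label, stages in plan.strata.items():
        missing = [s for s in stages if s not in known_stages]
        if missing:
            raise ValueError(
                f"stratum {label!r} references unknown stages {missing}"
            )
        pool = sorted(
            p for stage in stages for p in report.discarded_by_stage(stage)
        )
        if len(pool) <= plan.per_stratum_n:
            out[label] = pool
        else:
            out[label] = sorted(rng.sample(pool, plan.per_stratum_n))
    return out
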
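"""Per-subject dementia-probability staging and cognitive-slope contrasts.

The Stage-4 bootstrap leaves a per-subject tally: how many times each
test-cohort subject was drawn into a replicate and how many of those
times the frozen model labeled it mild AD. The dementia probability
P(AD) is the ratio of the two — 1.0 for a subject always classified AD,
0.0 for one always classified MCI. Subjects split into two strata at
50 %, with the boundary on the dementia side (P(AD) >= 0.5 is "likely
mild dementia").

The strata are then contrasted on longitudinal cognition, per domain
(executive or memory), in one of two modes: LEVEL compares per-subject
mean Z scores (a severity contrast), SLOPE compares per-subject
least-squares slopes in Z per month (a progression-rate contrast). Both
use an unequal-variance (Welch) two-sample t comparison with a
two-sided 95 % confidence interval. The estimate is oriented as
(likely-MCI group) minus (likely-dementia group), so a positive value
means the likely-MCI stratum scores higher (less impaired / slower
decline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .cohort import Cohort, SubjectRecord
from .core import BootstrapValidationResult
from .exceptions import InsufficientDataError

logger = logging.getLogger(__name__)


class Stratum(str, Enum):
    LIKELY_MCI = "LIKELY_MCI"            # P(AD) < 0.5
    LIKELY_DEMENTIA = "LIKELY_DEMENTIA"  # P(AD) >= 0.5


class Domain(str, Enum):
    EXECUTIVE = "EXECUTIVE"
    MEMORY = "MEMORY"


class ComparisonType(str, Enum):
    LEVEL = "LEVEL"  # per-subject mean Z
    SLOPE = "SLOPE"  # per-subject least-squares Z/month


@dataclass(frozen=True)
class PadScore:
    subject_id: str
    times_sampled: int
    times_labeled_ad: int

    @property
    def pad(self) -> float:
        if self.times_sampled == 0:
            raise ZeroDivisionError(
                f"subject {self.subject_id!r}: never sampled, P(AD) undefined"
            )
        return self.times_labeled_ad / self.times_sampled

    @property
    def stratum(self) -> Stratum:
        return Stratum.LIKELY_DEMENTIA if self.pad >= 0.5 else Stratum.LIKELY_MCI


@dataclass(frozen=True)
class SlopeComparison:
    domain: Domain
    comparison: ComparisonType
    estimate: float            # likely-MCI minus likely-dementia
    ci_low: float
    ci_high: float
    p_value: float
    n_likely_mci: int
    n_likely_dementia: int


def compute_pad(result: BootstrapValidationResult) -> list[PadScore]:
    """One P(AD) score per test-cohort subject sampled at least once.

    Subjects never drawn into any replicate have no defined P(AD); they
    are flagged in the log and excluded from the returned list (and
    hence from both strata).
    """
    scores = []
    skipped = []
    for sid, sampled, labeled in zip(
        result.subject_ids, result.times_sampled, result.times_labeled_ad
    ):
        if sampled == 0:
            skipped.append(sid)
            continue
        scores.append(PadScore(subject_id=sid, times_sampled=int(sampled),
                               times_labeled_ad=int(labeled)))
    if skipped:
        logger.warning(
            "compute_pad: %d subject(s) never sampled, excluded from strata: %s",
            len(skipped), skipped,
        )
    return scores


def _domain_values(visit, domain: Domain):
    return visit.executive_z if domain is Domain.EXECUTIVE else visit.memory_z


def _subject_summary(subject: SubjectRecord, domain: Domain,
                     comparison: ComparisonType) -> float | None:
    """Per-subject longitudinal summary, or None if data are insufficient."""
    points = [
        (v.months_from_baseline, _domain_values(v, domain))
        for v in subject.visits
        if _domain_values(v, domain) is not None
    ]
    if comparison is ComparisonType.LEVEL:
        if not points:
            return None
        return float(np.mean([z for _, z in points]))
    if len(points) < 2:
        return None
    months = np.array([m for m, _ in points])
    z = np.array([z for _, z in points])
    slope, _ = np.polyfit(months, z, 1)
    return float(slope)


def compare_groups(
    cohort: Cohort,
    pad_scores: list[PadScore],
    domain: Domain | str = Domain.EXECUTIVE,
    comparison: ComparisonType | str = ComparisonType.SLOPE,
) -> SlopeComparison:
    """Welch contrast of longitudinal cognition between P(AD) strata.

    LEVEL mode needs >= 2 subjects with >= 1 scored visit per stratum;
    SLOPE mode needs >= 2 subjects with >= 2 scored visits per stratum
    (a single-visit subject cannot define a slope and is excluded with a
    log entry).
    """
    domain = Domain(domain)
    comparison = ComparisonType(comparison)
    by_id = {s.subject_id: s for s in cohort.subjects}

    samples: dict[Stratum, list[float]] = {Stratum.LIKELY_MCI: [], Stratum.LIKELY_DEMENTIA: []}
    for score in pad_scores:
        subject = by_id.get(score.subject_id)
        if subject is None:
            continue
        summary = _subject_summary(subject, domain, comparison)
        if summary is None:
            logger.info(
                "compare_groups: subject %r excluded (insufficient %s data for %s)",
                score.subject_id, domain.value, comparison.value,
            )
            continue
        samples[score.stratum].append(summary)

    for stratum, values in samples.items():
        if len(values) < 2:
            raise InsufficientDataError(
                f"stratum {stratum.value}: need >= 2 subjects with sufficient "
                f"{domain.value.lower()} visits for a {comparison.value} comparison, "
                f"got {len(values)}"
            )

    low = np.asarray(samples[Stratum.LIKELY_MCI])
    high = np.asarray(samples[Stratum.LIKELY_DEMENTIA])
    result = stats.ttest_ind(low, high, equal_var=False)
    ci = result.confidence_interval(confidence_level=0.95)
    return SlopeComparison(
        domain=domain,
        comparison=comparison,
        estimate=float(np.mean(low) - np.mean(high)),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(result.pvalue),
        n_likely_mci=low.size,
        n_likely_dementia=high.size,
    )


def pad_table(pad_scores: list[PadScore]):
    """P(AD) scores as a DataFrame ready for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "times_sampled": s.times_sampled,
                "times_labeled_ad": s.times_labeled_ad,
                "pad": s.pad,
                "stratum": s.stratum.value,
            }
            for s in pad_scores
        ]
    )
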
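"""SST verdict logic: threshold criterion, bias-randomness criterion, and
the 2/3/5-replicate protocol.

A system suitability check consists of replicate injections of the
reference panel in one polarity, acquired either before (PRE) or after
(POST) a sample batch.  The instrument is suitable when every measured
mass error stays within the ppm threshold AND the per-compound mean
errors show no systematic sign bias.  With only two replicates, an
adaptive rule decides whether a third injection is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "InjectionResult",
    "CompoundSummary",
    "BiasCheck",
    "SSTVerdict",
    "Recommendation",
    "summarize_replicates",
    "check_threshold",
    "check_bias",
    "adaptive_protocol",
    "evaluate_sst",
]


class Recommendation(str, Enum):
    PROCEED = "PROCEED"
    THIRD_INJECTION = "THIRD_INJECTION"
    RECALIBRATE = "RECALIBRATE"


@dataclass(frozen=True)
class InjectionResult:
    """Per-injection vector of compound ppm errors.

    ``errors`` maps compound name to signed ppm error; a compound absent
    from the map was not detected in this injection.
    """

    injection_id: str
    polarity: str
    phase: str  # PRE | POST
    errors: Mapping[str, float]
    timestamp: datetime | None = None


@dataclass(frozen=True)
class CompoundSummary:
    compound_name: str
    n: int
    n_missing: int
    mean_error: float | None
    sd_error: float | None  # sample sd (n-1); None when n < 2


@dataclass(frozen=True)
class BiasCheck:
    """Exact two-sided sign-test result on per-compound mean error signs."""

    flagged: bool
    sign: int  # +1 / -1 for the dominant sign, 0 when balanced or inconclusive
    p_value: float | None
    n_used: int
    conclusive: bool


@dataclass(frozen=True)
class SSTVerdict:
    polarity: str
    phase: str
    passed: bool
    failed_compounds: tuple[str, ...]
    missing_compounds: tuple[str, ...]
    bias: BiasCheck
    recommendation: Recommendation
    summaries: tuple[CompoundSummary, ...]
    n_replicates: int


def _check_homogeneous(results: Sequence[InjectionResult]) -> tuple[str, str]:
    if not results:
        raise ValueError("at least one injection result is required")
    polarities = {r.polarity for r in results}
    phases = {r.phase for r in results}
    if len(polarities) > 1 or len(phases) > 1:
        raise ValueError(
            f"mixed polarity/phase in replicate set: {sorted(polarities)}, {sorted(phases)}"
        )
    return results[0].polarity, results[0].phase


def summarize_replicates(
    results: Sequence[InjectionResult],
    compounds: Iterable[str] | None = None,
) -> list[CompoundSummary]:
    """Per-compound mean and sample standard deviation over detected
    replicates; sorted by compound name for a stable output order.

    ``compounds`` extends the summarized set beyond the observed names,
    so compounds undetected in every replicate still get an n=0 row."""
    _check_homogeneous(results)
    names = sorted({name for r in results for name in r.errors} | set(compounds or ()))
    summaries = []
    for name in names:
        values = [r.errors[name] for r in results if name in r.errors]
        n = len(values)
        mean = float(np.mean(values)) if n else None
        sd = float(np.std(values, ddof=1)) if n >= 2 else None
        summaries.append(
            CompoundSummary(
                compound_name=name,
                n=n,
                n_missing=len(results) - n,
                mean_error=mean,
                sd_error=sd,
            )
        )
    return summaries


def check_threshold(
    results: Sequence[InjectionResult],
    threshold_ppm: float = 3.0,
    mode: str = "each",
) -> list[str]:
    """Compounds violating the maximum mass deviation threshold.

    ``mode="each"`` (default, the strict reading of a maximum-deviation
    criterion): a compound fails when any replicate exceeds the threshold
    in absolute value.  ``mode="mean"``: only the replicate mean is held
    to the threshold.
    """
    if not threshold_ppm > 0:
        raise ValueError("threshold_ppm must be positive")
    if mode not in ("each", "mean"):
        raise ValueError(f"mode must be 'each' or 'mean', got {mode!r}")
    _check_homogeneous(results)
    failed = []
    for summary in summarize_replicates(results):
        values = [
            r.errors[summary.compound_name] for r in results if summary.compound_name in r.errors
        ]
        if not values:
            continue
        if mode == "each":
            bad = any(abs(v) > threshold_ppm for v in values)
        else:
            bad = abs(float(np.mean(values))) > threshold_ppm
        if bad:
            failed.append(summary.compound_name)
    return failed


def sign_test_p(n_positive: int, n_negative: int) -> float:
    """Exact two-sided sign-test p-value under Binomial(n, 1/2):
    p = 2 * P(X >= max(k, n-k)), capped at 1."""
    n = n_positive + n_negative
    if n == 0:
        return 1.0
    k = max(n_positive, n_negative)
    p = 2.0 * float(stats.binom.sf(k - 1, n, 0.5))
    return min(p, 1.0)


def check_bias(
    summaries: Sequence[CompoundSummary],
    alpha: float = 0.05,
    min_compounds: int = 5,
) -> BiasCheck:
    """Test whether per-compound mean errors are randomly signed.

    Uses an exact two-sided sign test on the signs of the compound mean
    errors (exact zeros dropped).  With fewer than ``min_compounds``
    usable means the check is inconclusive and never flags.
    """
    means = [s.mean_error for s in summaries if s.mean_error is not None]
    signs = [math.copysign(1, m) for m in means if m != 0.0]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = len(signs) - n_pos
    n = n_pos + n_neg
    if len(means) < min_compounds:
        return BiasCheck(flagged=False, sign=0, p_value=None, n_used=n, conclusive=False)
    p = sign_test_p(n_pos, n_neg)
    dominant = 0 if n_pos == n_neg else (1 if n_pos > n_neg else -1)
    return BiasCheck(
        flagged=p < alpha,
        sign=dominant if p < alpha else 0,
        p_value=p,
        n_used=n,
        conclusive=True,
    )


def adaptive_protocol(
    first_two: Sequence[InjectionResult],
    threshold_ppm: float = 3.0,
    delta_ppm: float = 1.5,
) -> str:
    """Decide whether two replicates suffice or a third is needed.

    A third injection is required when, for any compound, (i) either
    replicate exceeds the ppm threshold, (ii) the two replicates disagree
    by more than ``delta_ppm`` (an outlier pair), or (iii) the compound
    was detected in only one of the two replicates.
    Returns ``"ACCEPT_TWO"`` or ``"THIRD_INJECTION"``.
    """
    if len(first_two) != 2:
        raise ValueError(f"adaptive protocol requires exactly 2 results, got {len(first_two)}")
    _check_homogeneous(first_two)
    a, b = first_two
    for name in sorted(set(a.errors) | set(b.errors)):
        in_a, in_b = name in a.errors, name in b.errors
        if in_a != in_b:
            return "THIRD_INJECTION"
        if abs(a.errors[name]) > threshold_ppm or abs(b.errors[name]) > threshold_ppm:
            return "THIRD_INJECTION"
        if abs(a.errors[name] - b.errors[name]) > delta_ppm:
            return "THIRD_INJECTION"
    return "ACCEPT_TWO"


def evaluate_sst(
    results: Sequence[InjectionResult],
    panel_compounds: Iterable[str] | None = None,
    threshold_ppm: float = 3.0,
    threshold_mode: str = "each",
    bias_alpha: float = 0.05,
    adaptive_delta_ppm: float = 1.5,
    allow_missing: Iterable[str] = (),
) -> SSTVerdict:
    """Full SST evaluation of a replicate set (2-5 injections).

    ``panel_compounds``, when given, is the set of compound names that
    must be detected; compounds in ``allow_missing`` are exempt.  The
    verdict passes only when no compound breaches the threshold, the bias
    check does not flag, and no required compound is missing.
    """
    polarity, phase = _check_homogeneous(results)
    if not 2 <= len(results) <= 5:
        raise ValueError(f"expected 2-5 replicates, got {len(results)}")

    summaries = summarize_replicates(results, compounds=panel_compounds)
    failed = check_threshold(results, threshold_ppm=threshold_ppm, mode=threshold_mode)
    bias = check_bias(summaries, alpha=bias_alpha)

    allowed = set(allow_missing)
    observed = {s.compound_name: s for s in summaries}
    missing: list[str] = []
    if panel_compounds is not None:
        for name in panel_compounds:
            if name in allowed:
                continue
            summary = observed.get(name)
            if summary is None or summary.n_missing > 0:
                missing.append(name)
    else:
        missing = [
            s.compound_name for s in summaries if s.n_missing > 0 and s.compound_name not in allowed
        ]

    passed = not failed and not bias.flagged and not missing
    if failed or bias.flagged:
        recommendation = Recommendation.RECALIBRATE
    elif len(results) == 2 and (
        missing
        or adaptive_protocol(results, threshold_ppm=threshold_ppm, delta_ppm=adaptive_delta_ppm)
        == "THIRD_INJECTION"
    ):
        recommendation = Recommendation.THIRD_INJECTION
    elif missing:
        # detections are absent despite enough replicates: operator must
        # investigate before acquisition, treated like a failing check
        recommendation = Recommendation.RECALIBRATE
    else:
        recommendation = Recommendation.PROCEED

    return SSTVerdict(
        polarity=polarity,
        phase=phase,
        passed=passed,
        failed_compounds=tuple(sorted(failed)),
        missing_compounds=tuple(sorted(missing)),
        bias=bias,
        recommendation=recommendation,
        summaries=tuple(summaries),
        n_replicates=len(results),
    )
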
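"""Mating-trial data: loading, validation, summaries, and strain comparisons.

A trial pairs one female with conspecific males and is checked for mating
at a fixed interval (default every 20 min) through a dark period (default
7 h).  The recorded time is the first check at which mating is observed,
so valid times are positive multiples of the check interval.  Times are
stored as exact :class:`fractions.Fraction` hours to avoid float drift in
downstream binning.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from allochrony.errors import ValidationError

__all__ = [
    "MatingObservation",
    "StrainSummary",
    "TestResult",
    "STRAINS",
    "DEFAULT_SCOTOPHASE_H",
    "DEFAULT_CHECK_INTERVAL_H",
    "load_trials",
    "summarize_trials",
    "fisher_exact_2x2",
    "rank_sum_test",
]

STRAINS = ("E", "Z")

DEFAULT_SCOTOPHASE_H = Fraction(7)
DEFAULT_CHECK_INTERVAL_H = Fraction(1, 3)

#: absolute slack (hours) when snapping a decimal time to the check grid;
#: 36 s, far below the 20-min interval but wide enough for values written
#: with 2 decimals (1.33 for 4/3).
_SNAP_TOL_H = 0.01


@dataclass(frozen=True)
class MatingObservation:
    """Outcome of one mating trial.

    ``time_h`` is present iff ``mated`` and is an exact Fraction in hours.
    """

    trial_id: str
    strain: str
    mated: bool
    time_h: Fraction | None = None

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValidationError(
                f"trial {self.trial_id!r}: unknown strain {self.strain!r} "
                f"(expected one of {STRAINS})"
            )
        if self.mated and self.time_h is None:
            raise ValidationError(f"trial {self.trial_id!r}: mated but no time recorded")
        if not self.mated and self.time_h is not None:
            raise ValidationError(f"trial {self.trial_id!r}: unmated but has a time")
        if self.time_h is not None and self.time_h <= 0:
            raise ValidationError(f"trial {self.trial_id!r}: time_h must be positive")


@dataclass(frozen=True)
class StrainSummary:
    strain: str
    n_trials: int
    n_mated: int
    prop_mated: float
    median_h: float | None
    mean_h: float | None


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    extras: dict = field(default_factory=dict)


def _snap_to_grid(
    time: float, check_interval_h: Fraction, trial_id: str, enforce: bool
) -> Fraction:
    """Snap a decimal time to the nearest check multiple, or raise."""
    ratio = time / float(check_interval_h)
    k = round(ratio)
    if abs(time - k * float(check_interval_h)) <= _SNAP_TOL_H and k >= 1:
        return k * check_interval_h
    if enforce:
        raise ValidationError(
            f"trial {trial_id!r}: time_h={time} is not a positive multiple of the "
            f"check interval {float(check_interval_h):g} h "
            "(pass enforce_quantization=False to keep raw times)"
        )
    return Fraction(time).limit_denominator(10**6)


def load_trials(
    path: str | Path,
    *,
    scotophase_h: Fraction | float = DEFAULT_SCOTOPHASE_H,
    check_interval_h: Fraction | float = DEFAULT_CHECK_INTERVAL_H,
    enforce_quantization: bool = True,
) -> list[MatingObservation]:
    """Read a trial CSV (``trial_id,strain,mated,time_h``).

    ``mated`` is 0/1; ``time_h`` is decimal hours, empty for unmated rows.
    Times must fall in ``(0, scotophase_h]`` and, unless
    ``enforce_quantization=False``, lie on the check-interval grid.
    """
    path = Path(path)
    scotophase_h = Fraction(scotophase_h)
    check_interval_h = Fraction(check_interval_h)
    required = ["trial_id", "strain", "mated", "time_h"]
    out: list[MatingObservation] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != required:
            raise ValidationError(
                f"{path}: expected header {','.join(required)!r}, "
                f"got {reader.fieldnames!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                trial_id = row["trial_id"].strip()
                strain = row["strain"].strip()
                mated_raw = row["mated"].strip()
                time_raw = (row["time_h"] or "").strip()
                if mated_raw not in {"0", "1"}:
                    raise ValidationError(f"mated must be 0 or 1, got {mated_raw!r}")
                mated = mated_raw == "1"
                time_h: Fraction | None = None
                if mated:
                    if not time_raw:
                        raise ValidationError("mated row has empty time_h")
                    time_h = _snap_to_grid(
                        float(time_raw), check_interval_h, trial_id, enforce_quantization
                    )
                    if not (0 < time_h <= scotophase_h):
                        raise ValidationError(
                            f"time_h={float(time_h):g} outside (0, {float(scotophase_h):g}]"
                        )
                elif time_raw:
                    raise ValidationError("unmated row has a time_h value")
                out.append(MatingObservation(trial_id, strain, mated, time_h))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def summarize_trials(
    obs: Iterable[MatingObservation], strain: str
) -> StrainSummary:
    """Counts, mating proportion, and median/mean time among mated females."""
    if strain not in STRAINS:
        raise ValidationError(f"unknown strain {strain!r} (expected one of {STRAINS})")
    rows = [o for o in obs if o.strain == strain]
    if not rows:
        raise ValidationError(f"no observations for strain {strain!r}")
    times = [o.time_h for o in rows if o.mated]
    n_mated = len(times)
    median_h = float(statistics.median(times)) if times else None
    mean_h = float(sum(times) / n_mated) if times else None
    return StrainSummary(
        strain=strain,
        n_trials=len(rows),
        n_mated=n_mated,
        prop_mated=n_mated / len(rows),
        median_h=median_h,
        mean_h=mean_h,
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the table ``[[a, b], [c, d]]``.

    The two-sided p sums hypergeometric point probabilities that do not
    exceed the observed table's probability, with a relative slack of 1e-7
    to absorb floating-point ties (the minimum-likelihood convention used
    by standard statistical packages).
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValidationError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        raise ValidationError("all four counts are zero")
    # support of the (r1, c1 | n) hypergeometric
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if b * c:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d else math.nan
    return TestResult("fisher_exact", odds, min(p, 1.0), {"table": [[a, b], [c, d]]})


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], *, force_normal: bool = False
) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Reports the rank-sum statistic W (sum of midranks of ``x``) together
    with the equivalent Mann-Whitney U in ``extras``.  Uses exact
    enumeration when both samples have n <= 8 and there are no ties,
    otherwise a tie-corrected normal approximation without continuity
    correction (``force_normal=True`` skips the exact branch).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = not force_normal and not has_ties and x.size <= 8 and y.size <= 8
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    u = float(res.statistic)
    w = u + x.size * (x.size + 1) / 2.0
    p = float(res.pvalue)
    if math.isnan(p):  # all pooled values tied: zero variance, no evidence
        p = 1.0
    return TestResult(
        "wilcoxon_rank_sum_W",
        w,
        min(p, 1.0),
        {"U": u, "method": method, "n_x": int(x.size), "n_y": int(y.size)},
    )
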
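"""Reproductive isolation from binned mating times.

Mated observations are binned into right-closed time windows
``((k-1)*w, k*w]``.  Within each window the two strains play the role of
alleles: with strain fractions ``p_i`` and ``q_i = 1 - p_i`` among the
``n_i`` matings of window ``i``, random mating would produce ``2 p_i q_i
n_i`` hybrid and ``(p_i^2 + q_i^2) n_i`` pure-strain offspring.  The
isolation statistic is

    RI = 1 - (sum_i 2 p_i q_i n_i) / (sum_i (p_i^2 + q_i^2) n_i)

which is 0 under random mating (every mixed window 50:50) and 1 when no
window contains both strains.  Empty windows contribute to neither sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from allochrony.errors import ComputationError, ValidationError
from allochrony.trial_stats import MatingObservation

__all__ = [
    "WindowCount",
    "IsolationResult",
    "bin_matings",
    "reproductive_isolation",
    "bootstrap_ri_ci",
    "combine_sequential_barriers",
]


@dataclass(frozen=True)
class WindowCount:
    """Strain-wise mating counts for one time window."""

    window_index: int
    n_Z: int
    n_E: int

    def __post_init__(self) -> None:
        if self.n_Z < 0 or self.n_E < 0:
            raise ValidationError("window counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_Z + self.n_E

    @property
    def p(self) -> float:
        """Fraction of this window's matings that are Z strain."""
        if self.n == 0:
            raise ComputationError("p undefined for an empty window")
        return self.n_Z / self.n

    @property
    def q(self) -> float:
        """Fraction of this window's matings that are E strain."""
        return 1.0 - self.p


@dataclass(frozen=True)
class IsolationResult:
    ri: float
    expected_hybrids: float
    expected_pure: float
    n_windows: int
    ci_low: float | None = None
    ci_high: float | None = None


def bin_matings(
    obs: Iterable[MatingObservation],
    window_h: float | Fraction = 1,
    span_h: float | Fraction = 7,
) -> list[WindowCount]:
    """Bin mated observations into right-closed windows over ``(0, span_h]``.

    Returns one :class:`WindowCount` per window (1-based indices), all
    windows present even when empty.  Unmated observations are ignored.
    A mating time outside the span is an error.
    """
    window_h = Fraction(window_h)
    span_h = Fraction(span_h)
    if window_h <= 0 or span_h <= 0:
        raise ValidationError("window_h and span_h must be positive")
    w = math.ceil(span_h / window_h)
    n_z = [0] * w
    n_e = [0] * w
    for o in obs:
        if not o.mated:
            continue
        t = Fraction(o.time_h)
        if not (0 < t <= span_h):
            raise ValidationError(
                f"trial {o.trial_id!r}: mating time {float(t):g} h outside "
                f"(0, {float(span_h):g}]"
            )
        k = math.ceil(t / window_h)  # exact: t, window_h are rationals
        if o.strain == "Z":
            n_z[k - 1] += 1
        else:
            n_e[k - 1] += 1
    return [WindowCount(i + 1, n_z[i], n_e[i]) for i in range(w)]


def reproductive_isolation(windows: Sequence[WindowCount]) -> IsolationResult:
    """Hardy–Weinberg expected-offspring isolation statistic over windows."""
    hyb = 0.0
    pure = 0.0
    for win in windows:
        if win.n == 0:
            continue
        # 2pqn and (p^2+q^2)n rewritten in integer counts: exact in floats
        hyb += 2.0 * win.n_Z * win.n_E / win.n
        pure += (win.n_Z**2 + win.n_E**2) / win.n
    if hyb == 0.0 and pure == 0.0:
        raise ComputationError("no matings observed: all windows empty")
    return IsolationResult(
        ri=1.0 - hyb / pure,
        expected_hybrids=hyb,
        expected_pure=pure,
        n_windows=len(windows),
    )


def _ri_from_window_indices(idx_z: np.ndarray, idx_e: np.ndarray, w: int) -> float:
    nz = np.bincount(idx_z, minlength=w + 1)[1:].astype(float)
    ne = np.bincount(idx_e, minlength=w + 1)[1:].astype(float)
    n = nz + ne
    occ = n > 0
    hyb = float((2.0 * nz[occ] * ne[occ] / n[occ]).sum())
    pure = float(((nz[occ] ** 2 + ne[occ] ** 2) / n[occ]).sum())
    return 1.0 - hyb / pure


def bootstrap_ri_ci(
    obs: Sequence[MatingObservation],
    n_boot: int,
    level: float = 0.95,
    seed: int | None = None,
    *,
    window_h: float | Fraction = 1,
    span_h: float | Fraction = 7,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the isolation statistic.

    Mated observations are resampled with replacement stratified by
    strain, so each strain's number of matings is held fixed; the
    statistic conditions on who mated, not on mating propensity.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    window_h = Fraction(window_h)
    span_h = Fraction(span_h)
    w = math.ceil(span_h / window_h)
    idx = {
        s: np.array(
            [math.ceil(Fraction(o.time_h) / window_h) for o in obs if o.mated and o.strain == s],
            dtype=np.int64,
        )
        for s in ("Z", "E")
    }
    if idx["Z"].size + idx["E"].size == 0:
        raise ComputationError("no matings observed: cannot bootstrap")
    rng = np.random.default_rng(seed)
    ris = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_retries):
            rz = rng.choice(idx["Z"], size=idx["Z"].size) if idx["Z"].size else idx["Z"]
            re_ = rng.choice(idx["E"], size=idx["E"].size) if idx["E"].size else idx["E"]
            if rz.size + re_.size > 0:
                ris[b] = _ri_from_window_indices(rz, re_, w)
                break
        else:  # pragma: no cover - unreachable while strain totals are fixed
            raise ComputationError("bootstrap resample produced no matings repeatedly")
    alpha = 1.0 - level
    lo, hi = np.quantile(ris, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def combine_sequential_barriers(strengths: Iterable[float]) -> float:
    """Total isolation from sequentially acting barriers.

    Each barrier removes its fraction of the gene flow left by earlier
    barriers: ``total = 1 - prod(1 - s_k)``.
    """
    total_pass = 1.0
    strengths = list(strengths)
    for s in strengths:
        if not (0.0 <= s <= 1.0):
            raise ValidationError(f"barrier strength {s} outside [0, 1]")
        total_pass *= 1.0 - s
    return 1.0 - total_pass
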
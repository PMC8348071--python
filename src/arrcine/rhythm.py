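"""RR-interval series: generation, summary statistics and irregularity.

The irregularity criterion used throughout the package is the coefficient of
variation of RR-interval durations, ``CV_RR = 100 * SD / mean`` (percent).
A rhythm is *irregular* when CV_RR strictly exceeds a threshold, 10% by
default.  Three synthetic arrhythmia mechanisms are provided:

``afib``
    i.i.d. log-normal RR durations (moment-matched to the requested mean and
    CV), mimicking the near-memoryless cycle lengths of atrial fibrillation.
``ectopy``
    a regular baseline interrupted by short-coupled ectopic beats, each
    followed by a compensatory pause of equal and opposite deviation.
``pauses``
    a mildly jittered baseline with occasional dropped beats, which merge two
    cycles into one roughly doubled duration (conduction-disorder-like).

All generators are moment-matched: the ectopic/pause beat counts and the
baseline jitter are solved from the requested ``(mean_rr, target_cv)`` so the
realized CV_RR is an unbiased estimate of the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorruptTimingError, InsufficientDataError, InvalidSpecError

__all__ = [
    "RRSeries",
    "ArrhythmiaSpec",
    "generate_rr",
    "cv_rr",
    "classify_irregular",
    "rr_from_dicom_fields",
    "rr_from_dicom_dataset",
]

_PATTERNS = ("afib", "ectopy", "pauses")


@dataclass(frozen=True)
class RRSeries:
    """A sequence of heartbeat durations in milliseconds."""

    durations: np.ndarray
    source: str = "manual"  # "synthetic" | "dicom" | "manual"

    def __post_init__(self) -> None:
        arr = np.asarray(self.durations, dtype=float)
        if arr.ndim != 1:
            raise InvalidSpecError("RR durations must be a 1-D sequence")
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
            raise InvalidSpecError("RR durations must be positive and finite")
        object.__setattr__(self, "durations", arr)

    def __len__(self) -> int:
        return self.durations.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.durations))

    def sd(self, ddof: int = 1) -> float:
        return float(np.std(self.durations, ddof=ddof))

    @property
    def mean_hr_bpm(self) -> float:
        """Mean heart rate in beats per minute (60000 / mean RR)."""
        return 60000.0 / self.mean

    def to_csv(self, path: str | Path) -> None:
        """Write a two-column CSV (beat_index, rr_ms)."""
        pd.DataFrame(
            {"beat_index": np.arange(len(self)), "rr_ms": self.durations}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "manual") -> "RRSeries":
        df = pd.read_csv(path)
        return cls(df["rr_ms"].to_numpy(dtype=float), source=source)


@dataclass(frozen=True)
class ArrhythmiaSpec:
    """Parameters of a synthetic irregular RR series.

    ``target_cv`` is in percent; ``seed`` is mandatory — every stochastic
    operation in the package is explicitly seeded.
    """

    mean_rr: float
    pattern: str
    target_cv: float
    n_beats: int
    seed: int
    # fraction of beats that are ectopic (ectopy pattern); the compensatory
    # pause occupies the following beat, so at most half the series.
    ectopic_fraction: float = field(default=0.15)

    def __post_init__(self) -> None:
        if not (self.mean_rr > 0 and math.isfinite(self.mean_rr)):
            raise InvalidSpecError("mean_rr must be positive and finite")
        if self.pattern not in _PATTERNS:
            raise InvalidSpecError(f"pattern must be one of {_PATTERNS}")
        if not (0 <= self.target_cv <= 100):
            raise InvalidSpecError("target_cv must lie in [0, 100] percent")
        if self.n_beats < 2:
            raise InvalidSpecError("n_beats must be at least 2")
        if not (0 < self.ectopic_fraction <= 0.5):
            raise InvalidSpecError("ectopic_fraction must lie in (0, 0.5]")


def cv_rr(series: RRSeries, ddof: int = 1) -> float:
    """Coefficient of variation of RR durations, in percent.

    ``ddof=1`` (sample SD) by default; pass ``ddof=0`` for the population SD.
    """
    if len(series) < 2:
        raise InsufficientDataError("CV_RR needs at least 2 beats")
    return 100.0 * series.sd(ddof=ddof) / series.mean


def classify_irregular(
    series: RRSeries, threshold: float = 10.0, ddof: int = 1
) -> bool:
    """True iff CV_RR strictly exceeds ``threshold`` percent."""
    return cv_rr(series, ddof=ddof) > threshold


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """n i.i.d. log-normal draws with the given arithmetic mean and CV."""
    if cv <= 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _pause_count(c: float, n: int) -> int:
    """Number of doubled beats so that pauses alone supply ~75% of target CV."""
    cp = 0.75 * c
    if cp <= 0:
        return 0
    # pure-pause CV: c'^2 (1+q)^2 = q(1-q); smaller root of the quadratic
    a = 1.0 + cp * cp
    b = 2.0 * cp * cp - 1.0
    disc = b * b - 4.0 * a * cp * cp
    q = (-b - math.sqrt(max(disc, 0.0))) / (2.0 * a)
    return max(1, round(q * n))


def generate_rr(spec: ArrhythmiaSpec) -> RRSeries:
    """Generate a synthetic RR series per ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_beats, spec.mean_rr
    c = spec.target_cv / 100.0

    if c == 0.0:
        return RRSeries(np.full(n, float(m)), source="synthetic")

    if spec.pattern == "afib":
        d = _lognormal(rng, m, c, n)

    elif spec.pattern == "ectopy":
        # disjoint (ectopic, compensatory) slots; deviation solved so the
        # pair variance 2*(k/n)*delta^2 hits the target exactly.
        k = int(np.clip(round(spec.ectopic_fraction * n), 1, n // 2))
        delta = c * math.sqrt(n / (2.0 * k))
        var_pairs = 2.0 * k / n * delta * delta
        if delta > 0.85:
            # short-coupling floor: cap the deviation and supply the
            # remaining variance as multiplicative baseline jitter.
            delta = 0.85
            var_pairs = 2.0 * k / n * delta * delta
        resid = max(c * c - var_pairs, 0.0)
        d = _lognormal(rng, m, math.sqrt(resid), n) if resid > 1e-12 else np.full(n, float(m))
        slots = rng.choice(n // 2, size=k, replace=False)
        short = 2 * slots
        d[short] -= delta * m
        d[short + 1] += delta * m
        d = np.maximum(d, 1e-3 * m)

    elif spec.pattern == "pauses":
        k = min(_pause_count(c, n), n)
        r = k / n
        # baseline jitter solved from exact two-point moments:
        # E[D^2]/m^2 = (1-r)(1+j^2) + r(4+2j^2), mean/m = 1+r
        j2 = ((1.0 + c * c) * (1.0 + r) ** 2 - 1.0 - 3.0 * r) / (1.0 + r)
        j = math.sqrt(max(j2, 0.0))
        d = _lognormal(rng, m, j, n)
        where = rng.choice(n, size=k, replace=False)
        d[where] += _lognormal(rng, m, j, k)  # dropped beat doubles the cycle
    else:  # pragma: no cover - guarded by the spec validator
        raise InvalidSpecError(spec.pattern)

    return RRSeries(d, source="synthetic")


def rr_from_dicom_fields(trigger_times) -> RRSeries:
    """RR durations from successive R-peak / trigger timestamps (ms)."""
    t = np.asarray(trigger_times, dtype=float)
    if t.size < 3:
        raise InsufficientDataError("need at least 3 trigger timestamps")
    d = np.diff(t)
    if np.any(d <= 0):
        raise CorruptTimingError("non-positive inter-trigger interval")
    return RRSeries(d, source="dicom")


def rr_from_dicom_dataset(datasets) -> RRSeries:
    """Extract an RR series from pydicom datasets using timing fields only.

    Looks at ``TriggerTime`` (0018,1060) across the frame datasets; falls back
    to ``NominalInterval`` (0018,1062) when trigger times are absent.  Pixel
    data are never touched.
    """
    times = []
    intervals = []
    for ds in datasets:
        tt = getattr(ds, "TriggerTime", None)
        if tt is not None:
            times.append(float(tt))
        ni = getattr(ds, "NominalInterval", None)
        if ni is not None:
            intervals.append(float(ni))
    if len(times) >= 3:
        return rr_from_dicom_fields(sorted(times))
    if len(intervals) >= 2:
        return RRSeries(np.asarray(intervals, dtype=float), source="dicom")
    raise InsufficientDataError("no usable DICOM timing fields found")
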
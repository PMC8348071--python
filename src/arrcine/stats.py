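"""Paired statistics for the two-sequence comparison.

The ordinal image-quality scores are compared with the Wilcoxon signed-rank
test.  Zero differences are dropped by default (the classic Wilcoxon
convention) — with heavily tied ordinal data this choice is material, so the
Pratt variant (rank zeros, then discard their contribution) is available via
``zero_method="pratt"``.  Ties among the absolute differences are mid-ranked.
The null distribution is enumerated exactly over all sign assignments (by
dynamic programming over the integer-valued doubled ranks) whenever the
number of non-zero pairs is at most 25; beyond that a normal approximation
with tie-corrected variance and continuity correction is used.  The
two-sided p-value is ``P(|W - mu| >= |w_obs - mu|)`` under the null, where
``W`` is the positive-rank sum and ``mu`` its null mean.

Continuous quantities (edge sharpness, ARA rates) use the classical paired
Student t-test.  Interobserver agreement uses the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1) —
the standard choice when both raters are considered a random draw from a
population of raters — with ICC(3,1) available, and Cohen's kappa (optionally
linearly weighted) for categorical ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FixtureError, InsufficientDataError, InvalidSpecError

__all__ = [
    "StatResult",
    "PairedCohortTable",
    "wilcoxon_signed_rank",
    "paired_t",
    "icc_absolute",
    "cohen_kappa",
    "median_range",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    n_effective: int
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise InvalidSpecError("p_value outside [0, 1]")


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(|W - mu| >= |w_obs - mu|) by DP over sign assignments.

    ``ranks`` are (possibly mid-ranked) positive ranks; doubling makes them
    integers, so the distribution of 2*W is a polynomial product of
    ``(1 + z^(2r))`` computed by convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    support = np.arange(total + 1)
    mu = total / 2.0
    dev = abs(2.0 * w_obs - mu)
    return float(counts[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(
    a,
    b=None,
    zero_method: str = "wilcox",
    mode: str = "auto",
    exact_cutoff: int = 25,
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    ``a`` may be a difference vector (with ``b`` omitted) or the first of two
    matched samples.  The reported ``statistic`` is the signed rank sum
    ``W+ - W-`` (so swapping the samples negates it); the positive-rank sum
    ``W+`` is available in ``extra``.
    """
    d = np.asarray(a, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    if d.size < 1:
        raise InsufficientDataError("no pairs")
    if zero_method not in ("wilcox", "pratt"):
        raise InvalidSpecError("zero_method must be 'wilcox' or 'pratt'")

    nonzero = d != 0
    n_eff = int(nonzero.sum())
    if n_eff == 0:
        return StatResult(0.0, 1.0, "wilcoxon (degenerate: all ties)", 0, True)

    if zero_method == "wilcox":
        dd = d[nonzero]
        ranks = sps.rankdata(np.abs(dd))
    else:  # pratt: rank zeros too, then drop their ranks
        ranks_all = sps.rankdata(np.abs(d))
        dd = d[nonzero]
        ranks = ranks_all[nonzero]

    w_plus = float(ranks[dd > 0].sum())
    w_minus = float(ranks[dd < 0].sum())
    rank_sum = float(ranks.sum())
    mu = rank_sum / 2.0

    use_exact = mode == "exact" or (mode == "auto" and n_eff <= exact_cutoff)
    if use_exact:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "wilcoxon (exact)"
    else:
        # tie-corrected variance of W+ under sign flips: sum(r_i^2) / 4
        var = float(np.sum(ranks**2)) / 4.0
        dev = abs(w_plus - mu)
        z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity correction
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = "wilcoxon (normal approx.)"
    return StatResult(
        statistic=w_plus - w_minus,
        p_value=p,
        method=method,
        n_effective=n_eff,
        extra={"w_plus": w_plus, "w_minus": w_minus, "zero_method": zero_method},
    )


# --------------------------------------------------------------------------
# Paired t-test
# --------------------------------------------------------------------------


def paired_t(values_a, values_b) -> StatResult:
    """Classical two-sided paired Student t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InsufficientDataError("need two equal-length samples, n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return StatResult(
            np.nan, 1.0, "paired t (degenerate: zero-variance differences)",
            a.size, True,
        )
    t, p = sps.ttest_rel(a, b)
    return StatResult(float(t), float(p), "paired t", int(a.size))


# --------------------------------------------------------------------------
# Interobserver agreement
# --------------------------------------------------------------------------


def icc_absolute(ratings, model: str = "icc2") -> StatResult:
    """Single-measure intraclass correlation from a (subjects x raters) matrix.

    ``model="icc2"`` is the two-way random, absolute-agreement ICC(2,1);
    ``model="icc3"`` the two-way mixed, consistency ICC(3,1).  Computed from
    the two-way ANOVA mean squares; the p-value is the F-test of
    MS_subjects / MS_error.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 raters")
    if model not in ("icc2", "icc3"):
        raise InvalidSpecError("model must be 'icc2' or 'icc3'")
    n, k = x.shape
    grand = x.mean()
    ms_r = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)  # subjects
    ms_c = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)  # raters
    sse = np.sum((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2)
    ms_e = sse / ((n - 1) * (k - 1))

    if ms_r <= 0 or (ms_r == ms_e == 0):
        return StatResult(np.nan, 1.0, f"{model} (degenerate)", n, True)
    if model == "icc2":
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
        label = "ICC(2,1) absolute agreement"
    else:
        denom = ms_r + (k - 1) * ms_e
        label = "ICC(3,1) consistency"
    icc = float((ms_r - ms_e) / denom) if denom > 0 else np.nan
    if ms_e > 0:
        f = ms_r / ms_e
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0
    return StatResult(icc, p, label, n)


def cohen_kappa(ratings_a, ratings_b, weights: str | None = None) -> StatResult:
    """Cohen's kappa between two raters; ``weights`` in {None, 'linear'}."""
    from sklearn.metrics import cohen_kappa_score

    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size < 1:
        raise InsufficientDataError("need two equal-length rating lists")
    if weights not in (None, "linear"):
        raise InvalidSpecError("weights must be None or 'linear'")
    cats = np.union1d(np.unique(a), np.unique(b))
    if cats.size < 2:
        return StatResult(np.nan, 1.0, "kappa (degenerate: one category)", a.size, True)
    kappa = float(cohen_kappa_score(a, b, weights=weights))
    label = "Cohen kappa" + (" (linear weights)" if weights else "")
    return StatResult(kappa, np.nan, label, int(a.size))


def median_range(values) -> dict:
    """Median and (min, max) range; even-n median is the central midpoint."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("empty sample")
    return {
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
    }


# --------------------------------------------------------------------------
# Paired cohort tables (cross-tabulations)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedCohortTable:
    """Per-patient paired ordinal scores for the two sequences.

    ``scores_ref`` / ``scores_rt`` hold one ordinal value per patient (for
    banded tables these are band indices).  ``scale_values`` lists the
    admissible ordinal values; ``scale_labels`` their printed labels;
    ``better`` says whether a higher or lower value means better quality.
    """

    scores_ref: np.ndarray
    scores_rt: np.ndarray
    scale_values: tuple
    scale_labels: tuple
    better: str = "higher"  # "higher" | "lower"

    def __post_init__(self) -> None:
        ref = np.asarray(self.scores_ref)
        rt = np.asarray(self.scores_rt)
        if ref.shape != rt.shape or ref.size < 1:
            raise InvalidSpecError("need matched, non-empty score vectors")
        values = set(self.scale_values)
        if not (set(ref.tolist()) <= values and set(rt.tolist()) <= values):
            raise InvalidSpecError("scores outside the declared scale")
        if self.better not in ("higher", "lower"):
            raise InvalidSpecError("better must be 'higher' or 'lower'")
        object.__setattr__(self, "scores_ref", ref)
        object.__setattr__(self, "scores_rt", rt)

    @property
    def n_patients(self) -> int:
        return int(self.scores_ref.size)

    def crosstab(self) -> np.ndarray:
        """Counts matrix, rows = reference scale value, cols = real-time."""
        k = len(self.scale_values)
        index = {v: i for i, v in enumerate(self.scale_values)}
        out = np.zeros((k, k), dtype=int)
        for r, t in zip(self.scores_ref.tolist(), self.scores_rt.tolist()):
            out[index[r], index[t]] += 1
        return out

    def equal_or_better(self) -> tuple[int, float]:
        """(count, percent) of patients where the real-time score is at least
        as good as the reference score."""
        if self.better == "higher":
            n = int(np.sum(self.scores_rt >= self.scores_ref))
        else:
            n = int(np.sum(self.scores_rt <= self.scores_ref))
        return n, 100.0 * n / self.n_patients

    @classmethod
    def from_crosstab(
        cls,
        counts,
        scale_values,
        scale_labels=None,
        better: str = "higher",
        n_patients: int | None = None,
    ) -> "PairedCohortTable":
        counts = np.asarray(counts, dtype=int)
        k = len(scale_values)
        if counts.shape != (k, k) or np.any(counts < 0):
            raise FixtureError("counts must be a non-negative k x k matrix")
        if n_patients is not None and counts.sum() != n_patients:
            raise FixtureError(
                f"counts sum to {counts.sum()}, expected {n_patients}"
            )
        ref, rt = [], []
        for i, vi in enumerate(scale_values):
            for j, vj in enumerate(scale_values):
                ref.extend([vi] * counts[i, j])
                rt.extend([vj] * counts[i, j])
        return cls(
            np.asarray(ref),
            np.asarray(rt),
            tuple(scale_values),
            tuple(scale_labels) if scale_labels else tuple(map(str, scale_values)),
            better,
        )

    @classmethod
    def from_long_csv(
        cls, path: str | Path, scale_values, better: str = "higher"
    ) -> "PairedCohortTable":
        df = pd.read_csv(path)
        return cls(
            df["score_ref"].to_numpy(),
            df["score_rt"].to_numpy(),
            tuple(scale_values),
            tuple(map(str, scale_values)),
            better,
        )

    def to_long_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "patient_id": np.arange(self.n_patients),
                "score_ref": self.scores_ref,
                "score_rt": self.scores_rt,
            }
        ).to_csv(path, index=False)
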
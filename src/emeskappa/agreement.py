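"""Multi-rater weighted Fleiss-type kappa for ordinal rating studies.

The statistic generalises Fleiss' kappa to ordinal categories through an
agreement weight matrix ``w`` (symmetric, unit diagonal, entries in
[0, 1]).  With ``n_ik`` the number of raters assigning category ``k`` to
subject ``i`` and ``r_i`` the subject's rater total:

    a_i = sum_{k,l} w_kl * n_ik * (n_il - [k = l]) / (r_i * (r_i - 1))
    pa  = mean_i a_i                       (observed weighted agreement)
    p_k = mean_i n_ik / r_i                (pooled category marginals)
    pe  = sum_{k,l} w_kl * p_k * p_l       (chance-expected agreement)
    kappa = (pa - pe) / (1 - pe)

Chance correction uses the pooled marginals, as in Fleiss' original
multi-rater coefficient; with two raters this reduces to the weighted
Scott/Fleiss form computable from the 2-rater contingency table.

The asymptotic standard error comes from the subject-level
linearization (the influence-function / pseudo-value variance used by
Gwet for multi-rater weighted coefficients):

    psi_i = [(a_i - pa) - 2 (1 - kappa) (pi_i . wbar - pe)] / (1 - pe)
    se^2  = sum_i psi_i^2 / (n (n - 1))

with ``pi_ik = n_ik / r_i`` and ``wbar_k = sum_l w_kl p_l``.  A
subject-resampling percentile bootstrap is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scales import ALL_SCALES, OrdinalItemScale, Segment
from .scoring import per_rater_scores

WEIGHT_SCHEMES = ("identity", "linear", "quadratic")

#: Conventional interpretation bands for kappa magnitude
#: (poor < 0 <= slight <= 0.20 < fair <= 0.40 < moderate <= 0.60
#:  < substantial <= 0.80 < almost perfect).
AGREEMENT_BANDS = (
    (0.00, "slight"),
    (0.20, "fair"),
    (0.40, "moderate"),
    (0.60, "substantial"),
    (0.80, "almost perfect"),
)


class DegenerateAgreementError(ValueError):
    """Chance agreement pe = 1: every rating in one category, kappa undefined."""


@dataclass(frozen=True)
class WeightMatrix:
    """K x K agreement weights: symmetric, unit diagonal, entries in [0, 1]."""

    w: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("weight matrix diagonal must be 1")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.w.shape[0]


def make_weights(scheme: str, K: int) -> WeightMatrix:
    """Standard ordinal agreement weights.

    identity:  w_kl = 1 if k == l else 0 (classical unweighted kappa)
    linear:    w_kl = 1 - |k - l| / (K - 1)
    quadratic: w_kl = 1 - (k - l)^2 / (K - 1)^2
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    k = np.arange(K)
    d = np.abs(k[:, None] - k[None, :]).astype(float)
    if scheme == "identity":
        w = (d == 0).astype(float)
    elif scheme == "linear":
        w = 1.0 - d / (K - 1)
    elif scheme == "quadratic":
        w = 1.0 - (d / (K - 1)) ** 2
    else:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}"
        )
    return WeightMatrix(w=w, scheme=scheme)


@dataclass(frozen=True)
class CountMatrix:
    """Subjects x categories rating-count table for one scale.

    ``counts[i, k]`` is the number of raters assigning category ``k`` to
    subject ``i``.  The number of columns is fixed by the scale, never
    by the observed categories.  Rows with fewer than two raters carry
    no pairwise agreement information and are excluded at construction;
    ``n_dropped`` records how many.
    """

    counts: np.ndarray
    scale: OrdinalItemScale
    subject_ids: tuple[str, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.shape[1] != self.scale.n_categories:
            raise ValueError(
                f"counts have {c.shape[1]} columns but scale "
                f"{self.scale.name!r} has {self.scale.n_categories} categories"
            )
        object.__setattr__(self, "counts", c)
        if len(self.subject_ids) != c.shape[0]:
            raise ValueError("subject_ids length must match counts rows")

    @classmethod
    def from_counts(
        cls,
        counts,
        scale: OrdinalItemScale,
        subject_ids: Sequence[str] | None = None,
    ) -> "CountMatrix":
        """Build from a raw count array, dropping rows with < 2 raters."""
        c = np.asarray(counts, dtype=np.int64)
        if subject_ids is None:
            subject_ids = [f"S{i:03d}" for i in range(c.shape[0])]
        keep = c.sum(axis=1) >= 2
        dropped = int((~keep).sum())
        return cls(
            counts=c[keep],
            scale=scale,
            subject_ids=tuple(np.asarray(subject_ids, dtype=object)[keep]),
            n_dropped=dropped,
        )

    @property
    def raters_per_subject(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def K(self) -> int:
        return self.counts.shape[1]


def scores_to_counts(
    scores: pd.DataFrame, scale: OrdinalItemScale
) -> CountMatrix:
    """Tabulate a ``subject_id, score`` frame into a CountMatrix."""
    if scores.empty:
        raise ValueError("empty selection: no ratings to tabulate")
    tab = pd.crosstab(scores["subject_id"], scores["score"])
    tab = tab.reindex(columns=list(scale.categories), fill_value=0)
    return CountMatrix.from_counts(
        tab.to_numpy(), scale, subject_ids=list(tab.index.astype(str))
    )


def build_count_matrix(
    table,
    item: str,
    segment: str | Segment | None = None,
    scale: OrdinalItemScale | None = None,
) -> CountMatrix:
    """Count matrix for one analysis cell of a ratings table.

    ``item`` may be a directly rated item (``erythema``,
    ``vascular_pattern``, ``erosions``, ``ulcers``, ``mayo``) or a
    derived score (``segment_emes``, ``global_emes``).  Derived scores
    are computed per rater first and then tabulated as ordinal
    categories on their full theoretical range (0-11 or 0-55).
    """
    if scale is None:
        if item not in ALL_SCALES:
            raise ValueError(f"unknown item {item!r}")
        scale = ALL_SCALES[item]

    if item == "global_emes":
        scores = per_rater_scores(table, "global_emes")
    elif item == "segment_emes":
        if segment is None:
            raise ValueError("segment required for segment_emes")
        seg = segment.value if isinstance(segment, Segment) else str(segment)
        all_seg = per_rater_scores(table, "segment_emes")
        scores = all_seg[all_seg["segment"] == seg]
    elif item == "mayo":
        sel = table.select("mayo")
        scores = sel.rename(columns={"value": "score"})
    else:
        sel = table.select(item, segment)
        scores = sel.rename(columns={"value": "score"})
    if scores.empty:
        raise ValueError(
            f"empty selection for item={item!r}, segment={segment!r}"
        )
    return scores_to_counts(scores, scale)


def _components(counts: np.ndarray, w: np.ndarray):
    """Per-subject observed agreement a_i, pa, pooled marginals p, pe."""
    c = counts.astype(float)
    r = c.sum(axis=1)
    cw = c @ w
    # diag(w) = 1, so sum_kl w_kl n_ik (n_il - [k=l]) = (n W n) - r_i
    a = ((c * cw).sum(axis=1) - r) / (r * (r - 1.0))
    pa = float(a.mean())
    p = (c / r[:, None]).mean(axis=0)
    pe = float(p @ w @ p)
    return a, pa, p, pe


def weighted_fleiss_kappa(
    counts: CountMatrix, weights: WeightMatrix
) -> tuple[float, float, float]:
    """Weighted Fleiss' kappa; returns ``(kappa, pa, pe)``.

    Raises :class:`DegenerateAgreementError` when pe = 1 (all ratings in
    a single category across the study), where kappa is undefined.
    """
    _check_pair(counts, weights)
    _, pa, _, pe = _components(counts.counts, weights.w)
    if pe >= 1.0 - 1e-12:
        raise DegenerateAgreementError(
            "chance agreement pe = 1 (all ratings in one category); "
            "kappa is undefined"
        )
    kappa = (pa - pe) / (1.0 - pe)
    return float(kappa), pa, pe


def kappa_se_asymptotic(counts: CountMatrix, weights: WeightMatrix) -> float:
    """Large-sample SE from the subject-level linearization (see module
    docstring); requires at least two subjects."""
    _check_pair(counts, weights)
    n = counts.n_subjects
    if n < 2:
        raise ValueError("need >= 2 subjects for a standard error")
    c = counts.counts.astype(float)
    w = weights.w
    a, pa, p, pe = _components(c, w)
    if pe >= 1.0 - 1e-12:
        raise DegenerateAgreementError("pe = 1; variance undefined")
    kappa = (pa - pe) / (1.0 - pe)
    r = c.sum(axis=1)
    pi = c / r[:, None]
    wbar = w @ p
    psi = ((a - pa) - 2.0 * (1.0 - kappa) * (pi @ wbar - pe)) / (1.0 - pe)
    var = float((psi**2).sum()) / (n * (n - 1.0))
    return math.sqrt(max(var, 0.0))


def kappa_se_jackknife(counts: CountMatrix, weights: WeightMatrix) -> float:
    """Delete-1 jackknife SE over subjects; independent of the
    linearized formula and used to validate it."""
    _check_pair(counts, weights)
    n = counts.n_subjects
    if n < 2:
        raise ValueError("need >= 2 subjects for a standard error")
    c = counts.counts
    w = weights.w
    loo = np.empty(n)
    for i in range(n):
        sub = np.delete(c, i, axis=0)
        _, pa, _, pe = _components(sub, w)
        if pe >= 1.0 - 1e-12:
            raise DegenerateAgreementError("pe = 1 in a jackknife replicate")
        loo[i] = (pa - pe) / (1.0 - pe)
    var = (n - 1.0) / n * float(((loo - loo.mean()) ** 2).sum())
    return math.sqrt(var)


def kappa_ci_bootstrap(
    counts: CountMatrix,
    weights: WeightMatrix,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Percentile CI over B subject-level bootstrap resamples.

    Returns ``(ci_low, ci_high, n_skipped)``; degenerate resamples
    (pe = 1) are skipped and counted.  Deterministic given ``seed``.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    _check_pair(counts, weights)
    rng = np.random.default_rng(seed)
    n = counts.n_subjects
    c = counts.counts
    w = weights.w
    reps = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        _, pa, _, pe = _components(c[idx], w)
        if pe >= 1.0 - 1e-12:
            skipped += 1
            continue
        reps.append((pa - pe) / (1.0 - pe))
    if not reps:
        raise DegenerateAgreementError("all bootstrap resamples degenerate")
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), skipped


def kappa_pvalue(kappa: float, se: float) -> float:
    """Two-sided normal-approximation p-value for H0: kappa = 0."""
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        if kappa == 0:
            return 1.0
        return float(np.nextafter(0.0, 1.0))  # below machine resolution
    z = abs(kappa) / se
    return float(2.0 * stats.norm.sf(z))


def label_agreement(kappa: float) -> str:
    """Agreement-strength band for a kappa value.

    Bands: poor (< 0), slight [0, 0.20], fair (0.20, 0.40],
    moderate (0.40, 0.60], substantial (0.60, 0.80],
    almost perfect (0.80, 1].  Ties at printed boundaries fall to the
    lower band.
    """
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.0:
        return "poor"
    label = AGREEMENT_BANDS[0][1]
    for lower, name in AGREEMENT_BANDS:
        if kappa > lower:
            label = name
    return label


@dataclass(frozen=True)
class KappaResult:
    """One agreement estimate with uncertainty and interpretation."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    pa: float
    pe: float
    n_subjects: int
    n_raters_min: int
    n_raters_max: int
    scheme: str
    label: str
    flag: str = ""

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "pa": self.pa,
            "pe": self.pe,
            "n_subjects": self.n_subjects,
            "n_raters_min": self.n_raters_min,
            "n_raters_max": self.n_raters_max,
            "scheme": self.scheme,
            "label": self.label,
            "flag": self.flag,
        }


def kappa_analysis(
    counts: CountMatrix,
    weights: WeightMatrix,
    ci_method: str = "asymptotic",
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> KappaResult:
    """Full kappa analysis for one count matrix: estimate, SE, CI at the
    ``1 - alpha`` level, p-value and agreement band."""
    r = counts.raters_per_subject
    flag = ""
    try:
        kappa, pa, pe = weighted_fleiss_kappa(counts, weights)
    except DegenerateAgreementError:
        return KappaResult(
            kappa=float("nan"), se=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"),
            p_value=float("nan"), pa=1.0, pe=1.0,
            n_subjects=counts.n_subjects,
            n_raters_min=int(r.min()), n_raters_max=int(r.max()),
            scheme=weights.scheme, label="", flag="degenerate",
        )
    se = kappa_se_asymptotic(counts, weights)
    if ci_method == "asymptotic":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo, hi = kappa - z * se, kappa + z * se
    elif ci_method == "bootstrap":
        lo, hi, skipped = kappa_ci_bootstrap(
            counts, weights, B=B, seed=seed, alpha=alpha
        )
        if skipped > 0.10 * B:
            flag = f"bootstrap_skips={skipped}"
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    # a point estimate always lies inside its own interval
    lo, hi = min(lo, kappa), max(hi, kappa)
    if se == 0.0 and kappa != 0.0:
        flag = (flag + ";" if flag else "") + "se_zero"
    return KappaResult(
        kappa=kappa, se=se, ci_low=float(lo), ci_high=float(hi),
        p_value=kappa_pvalue(kappa, se), pa=pa, pe=pe,
        n_subjects=counts.n_subjects,
        n_raters_min=int(r.min()), n_raters_max=int(r.max()),
        scheme=weights.scheme, label=label_agreement(kappa), flag=flag,
    )


def _check_pair(counts: CountMatrix, weights: WeightMatrix) -> None:
    if counts.K != weights.K:
        raise ValueError(
            f"scale has {counts.K} categories but weights are "
            f"{weights.K} x {weights.K}"
        )
    if counts.n_subjects == 0:
        raise ValueError("no subjects with >= 2 raters")
    if (counts.raters_per_subject < 2).any():
        raise ValueError("every retained subject needs >= 2 raters")


__all__ = [
    "WeightMatrix",
    "CountMatrix",
    "KappaResult",
    "DegenerateAgreementError",
    "WEIGHT_SCHEMES",
    "make_weights",
    "build_count_matrix",
    "scores_to_counts",
    "weighted_fleiss_kappa",
    "kappa_se_asymptotic",
    "kappa_se_jackknife",
    "kappa_ci_bootstrap",
    "kappa_pvalue",
    "label_agreement",
    "kappa_analysis",
]
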
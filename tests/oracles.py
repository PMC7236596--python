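"""Independent brute-force references for the agreement statistics.

These deliberately avoid the package's count-matrix algebra: observed
agreement is enumerated over explicit rater pairs, and the two-rater
reference goes through a K x K contingency table.  They exist only to
validate the vectorized implementation.
"""

from __future__ import annotations

import numpy as np


def pairwise_weighted_kappa(counts, w) -> float:
    """Weighted multi-rater kappa by explicit pair enumeration.

    Per subject, reconstruct the rating list from the counts and average
    the weight over every ordered pair of distinct raters; chance
    agreement uses the pooled category marginals.
    """
    counts = np.asarray(counts)
    w = np.asarray(w, dtype=float)
    K = counts.shape[1]
    pa_per_subject = []
    for row in counts:
        ratings = np.repeat(np.arange(K), row)
        m = len(ratings)
        vals = [
            w[ratings[a], ratings[b]]
            for a in range(m)
            for b in range(m)
            if a != b
        ]
        pa_per_subject.append(float(np.mean(vals)))
    pa = float(np.mean(pa_per_subject))
    r = counts.sum(axis=1)
    p = (counts / r[:, None]).mean(axis=0)
    pe = float(p @ w @ p)
    return (pa - pe) / (1.0 - pe)


def two_rater_contingency_kappa(x1, x2, w, K: int) -> float:
    """Two-rater weighted kappa from the K x K contingency table.

    Observed agreement is the weighted sum over the joint table; chance
    agreement uses the pooled (averaged) margins, the two-rater
    specialization of the multi-rater coefficient's chance term.
    """
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    w = np.asarray(w, dtype=float)
    table = np.zeros((K, K))
    for a, b in zip(x1, x2):
        table[a, b] += 1.0
    table /= table.sum()
    po = float((w * table).sum())
    p = (table.sum(axis=1) + table.sum(axis=0)) / 2.0
    pe = float(p @ w @ p)
    return (po - pe) / (1.0 - pe)


def jackknife_se(counts, w) -> float:
    """Delete-1 jackknife SE computed from first principles."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]

    def kappa_of(c):
        r = c.sum(axis=1)
        Kcats = c.shape[1]
        pa_list = []
        for row in c:
            ratings = np.repeat(np.arange(Kcats), row.astype(int))
            m = len(ratings)
            vals = [
                w[ratings[a], ratings[b]]
                for a in range(m)
                for b in range(m)
                if a != b
            ]
            pa_list.append(np.mean(vals))
        pa = np.mean(pa_list)
        p = (c / r[:, None]).mean(axis=0)
        pe = p @ w @ p
        return (pa - pe) / (1.0 - pe)

    loo = np.array([kappa_of(np.delete(counts, i, axis=0)) for i in range(n)])
    return float(np.sqrt((n - 1.0) / n * ((loo - loo.mean()) ** 2).sum()))
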
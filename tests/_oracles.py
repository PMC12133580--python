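"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with plain
loops and library primitives (np.std / np.percentile / scipy quad), sharing
no code with the implementation paths they check.
"""

import math

import numpy as np
from scipy.integrate import quad

SQRT2PI = math.sqrt(2.0 * math.pi)
FLOOR = 1e-6
TIE = 1e-12


def oracle_silverman(values):
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1))
    iqr = float(np.percentile(v, 75) - np.percentile(v, 25))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * a * len(v) ** (-0.2)
    return h if h > 0 else FLOOR


def oracle_kde_at(point, data, h):
    total = 0.0
    for x in data:
        total += math.exp(-((point - x) ** 2) / (2.0 * h * h))
    return total / (len(data) * h * SQRT2PI)


def oracle_loo_kde_classify(values, labels):
    """Literal leave-one-out KDE classification, one holdout at a time."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    pred = np.zeros(len(v), dtype=bool)
    for i in range(len(v)):
        case_train = [v[j] for j in range(len(v)) if lab[j] and j != i]
        ref_train = [v[j] for j in range(len(v)) if not lab[j] and j != i]
        h_case = oracle_silverman(np.array(case_train))
        h_ref = oracle_silverman(np.array(ref_train))
        d_case = oracle_kde_at(v[i], case_train, h_case)
        d_ref = oracle_kde_at(v[i], ref_train, h_ref)
        pred[i] = (d_case - d_ref) > TIE * (d_case + d_ref)
    return pred


def oracle_interval_assignment(peaks, promoters, min_overlap=1):
    """All-pairs half-open interval intersection (O(n*m), no index)."""
    pk_chrom = peaks["chrom"].to_numpy()
    pk_start = peaks["start"].to_numpy()
    pk_end = peaks["end"].to_numpy()
    bound = set()
    for gene, prom in promoters.iterrows():
        same = pk_chrom == prom["chrom"]
        ov = np.minimum(pk_end, prom["end"]) - np.maximum(pk_start, prom["start"])
        if np.any(same & (ov >= min_overlap)):
            bound.add(gene)
    return bound


def oracle_dss_quadrature(bottom, top, ec50, hill, dose_min, dose_max, threshold=10.0):
    """Adaptive quadrature of the capped, thresholded 4PL on log10-dose."""
    l1, l2 = math.log10(dose_min), math.log10(dose_max)

    def integrand(l):
        y = bottom + (top - bottom) / (1.0 + (ec50 / 10.0**l) ** hill)
        return max(min(y, 100.0) - threshold, 0.0)

    pts = []
    if bottom < threshold < top:
        pts.append(math.log10(ec50) - math.log10((top - threshold) / (threshold - bottom)) / hill)
    if top > 100.0 > bottom:
        pts.append(math.log10(ec50) - math.log10((top - 100.0) / (100.0 - bottom)) / hill)
    pts = [p for p in pts if l1 < p < l2]
    area, _ = quad(integrand, l1, l2, points=sorted(pts) or None, limit=400)
    return 100.0 * area / ((100.0 - threshold) * (l2 - l1))
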
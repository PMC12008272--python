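"""Brute-force reference implementations used to cross-check the package.

These deliberately avoid the code paths (and, where practical, the
libraries) used by the implementation: metrics are spelled out from
their definitions, rankings via explicit sorts over pairwise cosines.
"""

import math

import numpy as np


def brute_cosine(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def brute_confusion_metrics(truth, pred):
    """Accuracy plus macro precision/recall/F1 from raw confusion counts."""
    tp = sum(t == "ON" and p == "ON" for t, p in zip(truth, pred))
    tn = sum(t == "OFF" and p == "OFF" for t, p in zip(truth, pred))
    fp = sum(t == "OFF" and p == "ON" for t, p in zip(truth, pred))
    fn = sum(t == "ON" and p == "OFF" for t, p in zip(truth, pred))
    acc = (tp + tn) / len(truth)

    def prf(tp_, fp_, fn_):
        prec = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        rec = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return prec, rec, f1

    p_on, r_on, f_on = prf(tp, fp, fn)
    p_off, r_off, f_off = prf(tn, fn, fp)
    return acc, (p_on + p_off) / 2, (r_on + r_off) / 2, (f_on + f_off) / 2


def brute_auc(truth, scores):
    """Mann-Whitney statistic with the midpoint convention on ties."""
    pos = [s for t, s in zip(truth, scores) if t == "ON"]
    neg = [s for t, s in zip(truth, scores) if t == "OFF"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def avg_ranks(v):
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_spearman(y, p):
    return float(np.corrcoef(avg_ranks(np.asarray(y)), avg_ranks(np.asarray(p)))[0, 1])


def brute_percentile(values, q):
    """Linear-interpolation (type 7) quantile."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_calibration(conf, truth_is_on, n_bins=10):
    conf = np.asarray(conf, float)
    y = np.asarray(truth_is_on, float)
    brier = float(np.mean((conf - y) ** 2))
    ece = 0.0
    mce = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        mask = (conf >= lo) & (conf < hi) if b < n_bins - 1 else (conf >= lo) & (conf <= hi)
        if not mask.any():
            continue
        gap = abs(y[mask].mean() - conf[mask].mean())
        ece += mask.sum() / len(conf) * gap
        mce = max(mce, gap)
    return brier, ece, mce
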
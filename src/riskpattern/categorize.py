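"""Automatic binarization of numeric variables by maximal information gain.

A numeric predictor is turned into a two-level categorical one by choosing
a cutoff x so that splitting the training records into "≤ x" and "> x"
maximizes the information gain for the binary target — the branching
criterion of classification trees, applied once per variable. Candidate
cutoffs are the midpoints between consecutive distinct observed values,
which yields the familiar half-unit cutoffs (58.5, 79.5, ...) on
integer-valued data. Records with a missing value are excluded from the
scan; ties in gain break toward the smaller cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["SplitRule", "entropy", "information_gain", "best_split", "apply_split"]


@dataclass(frozen=True)
class SplitRule:
    """A binarization rule ``value ≤ cutoff`` / ``value > cutoff``.

    ``gain`` is the information gain (bits) the rule achieves on the data
    it was fit to; it lies in [0, H(target)].
    """

    variable: str
    cutoff: float
    gain: float


def _as_bool(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.size == 0:
        raise ValidationError("labels must be non-empty")
    return y.astype(bool)


def entropy(labels) -> float:
    """Shannon entropy (base 2) of a binary label multiset."""
    y = _as_bool(labels)
    p = float(y.mean())
    return _binary_entropy(p)


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


def information_gain(labels, partition) -> float:
    """Information gain of a two-block partition for binary labels.

    ``partition`` assigns each label to block 0 or 1. The gain is
    H(labels) − Σ_b (n_b/n)·H(block b); an empty block contributes 0.
    """
    y = _as_bool(labels)
    blocks = np.asarray(partition).astype(bool)
    if blocks.shape != y.shape:
        raise ValidationError("labels and partition lengths differ")
    n = y.size
    h = entropy(y)
    cond = 0.0
    for b in (False, True):
        mask = blocks == b
        nb = int(mask.sum())
        if nb:
            cond += (nb / n) * _binary_entropy(float(y[mask].mean()))
    return max(0.0, h - cond)


def best_split(values, labels, variable: str = "") -> SplitRule | None:
    """Exhaustive best information-gain cutoff for one numeric variable.

    Scans every midpoint between consecutive distinct non-missing values
    and returns the cutoff maximizing the gain of the induced ≤x / >x
    partition, or None when no valid split exists (fewer than two distinct
    values, or maximal gain 0).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.shape != y.shape:
        raise ValidationError("values and labels lengths differ")
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep].astype(bool)
    if x.size == 0:
        return None

    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    # boundaries between consecutive distinct sorted values
    change = np.flatnonzero(np.diff(xs) > 0)
    if change.size == 0:
        return None
    cut_sizes = change + 1                       # records in the "≤ x" block
    pos_cum = np.cumsum(ys)
    n = xs.size
    n_pos = int(pos_cum[-1])

    left_n = cut_sizes
    left_pos = pos_cum[change]
    right_n = n - left_n
    right_pos = n_pos - left_pos

    h_total = _binary_entropy(n_pos / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        def block_entropy(pos, tot):
            p = pos / tot
            e = np.zeros_like(p, dtype=float)
            inner = (p > 0) & (p < 1)
            pi = p[inner]
            e[inner] = -pi * np.log2(pi) - (1 - pi) * np.log2(1 - pi)
            return e

        cond = (left_n / n) * block_entropy(left_pos, left_n) + (
            right_n / n
        ) * block_entropy(right_pos, right_n)
    gains = h_total - cond

    best = int(np.argmax(gains))  # first max = smallest cutoff on ties
    if gains[best] <= 0.0:
        return None
    cutoff = float((xs[change[best]] + xs[change[best] + 1]) / 2.0)
    return SplitRule(variable=variable, cutoff=cutoff, gain=float(gains[best]))


def apply_split(rule: SplitRule, value: float | None) -> str | None:
    """Categorize one value under a split rule; missing stays missing.

    The left category is inclusive: a value equal to the cutoff maps to
    "≤x".
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return "<=x" if value <= rule.cutoff else ">x"
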
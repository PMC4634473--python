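"""Information-gain feature ranking with MDL (entropy) discretization.

Numeric features are discretized by recursive binary splitting: each split
minimizes the class-information entropy of the induced partition and is
accepted only if its gain passes the minimum-description-length criterion

    gain(T) > [log2(N - 1) + log2(3^k - 2) - (k*H(S) - k1*H(S1) - k2*H(S2))] / N

with k the number of classes present in the segment (the classic recursive
entropy/MDL discretizer). The information gain of a feature is then
H(y) - sum_bins p(bin) * H(y | bin) in bits over the induced bins; a feature
with no accepted cut has zero gain (uninformative at this sample size).

Ranking must be computed on training folds only inside cross-validation —
ranking on the full matrix leaks the held-out subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .features import feature_columns_of


def _entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a non-negative count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _segment_entropies(left_counts: np.ndarray) -> np.ndarray:
    """Entropy (bits) of each row of a (m, k) count matrix; zero rows -> 0."""
    n = left_counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(left_counts > 0, np.log2(left_counts), 0.0)
        ent = np.where(
            n[:, 0] > 0,
            np.log2(np.where(n[:, 0] > 0, n[:, 0], 1.0))
            - np.sum(left_counts * logs, axis=1) / np.where(n[:, 0] > 0, n[:, 0], 1.0),
            0.0,
        )
    return ent


def mdl_discretize(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Cut points of the recursive entropy/MDL discretization of x given y.

    Returns a sorted (possibly empty) list of cut values (midpoints between
    adjacent distinct x values). A single class in y, or a constant x,
    yields an empty list.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ParameterError("x and y must have equal length")
    if len(x) < 2:
        raise ParameterError("need at least 2 samples")
    _, yi = np.unique(y, return_inverse=True)
    k_total = yi.max() + 1
    if k_total < 2:
        return []
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    onehot = np.zeros((len(x) + 1, k_total))
    onehot[np.arange(1, len(x) + 1), yi[order]] = 1.0
    cum = np.cumsum(onehot, axis=0)  # cum[i] = class counts of xs[:i]

    cuts: list[float] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2:
            continue
        counts = cum[hi] - cum[lo]
        ent = _entropy_bits(counts)
        if ent == 0.0:
            continue
        # candidate split positions: boundaries between distinct x values
        pos = lo + 1 + np.nonzero(xs[lo + 1 : hi] > xs[lo : hi - 1])[0]
        if len(pos) == 0:
            continue
        left = cum[pos] - cum[lo]
        right = counts - left
        nl = left.sum(axis=1)
        nr = n - nl
        Hl = _segment_entropies(left)
        Hr = _segment_entropies(right)
        weighted = (nl * Hl + nr * Hr) / n
        best = int(np.argmin(weighted))  # ties -> leftmost cut
        gain = ent - weighted[best]
        k = int(np.sum(counts > 0))
        k1 = int(np.sum(left[best] > 0))
        k2 = int(np.sum(right[best] > 0))
        delta = np.log2(3.0**k - 2.0) - (k * ent - k1 * Hl[best] - k2 * Hr[best])
        if gain <= (np.log2(n - 1) + delta) / n:
            continue
        p = pos[best]
        cuts.append(0.5 * (xs[p - 1] + xs[p]))
        stack.append((lo, p))
        stack.append((p, hi))
    return sorted(cuts)


def _equal_frequency_cuts(x: np.ndarray, n_bins: int = 10) -> list[float]:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return sorted(set(float(q) for q in qs))


def info_gain(
    x: np.ndarray,
    y: np.ndarray,
    discretizer: str = "mdl",
    n_bins: int = 10,
) -> float:
    """Information gain of feature x about labels y, in bits.

    IG = H(y) - sum_bins p(bin) H(y | bin) over the discretizer's bins.
    0 <= IG <= H(y); an empty cut list gives IG = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if discretizer == "mdl":
        cuts = mdl_discretize(x, y)
    elif discretizer == "equal_frequency":
        cuts = _equal_frequency_cuts(x, n_bins)
    else:
        raise ParameterError(f"unknown discretizer {discretizer!r}")
    if not cuts:
        return 0.0
    _, yi = np.unique(y, return_inverse=True)
    k = yi.max() + 1
    h_y = _entropy_bits(np.bincount(yi, minlength=k).astype(float))
    bins = np.searchsorted(cuts, x, side="right")
    h_cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        h_cond += sel.mean() * _entropy_bits(
            np.bincount(yi[sel], minlength=k).astype(float)
        )
    return max(0.0, h_y - h_cond)


def rank_features(
    M: pd.DataFrame,
    k: int,
    discretizer: str = "mdl",
) -> list[str]:
    """Top-k feature names by information gain (descending).

    Ties are broken by the matrix's canonical column order so the ranking is
    a deterministic function of the matrix.
    """
    table = ranking_table(M, discretizer=discretizer)
    if k > len(table):
        raise ParameterError(f"k={k} exceeds the {len(table)} available features")
    return table["feature_name"].head(k).tolist()


def ranking_table(M: pd.DataFrame, discretizer: str = "mdl") -> pd.DataFrame:
    """Full ranking as a table: feature_name, info_gain_bits, rank."""
    cols = feature_columns_of(M)
    y = M["label"].to_numpy()
    if len(pd.unique(y)) < 2:
        raise ParameterError("feature ranking needs at least 2 classes")
    gains = np.array(
        [info_gain(M[c].to_numpy(), y, discretizer=discretizer) for c in cols]
    )
    order = np.lexsort((np.arange(len(cols)), -gains))  # IG desc, column order ties
    table = pd.DataFrame(
        {
            "feature_name": [cols[i] for i in order],
            "info_gain_bits": gains[order],
        }
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def feature_budget(
    n_subjects: int, n_unique_classes: int, ratio: int = 10
) -> int:
    """Feature ceiling from the 10:1 samples-to-features rule.

    Repetitions of a movement by the same subject do not count as unique
    samples, so the budget is floor(n_subjects * n_unique_classes / ratio);
    a non-linear kernel is conventionally granted a doubled budget (ratio 5).
    """
    if n_subjects < 1 or n_unique_classes < 1 or ratio < 1:
        raise ParameterError("inputs must be >= 1")
    return (n_subjects * n_unique_classes) // ratio
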
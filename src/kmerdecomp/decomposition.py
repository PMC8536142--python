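"""Pearson correlation of k-mer spectra and its decomposition.

Contributions are defined as shares of the covariance (the numerator of the
Pearson coefficient) on frequency vectors: for a word set S,

    c(S) = sum_{w in S} (x_w - mean x)(y_w - mean y) / sum_{all w} (...)

which is exactly additive over any partition of word space. Contributions
may be negative (anticorrelated words). Spectra of different k are refused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmers import (
    Spectrum,
    WordSet,
    encode_word,
    hamming1_neighbors,
)

_COV_EPS = 0.0  # exact-zero covariance is the only undefined case


@dataclass
class CorrelationResult:
    """Pearson r plus the per-word centered cross-products used downstream."""

    r: float
    k: int
    label_x: str
    label_y: str
    cross_products: np.ndarray  # (x_w - mean x)(y_w - mean y), frequency scale
    denominator: float  # sqrt(ss_x * ss_y)

    @property
    def covariance_sum(self) -> float:
        return float(self.cross_products.sum())


def _centered_frequencies(x: Spectrum, y: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    if x.k != y.k:
        raise ValueError(f"cannot compare spectra of different k ({x.k} vs {y.k})")
    fx = x.frequencies
    fy = y.frequencies
    return fx - fx.mean(), fy - fy.mean()


def pearson_correlation(x: Spectrum, y: Spectrum) -> CorrelationResult:
    """Standard Pearson r over the 4^k-dimensional frequency vectors."""
    dx, dy = _centered_frequencies(x, y)
    ssx = float(np.dot(dx, dx))
    ssy = float(np.dot(dy, dy))
    if ssx == 0 or ssy == 0:
        raise ValueError("zero variance in a spectrum: correlation undefined")
    cross = dx * dy
    denom = np.sqrt(ssx * ssy)
    return CorrelationResult(
        r=float(cross.sum() / denom),
        k=x.k,
        label_x=x.label,
        label_y=y.label,
        cross_products=cross,
        denominator=denom,
    )


def _as_indices(s: WordSet | Iterable[str], k: int) -> np.ndarray:
    if isinstance(s, WordSet):
        if s.k != k:
            raise ValueError(f"word set k={s.k} does not match spectra k={k}")
        return s.indices()
    idx = []
    for w in s:
        if len(w) != k:
            raise ValueError(f"word {w!r} has length {len(w)}, expected {k}")
        idx.append(encode_word(w))
    return np.asarray(sorted(set(idx)), dtype=np.int64)


def contribution(x: Spectrum, y: Spectrum, s: WordSet | Iterable[str]) -> float:
    """Fraction of the correlation covariance carried by the words in ``s``."""
    dx, dy = _centered_frequencies(x, y)
    total = float(np.dot(dx, dy))
    if total == _COV_EPS:
        raise ValueError("zero covariance: contribution undefined")
    idx = _as_indices(s, x.k)
    return float(np.dot(dx[idx], dy[idx]) / total)


def contribution_from_result(result: CorrelationResult, s: WordSet | Iterable[str]) -> float:
    total = result.covariance_sum
    if total == 0:
        raise ValueError("zero covariance: contribution undefined")
    idx = _as_indices(s, result.k)
    return float(result.cross_products[idx].sum() / total)


def mismatch_contribution(
    x: Spectrum, y: Spectrum, word: str, max_mm: int = 0
) -> float:
    """Contribution of a word alone (0 mm) or with its Hamming-1 ball (<=1 mm).

    The denominator (full covariance) is unchanged, so 0-mm and 1-mm values
    are directly comparable.
    """
    if len(word) != x.k:
        raise ValueError(f"word length {len(word)} does not match k={x.k}")
    if max_mm not in (0, 1):
        raise ValueError("max_mm must be 0 or 1")
    words = {word}
    if max_mm == 1:
        words |= hamming1_neighbors(word)
    return contribution(x, y, words)


def word_ranks(result: CorrelationResult) -> np.ndarray:
    """1-based rank of every word in descending cross-product order."""
    order = np.argsort(-result.cross_products, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, order.size + 1)
    return ranks


def contribution_ratio_table(
    x: Spectrum, y: Spectrum, words: Sequence[str]
) -> pd.DataFrame:
    """Per-word 0-mm / <=1-mm contributions, their ratio and the 0-mm rank.

    Rows whose 0-mm contribution is zero are flagged (``ratio`` NaN) rather
    than divided.
    """
    result = pearson_correlation(x, y)
    ranks = word_ranks(result)
    rows = []
    for w in words:
        c0 = contribution_from_result(result, [w])
        c1 = contribution_from_result(result, {w} | hamming1_neighbors(w))
        flagged = c0 == 0
        rows.append(
            {
                "word": w,
                "c0": c0,
                "c1": c1,
                "ratio": np.nan if flagged else c1 / c0,
                "rank": int(ranks[encode_word(w)]),
                "zero_c0": flagged,
            }
        )
    return pd.DataFrame(rows)


def grouped_contributions(
    x: Spectrum,
    y: Spectrum,
    groups: Sequence[WordSet],
    add_remainder: bool = False,
    remainder_name: str = "remaining",
) -> pd.DataFrame:
    """One contribution per word set; sets within one grouping must be disjoint."""
    seen: set[str] = set()
    for g in groups:
        overlap = seen & g.words
        if overlap:
            raise ValueError(
                f"overlapping word sets in grouping (e.g. {sorted(overlap)[:3]})"
            )
        seen |= g.words
    result = pearson_correlation(x, y)
    rows = [
        {
            "set": g.name,
            "n_words": len(g),
            "contribution": contribution_from_result(result, g),
        }
        for g in groups
    ]
    if add_remainder:
        rows.append(
            {
                "set": remainder_name,
                "n_words": 4**x.k - len(seen),
                "contribution": 1.0 - sum(r["contribution"] for r in rows),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MeanCorrelation:
    """Mean real-pair r minus mean reference r, with quadrature error."""

    group: str
    mean_real: float
    sd_real: float
    mean_reference: float
    sd_reference: float

    @property
    def difference(self) -> float:
        # may exceed 1: the reference mean can be negative
        return self.mean_real - self.mean_reference

    @property
    def error(self) -> float:
        return float(np.hypot(self.sd_real, self.sd_reference))


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([float(v) for v in values], dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def mean_correlation_with_reference(
    real: Sequence[float | CorrelationResult],
    reference: Sequence[float | CorrelationResult],
    group: str = "",
) -> MeanCorrelation:
    """Average r over genome pairs and subtract the model-reference mean."""
    if len(real) == 0:
        raise ValueError("no real correlation values")
    if len(reference) == 0:
        raise ValueError("no reference correlation values")
    real_vals = [v.r if isinstance(v, CorrelationResult) else v for v in real]
    ref_vals = [v.r if isinstance(v, CorrelationResult) else v for v in reference]
    mr, sr = _mean_sd(real_vals)
    mm, sm = _mean_sd(ref_vals)
    return MeanCorrelation(
        group=group, mean_real=mr, sd_real=sr, mean_reference=mm, sd_reference=sm
    )
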
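"""Strand-pattern classification and deviation-pattern rule engine.

classify_strand_pattern decides whether a tandem-repeat word's contribution
tracks its inverse complement, its shift sequence, both (ambiguous) or
neither (own). deviation_profile attributes single-mismatch occurrences of
an STR word to the substituted base; the rule engine predicts the expected
base ranking per family and rule_coverage summarizes how many observed
profiles the rules explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .kmers import (
    BASES,
    Spectrum,
    WordSet,
    minimal_period,
    reverse_complement,
    shift_word,
    str_words_b_le2,
)

CALL_INV_COMPL = "inv_compl"
CALL_SHIFT = "shift"
CALL_INV_COMPL_EQ_SHIFT = "inv_compl_eq_shift"
CALL_AMBIGUOUS = "ambiguous"
CALL_OWN = "own"


@dataclass(frozen=True)
class PatternCall:
    word: str
    call: str
    tol: float
    values: dict[str, float]  # word, revcomp, shift -> contribution


def _close(a: float, b: float, tol: float) -> bool:
    m = max(abs(a), abs(b))
    if m == 0:
        return True
    return abs(a - b) / m <= tol


def classify_strand_pattern(
    contributions: Mapping[str, float],
    word: str,
    b: int | None = None,
    tol: float = 0.25,
) -> PatternCall:
    """Classify a repeat word by which companion value it tracks.

    inv_compl when the word's value is close (relative difference <= tol) to
    its inverse complement but not its shift; shift for the converse;
    ambiguous when both are close; own when neither is. When inverse
    complement and shift coincide as strings (homoW/homoS at odd k) the call
    is structurally inv_compl_eq_shift.
    """
    if b is None:
        b = minimal_period(word)
    rc = reverse_complement(word)
    sh = shift_word(word, b)
    try:
        v_word = float(contributions[word])
        v_rc = float(contributions[rc])
        v_sh = float(contributions[sh])
    except KeyError as exc:
        raise ValueError(f"missing contribution value for {exc.args[0]!r}") from exc
    values = {word: v_word, rc: v_rc, sh: v_sh}
    if rc == sh:
        return PatternCall(word, CALL_INV_COMPL_EQ_SHIFT, tol, values)
    near_rc = _close(v_word, v_rc, tol)
    near_sh = _close(v_word, v_sh, tol)
    if near_rc and near_sh:
        call = CALL_AMBIGUOUS
    elif near_rc:
        call = CALL_INV_COMPL
    elif near_sh:
        call = CALL_SHIFT
    else:
        call = CALL_OWN
    return PatternCall(word, call, tol, values)


@dataclass
class DeviationProfile:
    """Distribution of substituted bases among single-mismatch occurrences."""

    word: str
    counts: dict[str, float]
    empty: bool = False

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {b: 0.0 for b in self.counts}
        return {b: 100.0 * c / t for b, c in self.counts.items()}

    @property
    def ranking(self) -> tuple[str, ...]:
        """Bases in descending percentage order (alphabetical tie-break)."""
        return tuple(sorted(self.counts, key=lambda b: (-self.counts[b], b)))


def deviation_profile(
    spectrum: Spectrum,
    word: str,
    exclude: WordSet | set[str] | None = None,
) -> DeviationProfile:
    """Attribute each Hamming-1 neighbor's count to its substituted base.

    Neighbors that are themselves members of the excluded family set
    (default: the 16 b<=2 STR words) are skipped to avoid self-counting.
    """
    k = spectrum.k
    if len(word) != k:
        raise ValueError(f"word length {len(word)} does not match spectrum k={k}")
    if exclude is None:
        excl = str_words_b_le2(k).words
    elif isinstance(exclude, WordSet):
        excl = exclude.words
    else:
        excl = set(exclude)
    letters = set(word)
    if len(letters) == 1:
        # poly word: only the 3 other bases are observable as substitutions
        counts = {b: 0.0 for b in BASES if b not in letters}
    else:
        counts = {b: 0.0 for b in BASES}
    for i, ch in enumerate(word):
        for sub in BASES:
            if sub == ch:
                continue
            neighbor = word[:i] + sub + word[i + 1 :]
            if neighbor in excl:
                continue
            counts[sub] = counts.get(sub, 0.0) + float(spectrum.count_of(neighbor))
    total = sum(counts.values())
    return DeviationProfile(word=word, counts=counts, empty=(total == 0))


@dataclass(frozen=True)
class AmbiguityFlags:
    ambiguous: bool
    strong_tendency: bool


STRONG_TENDENCY_PCT = 42.5


def classify_ambiguity(
    profile: DeviationProfile, family_type: str | None = None
) -> AmbiguityFlags:
    """Band-based ambiguity call plus strong-tendency flag.

    poly families: ambiguous iff all three percentages lie in [30, 40].
    b=2 families: ambiguous iff all four lie in [20, 30] with at most one
    value rounding to 30. A strong tendency is any value > 42.5.
    """
    if family_type is None:
        family_type = "poly" if minimal_period(profile.word) == 1 else "duo"
    if family_type not in ("poly", "duo"):
        raise ValueError(f"unknown family type {family_type!r}")
    vals = list(profile.percentages.values())
    strong = any(v > STRONG_TENDENCY_PCT for v in vals)
    if profile.empty:
        return AmbiguityFlags(ambiguous=False, strong_tendency=False)
    if family_type == "poly":
        ambiguous = all(30.0 <= v <= 40.0 for v in vals)
    else:
        in_band = all(20.0 <= v <= 30.0 for v in vals)
        at_thirty = sum(1 for v in vals if round(v) == 30)
        ambiguous = in_band and at_thirty <= 1
    return AmbiguityFlags(ambiguous=ambiguous, strong_tendency=strong)


@dataclass(frozen=True)
class RuleExpectation:
    """Expected ranked deviation bases for an STR family word (data-free)."""

    word: str
    ranks: tuple[str, ...]
    rules_applied: tuple[int, ...]


_W = {"A", "T"}
_S = {"C", "G"}
# rank-1 base for a leading S letter: G pairs with A (both purines, R),
# C pairs with T (both pyrimidines, Y)
_S_TO_W = {"G": "A", "C": "T"}
_W_TO_S = {"A": "G", "T": "C"}


def expected_deviation_ranking(word: str) -> RuleExpectation:
    """Apply the three ranking rules, in order, to a b<=2 STR word.

    Rule 1 - the top deviation rank(s) are W bases: for poly words the
    deterministic W candidate (polyA -> T, polyT -> A, polyG -> A,
    polyC -> T); for unit-length-2 words ranks 1-2 are {A, T}, led by the
    word's leading letter when it is W, otherwise by the W partner of the
    leading S letter (G -> A, C -> T).
    Rule 2 - for homoR/homoY and polyW the second rank is the class-matching
    S base (R -> G, Y -> C).
    Rule 3 - for polyW ranks 1 and 2 are swapped.
    """
    letters = set(word)
    period = minimal_period(word)
    if period > 2 or len(letters) > 2:
        raise ValueError(f"{word!r} is outside the rule domain (b <= 2 STR words)")
    applied: list[int] = []
    if period == 1:
        base = word[0]
        first = "T" if base in ("A", "C") else "A"
        ranks = [first]
        applied.append(1)
        if base in _W:  # polyW: rules 2 and 3
            ranks.append(_W_TO_S[base])
            applied.append(2)
            ranks[0], ranks[1] = ranks[1], ranks[0]
            applied.append(3)
        return RuleExpectation(word, tuple(ranks), tuple(applied))
    lead = word[0]
    first = lead if lead in _W else _S_TO_W[lead]
    second = "A" if first == "T" else "T"
    ranks = [first, second]
    applied.append(1)
    if letters in ({"A", "G"}, {"C", "T"}):  # homoR / homoY
        ranks[1] = "G" if letters == {"A", "G"} else "C"
        applied.append(2)
    return RuleExpectation(word, tuple(ranks), tuple(applied))


@dataclass
class RuleCoverage:
    n: int
    covered: float
    ambiguous: float
    uncovered: float
    details: list[dict] = field(default_factory=list)


def rule_coverage(
    profiles: Sequence[DeviationProfile],
    flags: Sequence[AmbiguityFlags] | None = None,
) -> RuleCoverage:
    """Fractions of profiles matching rule expectations / ambiguous / neither."""
    if len(profiles) == 0:
        raise ValueError("no profiles given")
    if flags is None:
        flags = [classify_ambiguity(p) for p in profiles]
    n_cov = n_amb = n_unc = 0
    details = []
    for p, f in zip(profiles, flags):
        expectation = expected_deviation_ranking(p.word)
        status: str
        if f.ambiguous:
            status = "ambiguous"
            n_amb += 1
        elif p.ranking[: len(expectation.ranks)] == expectation.ranks:
            status = "covered"
            n_cov += 1
        else:
            status = "uncovered"
            n_unc += 1
        details.append(
            {
                "word": p.word,
                "status": status,
                "observed": p.ranking,
                "expected": expectation.ranks,
            }
        )
    n = len(profiles)
    return RuleCoverage(
        n=n,
        covered=n_cov / n,
        ambiguous=n_amb / n,
        uncovered=n_unc / n,
        details=details,
    )


def bipartition_subsets(
    matrix: np.ndarray,
    threshold: float = 0.5,
    method: str = "threshold",
    max_iter: int = 100,
) -> np.ndarray:
    """Split genomes into a high-correlation pool (#S1) and the rest (#S2).

    Algorithmic stand-in for a visual call on a genome-genome correlation
    heatmap. ``threshold`` method: seed with the genome of highest mean
    off-diagonal correlation, then repeatedly admit genomes whose mean
    correlation against the current pool exceeds the threshold.
    ``agglomeration``: average-linkage 2-clustering on 1 - r. Returns a
    boolean array, True = #S1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if np.isnan(m).any():
        raise ValueError("matrix contains NaN")
    n = m.shape[0]
    if n == 1:
        return np.array([True])
    if method == "threshold":
        offdiag_mean = (m.sum(axis=1) - np.diag(m)) / (n - 1)
        members = np.zeros(n, dtype=bool)
        members[int(np.argmax(offdiag_mean))] = True
        for _ in range(max_iter):
            pool = np.nonzero(members)[0]
            score = np.empty(n)
            for i in range(n):
                others = pool[pool != i]
                if others.size == 0:
                    score[i] = np.inf  # lone seed stays
                else:
                    score[i] = m[i, others].mean()
            new = score > threshold
            new[int(np.argmax(offdiag_mean))] |= members.sum() == 1
            if np.array_equal(new, members):
                break
            members = new
            if not members.any():
                break
        return members
    if method == "agglomeration":
        d = 1.0 - (m + m.T) / 2.0
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
        z = linkage(squareform(d, checks=False), method="average")
        labels = fcluster(z, t=2, criterion="maxclust")
        means = []
        for lab in (1, 2):
            idx = np.nonzero(labels == lab)[0]
            if idx.size < 2:
                means.append(-np.inf)
            else:
                sub = m[np.ix_(idx, idx)]
                means.append((sub.sum() - np.trace(sub)) / (idx.size * (idx.size - 1)))
        s1_label = 1 if means[0] >= means[1] else 2
        return labels == s1_label
    raise ValueError(f"unknown method {method!r}")
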
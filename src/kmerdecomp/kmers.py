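"""k-mer word algebra.

Spectra of overlapping k-mer windows counted on a single strand, reverse
complements, tandem-repeat shift sequences, STR word enumeration by minimal
repeat-unit length, extended-base-code word families, Hamming-1
neighborhoods and G+C word bins.

Words are encoded as base-4 integers with A=0, C=1, G=2, T=3, most
significant digit first, so the lexicographic order of words equals the
numeric order of codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
MAX_K = 11

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> base code lookup; anything that is not A/C/G/T (either case) maps to -1
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_word(word: str) -> int:
    """Return the integer code of a word over ACGT."""
    code = 0
    for ch in word:
        b = _ENCODE_LUT[ord(ch)]
        if b < 0:
            raise ValueError(f"word {word!r} contains non-ACGT letter {ch!r}")
        code = code * 4 + int(b)
    return code


def decode_word(code: int, k: int) -> str:
    """Inverse of :func:`encode_word` for words of length ``k``."""
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    letters = []
    for _ in range(k):
        letters.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(letters))


def all_words(k: int) -> list[str]:
    return [decode_word(i, k) for i in range(4**k)]


def reverse_complement(word: str) -> str:
    """Inverse complement of a word (single-strand convention elsewhere)."""
    for ch in word:
        if _ENCODE_LUT[ord(ch)] < 0:
            raise ValueError(f"non-ACGT letter {ch!r} in {word!r}")
    return word.translate(_COMPLEMENT)[::-1].upper()


def shift_word(word: str, b: int) -> str:
    """Shift sequence of a tandem-repeat word with repeat-unit length ``b``.

    The word must be the length-k prefix of an infinite repeat of its first
    ``b`` letters; the result is the length-k prefix of the same infinite
    repeat read one position later (a cyclic rotation of the unit).
    """
    k = len(word)
    if not 1 <= b <= k:
        raise ValueError(f"unit length {b} invalid for word of length {k}")
    for i in range(b, k):
        if word[i] != word[i - b]:
            raise ValueError(f"{word!r} is not periodic with unit length {b}")
    unit = word[:b]
    rotated = unit[1:] + unit[0]
    return (rotated * (k // b + 1))[:k]


def minimal_period(word: str) -> int:
    """Smallest p such that the word is a prefix of an infinite p-periodic repeat."""
    k = len(word)
    for p in range(1, k + 1):
        if all(word[i] == word[i - p] for i in range(p, k)):
            return p
    return k  # unreachable: p = k always holds


@dataclass(frozen=True)
class WordSet:
    """A named set of equal-length words with family metadata."""

    name: str
    k: int
    words: frozenset[str]
    family: str | None = None
    unit_length: int | None = None

    def __post_init__(self) -> None:
        for w in self.words:
            if len(w) != self.k:
                raise ValueError(
                    f"word set {self.name!r}: {w!r} has length {len(w)}, expected {self.k}"
                )

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __iter__(self):
        return iter(sorted(self.words))

    def indices(self) -> np.ndarray:
        """Sorted integer codes of the member words."""
        return np.array(sorted(encode_word(w) for w in self.words), dtype=np.int64)

    def union(self, other: "WordSet", name: str | None = None) -> "WordSet":
        if other.k != self.k:
            raise ValueError("cannot union word sets of different k")
        return WordSet(
            name=name or f"{self.name}|{other.name}",
            k=self.k,
            words=self.words | other.words,
            family=self.family if self.family == other.family else None,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "k": self.k,
            "words": sorted(self.words),
            "family": self.family,
            "unit_length": self.unit_length,
        }


def word_sets_to_json(sets: Iterable[WordSet], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in sets], indent=1))


def enumerate_str_words(k: int, b: int) -> WordSet:
    """All k-mers whose minimal repeat-unit length is exactly ``b``.

    A word qualifies when it is the length-k prefix of an infinite repeat of
    a length-``b`` unit and of no shorter unit; b=1 gives 4 words, b=2 gives
    12 for any k >= 3.
    """
    if b < 1:
        raise ValueError("unit length must be >= 1")
    if b > k:
        raise ValueError(f"unit length {b} exceeds word length {k}")
    words = set()
    for code in range(4**b):
        unit = decode_word(code, b)
        if minimal_period(unit * 2) < b:  # unit itself reducible
            continue
        word = (unit * (k // b + 1))[:k]
        if minimal_period(word) == b:
            words.add(word)
    return WordSet(
        name=f"b{b}", k=k, words=frozenset(words), family="str", unit_length=b
    )


def str_words_b_le2(k: int) -> WordSet:
    """The 16 tandem-repeat words with repeat-unit length <= 2."""
    s = enumerate_str_words(k, 1).union(enumerate_str_words(k, 2), name="b<=2")
    return WordSet(name="b<=2", k=k, words=s.words, family="str")


#: extended base code: two-letter base classes
BASE_CLASSES: Mapping[str, tuple[str, str]] = {
    "W": ("A", "T"),
    "S": ("C", "G"),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}


def _repeat(unit: str, k: int) -> str:
    return (unit * (k // len(unit) + 1))[:k]


def word_family_sets(k: int) -> dict[str, WordSet]:
    """Named poly/homo word families over the extended base code.

    polyA..polyT are homopolymer singletons; polyW/polyS pair them by base
    class. homoW/S/R/Y/K/M each hold the two unit-length-2 repeat words over
    the indicated two-base class, e.g. homoR = {(AG)n, (GA)n}.
    """
    if k < 3:
        raise ValueError("family sets require k >= 3")
    sets: dict[str, WordSet] = {}
    for base in BASES:
        sets[f"poly{base}"] = WordSet(
            f"poly{base}", k, frozenset({base * k}), family="poly", unit_length=1
        )
    for cls in ("W", "S"):
        a, b = BASE_CLASSES[cls]
        sets[f"poly{cls}"] = WordSet(
            f"poly{cls}", k, frozenset({a * k, b * k}), family="poly", unit_length=1
        )
    for cls, (a, b) in BASE_CLASSES.items():
        sets[f"homo{cls}"] = WordSet(
            f"homo{cls}",
            k,
            frozenset({_repeat(a + b, k), _repeat(b + a, k)}),
            family="homo",
            unit_length=2,
        )
    return sets


def hamming1_neighbors(word: str) -> set[str]:
    """All words at Hamming distance exactly 1 (3k of them; excludes the word)."""
    for ch in word:
        if _ENCODE_LUT[ord(ch)] < 0:
            raise ValueError(f"non-ACGT letter {ch!r} in {word!r}")
    out = set()
    for i, ch in enumerate(word):
        for sub in BASES:
            if sub != ch:
                out.add(word[:i] + sub + word[i + 1 :])
    return out


def gc_fraction_of_words(k: int) -> np.ndarray:
    """G+C letter fraction for every word code 0..4^k-1."""
    counts = np.zeros(4**k, dtype=np.int16)
    idx = np.arange(4**k, dtype=np.int64)
    for j in range(k):
        digit = (idx >> (2 * (k - 1 - j))) & 3
        counts += (digit == 1) | (digit == 2)  # C or G
    return counts / k


def gc_bin_sets(k: int, edges: Sequence[float]) -> list[WordSet]:
    """Partition word space into G+C-content bins.

    ``edges`` are percentages in (0, 100]; bin i covers
    [edges[i-1], edges[i]) with the leading bin starting at 0 and a trailing
    bin [edges[-1], 100] when edges[-1] < 100. Bins are disjoint and
    exhaustive.
    """
    edges = list(edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if edges and (edges[0] <= 0 or edges[-1] > 100):
        raise ValueError("bin edges must lie in (0, 100]")
    gc_pct = gc_fraction_of_words(k) * 100.0
    assignment = np.searchsorted(np.asarray(edges, dtype=float), gc_pct, side="right")
    bounds = [0.0, *edges]
    if not edges or edges[-1] < 100:
        bounds.append(100.0)
    # the trailing bin includes its upper bound (100% G+C words)
    assignment = np.minimum(assignment, len(bounds) - 2)
    sets = []
    for i in range(len(bounds) - 1):
        members = frozenset(
            decode_word(int(c), k) for c in np.nonzero(assignment == i)[0]
        )
        lo, hi = bounds[i], bounds[i + 1]
        name = f"S_GC<{hi:g}%" if i == 0 else f"S_{lo:g}%<=GC<{hi:g}%"
        if i == len(bounds) - 2:
            name = f"S_GC>={lo:g}%" if i > 0 else "S_all"
        sets.append(WordSet(name, k, members, family="gc_bin"))
    return sets


@dataclass
class Spectrum:
    """Counts of all 4^k words of one strand of a sequence set.

    ``counts[i]`` is the number of valid windows equal to ``decode_word(i, k)``;
    ``total_windows`` is the number of counted windows. Expected (model)
    spectra may carry fractional counts.
    """

    k: int
    counts: np.ndarray
    total_windows: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (4**self.k,):
            raise ValueError(
                f"counts must have 4^k = {4 ** self.k} entries, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.isclose(float(self.counts.sum()), float(self.total_windows), rtol=1e-9, atol=1e-6):
            raise ValueError(
                f"counts sum {self.counts.sum()} != total_windows {self.total_windows}"
            )

    @property
    def frequencies(self) -> np.ndarray:
        """counts / total_windows; all-zero when the spectrum is empty."""
        if self.total_windows == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(self.total_windows)

    def count_of(self, word: str) -> float:
        return self.counts[encode_word(word)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\ttotal_windows={self.total_windows}\tlabel={self.label}\n")
            for i, c in enumerate(self.counts):
                fh.write(f"{decode_word(i, self.k)}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Spectrum":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").split("\t") if "=" in item
            )
            k = int(meta["k"])
            total = float(meta["total_windows"])
            counts = np.zeros(4**k)
            for line in fh:
                word, c = line.rstrip("\n").split("\t")
                counts[encode_word(word)] = float(c)
        if counts.sum() == np.floor(counts).sum():
            counts = counts.astype(np.int64)
            total = int(total)
        return cls(k=k, counts=counts, total_windows=total, label=meta.get("label", ""))


def _encode_sequence(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def compute_spectrum(
    sequences: Iterable[str | bytes], k: int, label: str = ""
) -> Spectrum:
    """Count all length-k windows (step 1, one strand) over ACGT only.

    Windows containing any other letter are skipped, and windows never span
    two sequences.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    counts = np.zeros(4**k, dtype=np.int64)
    total = 0
    for seq in sequences:
        enc = _encode_sequence(seq)
        n = len(enc)
        if n < k:
            continue
        m = n - k + 1
        codes = np.zeros(m, dtype=np.int64)
        valid = np.ones(m, dtype=bool)
        for j in range(k):
            b = enc[j : j + m]
            valid &= b >= 0
            codes = codes * 4 + np.where(b < 0, 0, b).astype(np.int64)
        codes = codes[valid]
        counts += np.bincount(codes, minlength=4**k)
        total += codes.size
    return Spectrum(k=k, counts=counts, total_windows=total, label=label)
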
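import numpy as np
import pytest

from kmerdecomp.kmers import BASES, Spectrum, encode_word


def naive_spectrum(sequences, k):
    """Independent substring-scan oracle for compute_spectrum."""
    counts = np.zeros(4**k, dtype=np.int64)
    total = 0
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(ch not in BASES for ch in window):
                continue
            counts[encode_word(window)] += 1
            total += 1
    return Spectrum(k=k, counts=counts, total_windows=total)


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def spectrum_from_counts(k, count_map, pad_word=None, pad=0):
    """Build a Spectrum with the given word counts (plus optional padding)."""
    counts = np.zeros(4**k, dtype=np.int64)
    for word, c in count_map.items():
        counts[encode_word(word)] = c
    if pad_word is not None:
        counts[encode_word(pad_word)] += pad
    return Spectrum(k=k, counts=counts, total_windows=int(counts.sum()))
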
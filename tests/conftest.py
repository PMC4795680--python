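import itertools

import numpy as np
import pytest
from hypothesis import settings

import sitefree as sf

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def enumerate_word_scores(pwm: sf.PWM, bg: sf.Background):
    """Independent brute-force oracle: score and probability of all 4**L words.

    Enumerates words explicitly and sums column weights one base at a time;
    shares no code path with the convolution-based distribution.
    """
    probs = bg.probs
    scores, word_probs = [], []
    for word in itertools.product(range(4), repeat=pwm.length):
        s = sum(pwm.weights[b, j] for j, b in enumerate(word))
        p = 1.0
        for b in word:
            p *= probs[b]
        scores.append(s)
        word_probs.append(p)
    return np.array(scores), np.array(word_probs)


def naive_scan_pwm(seq: str, pwm: sf.PWM, threshold: float, both_strands=True):
    """Per-window rescoring oracle for PWM scanning."""
    L = pwm.length
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if pwm.score_word(window) >= threshold - 1e-9:
            hits.append((i, i + L, "+"))
        if both_strands and pwm.score_word(sf.revcomp(window)) >= threshold - 1e-9:
            hits.append((i, i + L, "-"))
    return sorted(hits)


def naive_scan_exact(seq: str, patterns, both_strands=True):
    """Sliding-window string-comparison oracle for exact-site scanning."""
    hits = []
    for pattern in patterns:
        for strand, words in (
            ("+", sf.expand_iupac(pattern)),
            ("-", sf.expand_iupac(sf.revcomp(pattern))),
        ):
            if strand == "-" and not both_strands:
                continue
            word_set = set(words)
            k = len(pattern)
            for i in range(len(seq) - k + 1):
                if seq[i : i + k] in word_set:
                    hits.append((i, i + k, strand))
    return sorted(hits)


@pytest.fixture
def toy_exact_library():
    """Three exact 6-mer sites."""
    return sf.MotifLibrary(
        exact_sets=(sf.ExactSiteSet("toy_sites", ("GAATTC", "CAGGTA", "TTAACC")),)
    )
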
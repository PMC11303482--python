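import numpy as np
import pytest

from atacmotif import (
    BackgroundModel,
    GenomeSequence,
    build_pwm,
    calibrate_threshold,
)
from atacmotif.simulate import generate_figure2h_fixture, sox9_synthetic_pcm


@pytest.fixture(scope="session")
def sox9_pwm():
    """Sharp SOX9-like PWM calibrated at the default alpha, uniform bg."""
    return calibrate_threshold(
        build_pwm(sox9_synthetic_pcm(), BackgroundModel.uniform()), alpha=1e-4
    )


@pytest.fixture(scope="session")
def figure2h():
    """The deterministic integration fixture (built once per session)."""
    return generate_figure2h_fixture(seed=42)


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
    return GenomeSequence({"chr1": seq})


def naive_scan(pwm, seq):
    """Per-window rescoring loop: the independent oracle for the scanner."""
    from atacmotif import reverse_complement

    L = pwm.length
    hits = []
    for s in range(len(seq) - L + 1):
        w = seq[s : s + L]
        if "N" in w:
            continue
        for strand, word in (("+", w), ("-", reverse_complement(w))):
            score = sum(
                pwm.weights["ACGT".index(b), i] for i, b in enumerate(word)
            )
            if score >= pwm.threshold:
                hits.append((s, strand, score))
    return hits


def enumerate_tail(weights, bg, threshold):
    """Exact P(score >= threshold) for a random word, by full enumeration."""
    L = weights.shape[1]
    grids = np.meshgrid(*([np.arange(4)] * L), indexing="ij")
    words = np.stack([g.ravel() for g in grids])  # L x 4^L
    scores = weights[words, np.arange(L)[:, None]].sum(axis=0)
    probs = bg.q[words].prod(axis=0)
    return float(probs[scores >= threshold].sum())
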
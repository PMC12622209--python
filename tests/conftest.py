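import numpy as np
import pytest

from repalign import JudgmentSet, TripletJudgment


def J(a, b, c, odd):
    return TripletJudgment(a, b, c, odd)


@pytest.fixture
def abc_judgment():
    return JudgmentSet.from_judgments([J("a", "b", "c", "c")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_judgment_set(rng, n_items=8, n_trials=50):
    """Uniform random triples with uniform random odd choices."""
    items = [f"v{k}" for k in range(n_items)]
    judgments = []
    for _ in range(n_trials):
        a, b, c = rng.choice(n_items, size=3, replace=False)
        odd = rng.choice([a, b, c])
        judgments.append(J(items[a], items[b], items[c], items[odd]))
    return JudgmentSet(judgments, items)
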
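import numpy as np
import pytest

from abstention import LabeledScores, ScoreSimConfig, simulate_scores


@pytest.fixture
def make_scores():
    """Factory for seeded Beta-mixture score sets (default: imbalanced, overlapping)."""

    def _make(seed: int, n: int = 200, positive_fraction: float = 0.2,
              neg_shape=(2.0, 5.0), pos_shape=(5.0, 2.0)) -> LabeledScores:
        cfg = ScoreSimConfig(n=n, positive_fraction=positive_fraction,
                             neg_shape=neg_shape, pos_shape=pos_shape, seed=seed)
        s = simulate_scores(cfg)
        # guard against degenerate single-class draws at small n
        if s.labels.sum() in (0, len(s)):
            rng = np.random.default_rng(seed)
            labels = s.labels.copy()
            labels[rng.integers(len(s))] = 1 - labels[0]
            s = LabeledScores(s.scores, labels)
        return s

    return _make
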
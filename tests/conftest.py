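import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (pure-Python enumeration, no shared code
# with the implementation under test).
# ---------------------------------------------------------------------------

def brute_match_counts(x, m, r):
    """O(N^2) template matching by direct enumeration, plus overlap counts.

    Returns (B, A, K_B, K_A) with both template lengths counted over start
    indices 0..N-m-1, strict d < r, self-matches excluded.
    """
    N = len(x)
    n_templates = N - m
    pairs_m, pairs_m1 = [], []
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + a] - x[j + a]) for a in range(m)) < r:
                pairs_m.append((i, j))
                if max(abs(x[i + a] - x[j + a]) for a in range(m + 1)) < r:
                    pairs_m1.append((i, j))

    def overlapping(pairs, tlen):
        count = 0
        for p in range(len(pairs)):
            i1, j1 = pairs[p]
            cover1 = set(range(i1, i1 + tlen)) | set(range(j1, j1 + tlen))
            for q in range(p + 1, len(pairs)):
                i2, j2 = pairs[q]
                cover2 = set(range(i2, i2 + tlen)) | set(range(j2, j2 + tlen))
                if cover1 & cover2:
                    count += 1
        return count

    return (
        len(pairs_m),
        len(pairs_m1),
        overlapping(pairs_m, m),
        overlapping(pairs_m1, m + 1),
    )


def brute_sampen(x, m, r):
    """SampEn by enumeration; None when undefined (A or B zero)."""
    import math

    B, A, _, _ = brute_match_counts(x, m, r)
    if B == 0 or A == 0:
        return None
    return -math.log(A / B)


def brute_apen(x, m, r):
    """ApEn by enumeration with self-matches included (Pincus convention)."""
    import math

    N = len(x)

    def phi(k):
        n_templates = N - k + 1
        total = 0.0
        for i in range(n_templates):
            cnt = 0
            for j in range(n_templates):
                if max(abs(x[i + a] - x[j + a]) for a in range(k)) < r:
                    cnt += 1
            total += math.log(cnt / n_templates)
        return total / n_templates

    return phi(m) - phi(m + 1)
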
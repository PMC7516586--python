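"""Naive reference implementations transcribed literally from the definitions.

These are deliberately plain Python loops, independent of the package's
vectorized implementations, and serve as oracles in equivalence tests.
"""

import math


def apen_naive(u, m: int, r: float) -> float:
    """Approximate entropy by direct triple-loop transcription.

    C_i^m = #{j : max_k |u(i+k) - u(j+k)| <= r} / (N - m + 1), self-matches
    included; Phi^m = mean log C_i^m; ApEn = Phi^m - Phi^{m+1}.
    """
    u = list(map(float, u))
    n_total = len(u)

    def phi(q: int) -> float:
        count = n_total - q + 1
        patterns = [u[i : i + q] for i in range(count)]
        total = 0.0
        for i in range(count):
            matches = 0
            for j in range(count):
                d = max(abs(patterns[i][k] - patterns[j][k]) for k in range(q))
                if d <= r:
                    matches += 1
            total += math.log(matches / count)
        return total / count

    return phi(m) - phi(m + 1)


def fuzen_naive(u, m: int, n: float, r: float) -> float:
    """Fuzzy entropy by direct transcription.

    Patterns are de-meaned; D_ij = exp(-d_ij**n / r) with Chebyshev d;
    phi^q = mean_i [ mean_{j != i} D_ij ] over i = 1..N-q;
    FuzEn = ln phi^m - ln phi^{m+1}.
    """
    u = list(map(float, u))
    n_total = len(u)

    def phi(q: int) -> float:
        count = n_total - q
        patterns = []
        for i in range(count):
            window = u[i : i + q]
            base = sum(window) / q
            patterns.append([x - base for x in window])
        total = 0.0
        for i in range(count):
            sim = 0.0
            for j in range(count):
                if j == i:
                    continue
                d = max(abs(patterns[i][k] - patterns[j][k]) for k in range(q))
                sim += math.exp(-(d**n) / r)
            total += sim / (count - 1)
        return total / count

    return math.log(phi(m)) - math.log(phi(m + 1))
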
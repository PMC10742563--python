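"""Independent brute-force oracles for the entropy/recurrence measures.

Deliberately plain O(n^2) loop implementations kept separate from the
package so that oracle and implementation cannot share a defect.
"""

import numpy as np


def naive_sampen(x, m, r):
    n = len(x)
    N = n - m
    tm = [x[i:i + m] for i in range(N)]
    tm1 = [x[i:i + m + 1] for i in range(N)]
    b = a = 0
    for i in range(N):
        for j in range(i + 1, N):
            if max(abs(tm[i] - tm[j])) <= r:
                b += 1
            if max(abs(tm1[i] - tm1[j])) <= r:
                a += 1
    return -np.log(a / b)


def naive_apen(x, m, r):
    def phi(mm):
        n = len(x)
        N = n - mm + 1
        tpl = [x[i:i + mm] for i in range(N)]
        total = 0.0
        for i in range(N):
            c = sum(1 for j in range(N) if max(abs(tpl[i] - tpl[j])) <= r)
            total += np.log(c / N)
        return total / N

    return phi(m) - phi(m + 1)


def naive_fuzzen(x, m, r, grad):
    def phi(mm):
        N = len(x) - m
        tpl = [x[i:i + mm] - np.mean(x[i:i + mm]) for i in range(N)]
        tot = 0.0
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                d = max(abs(tpl[i] - tpl[j]))
                tot += np.exp(-((d / r) ** grad))
        return tot / (N * (N - 1))

    return -np.log(phi(m + 1) / phi(m))


def naive_rqa_entr(x, m, tau, eps_frac, lmin):
    N = len(x) - (m - 1) * tau
    E = np.array([x[i:i + (m - 1) * tau + 1:tau] for i in range(N)])
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            D[i, j] = max(abs(E[i] - E[j]))
    R = D < eps_frac * D.max()
    lengths = []
    for k in range(1, N):
        run = 0
        for i in range(N - k):
            if R[i, i + k]:
                run += 1
            else:
                if run >= lmin:
                    lengths.append(run)
                run = 0
        if run >= lmin:
            lengths.append(run)
    if not lengths:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def ar1_fixture(n=200, rho=0.9, scale=0.3, seed=42):
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n + 20)
    x = np.empty(n + 20)
    x[0] = 0.0
    for i in range(1, n + 20):
        x[i] = rho * x[i - 1] + scale * e[i]
    return x[20:]
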
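"""Independent brute-force re-implementations of every test statistic.

Each function is a direct, loop-level transcription of the displayed
formulas, kept deliberately naive (explicit sums, no shared helpers with
the package) so it can serve as an independent oracle for the vectorized
implementations.
"""

import math


def mean(v):
    return sum(v) / len(v)


def svar(v):
    m = mean(v)
    return sum((x - m) ** 2 for x in v) / (len(v) - 1)


def median(v):
    s = sorted(v)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def student_t_stat(g1, g2):
    n1, n2 = len(g1), len(g2)
    sp2 = ((n1 - 1) * svar(g1) + (n2 - 1) * svar(g2)) / (n1 + n2 - 2)
    return (1.0 / n1 + 1.0 / n2) ** -0.5 * (mean(g1) - mean(g2)) / math.sqrt(sp2)


def welch_t_stat(g1, g2):
    n1, n2 = len(g1), len(g2)
    return (mean(g1) - mean(g2)) / math.sqrt(svar(g1) / n1 + svar(g2) / n2)


def welch_df(g1, g2):
    n1, n2 = len(g1), len(g2)
    v1, v2 = svar(g1), svar(g2)
    return (v1 / n1 + v2 / n2) ** 2 / (
        v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1))
    )


def stsd_stat(g1, g2):
    s1, s2 = math.sqrt(svar(g1)), math.sqrt(svar(g2))
    return student_t_stat([x / s1 for x in g1], [x / s2 for x in g2])


def f_stat(g1, g2):
    return svar(g1) / svar(g2)


def _spread_stat(g1, g2, center):
    n1, n2 = len(g1), len(g2)
    c1, c2 = center(g1), center(g2)
    z1 = [abs(x - c1) for x in g1]
    z2 = [abs(x - c2) for x in g2]
    zb1, zb2 = mean(z1), mean(z2)
    zbar = (sum(z1) + sum(z2)) / (n1 + n2)
    num = (n1 + n2 - 2) * (n1 * (zb1 - zbar) ** 2 + n2 * (zb2 - zbar) ** 2)
    den = sum((z - zb1) ** 2 for z in z1) + sum((z - zb2) ** 2 for z in z2)
    return num / den


def levene_stat(g1, g2):
    return _spread_stat(g1, g2, mean)


def brown_forsythe_stat(g1, g2):
    return _spread_stat(g1, g2, median)


def lrt_stat(g1, g2):
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    v1m = (n1 - 1) / n1 * svar(g1)
    v2m = (n2 - 1) / n2 * svar(g2)
    mu = (sum(g1) + sum(g2)) / n
    vpm = (sum((x - mu) ** 2 for x in g1) + sum((x - mu) ** 2 for x in g2)) / n
    lam = (v1m ** (n1 / 2) * v2m ** (n2 / 2)) / vpm ** (n / 2)
    return -2.0 * math.log(lam)


def fisher_stat(p_mean, p_var):
    return -2.0 * (math.log(p_mean) + math.log(p_var))


def chi2_4_sf(x):
    # closed-form survival of chi-square with 4 df
    return math.exp(-x / 2.0) * (1.0 + x / 2.0)


def chi2_2_sf(x):
    return math.exp(-x / 2.0)


def bh_stepup(p):
    """Benjamini-Hochberg adjusted values by literal step-up with cummin."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
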
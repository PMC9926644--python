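"""Independent, loop-wise reference implementations used only by tests.

Deliberately written with plain Python loops and the ``math`` module —
no shared code with the package's vectorised path — so agreement between
the two is a real cross-check rather than a tautology.
"""

import math


def _mean(xs):
    return sum(xs) / len(xs)


def _sample_sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def oracle_effect_sizes(values, labels):
    """Per-variable Cohen's d, average d-bar and grand d_g, by brute force.

    values : list of rows (lists of floats); labels : list of hashables.
    Class order is sorted label order; per-variable d is class1 - class2.
    """
    classes = sorted(set(labels))
    assert len(classes) == 2
    rows1 = [row for row, lab in zip(values, labels) if lab == classes[0]]
    rows2 = [row for row, lab in zip(values, labels) if lab == classes[1]]
    n1, n2 = len(rows1), len(rows2)
    n_vars = len(values[0])

    d_per_var = []
    means1, means2, sds1, sds2 = [], [], [], []
    for j in range(n_vars):
        col1 = [row[j] for row in rows1]
        col2 = [row[j] for row in rows2]
        m1, m2 = _mean(col1), _mean(col2)
        s1, s2 = _sample_sd(col1), _sample_sd(col2)
        pooled = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        d_per_var.append((m1 - m2) / pooled)
        means1.append(m1)
        means2.append(m2)
        sds1.append(s1)
        sds2.append(s2)

    d_avg = sum(abs(d) for d in d_per_var) / n_vars

    mu_g1, mu_g2 = _mean(means1), _mean(means2)
    sigma_g1, sigma_g2 = _mean(sds1), _mean(sds2)
    pooled_g = math.sqrt(
        ((n1 - 1) * sigma_g1**2 + (n2 - 1) * sigma_g2**2) / (n1 + n2 - 2)
    )
    d_g = abs(mu_g1 - mu_g2) / pooled_g
    return d_per_var, d_avg, d_g
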
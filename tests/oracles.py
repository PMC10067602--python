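"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity from its textbook definition with plain
loops, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_pairs(genes):
    """All unordered gene pairs via an explicit i<j double loop."""
    out = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            out.append((a, b) if a < b else (b, a))
    return out


def brute_indicator_table(expr_df, pairs):
    """Pair indicators by direct cell comparison, one loop per sample."""
    table = {}
    for a, b in pairs:
        row = []
        for s in expr_df.columns:
            row.append(1 if expr_df.loc[a, s] > expr_df.loc[b, s] else 0)
        table[f"{a}|{b}"] = row
    return table


def newton_breslow_cox(X, time, event, tol=1e-12, max_iter=200):
    """Maximize the Breslow partial likelihood by full Newton iterations.

    Gradient and Hessian are accumulated with explicit loops over event
    times and risk sets.  Returns (beta, standard errors).
    """
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for i in range(n):
            if not event[i]:
                continue
            risk = [j for j in range(n) if time[j] >= time[i]]
            w = np.array([math.exp(X[j] @ beta) for j in risk])
            xs = X[risk]
            s0 = w.sum()
            s1 = (w[:, None] * xs).sum(axis=0)
            s2 = (w[:, None, None] * xs[:, :, None] * xs[:, None, :]).sum(axis=0)
            grad += X[i] - s1 / s0
            hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.abs(step).max() < tol:
            break
    # observed information at the optimum
    info = np.zeros((p, p))
    for i in range(n):
        if not event[i]:
            continue
        risk = [j for j in range(n) if time[j] >= time[i]]
        w = np.array([math.exp(X[j] @ beta) for j in risk])
        xs = X[risk]
        s0 = w.sum()
        s1 = (w[:, None] * xs).sum(axis=0)
        s2 = (w[:, None, None] * xs[:, :, None] * xs[:, None, :]).sum(axis=0)
        info += s2 / s0 - np.outer(s1, s1) / s0**2
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def brute_km(time, event):
    """Product-limit estimate over risk sets, returned as (times, S)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ts = sorted(set(time[event == 1]))
    s = 1.0
    surv = []
    for t in ts:
        at_risk = int((time >= t).sum())
        deaths = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return np.array(ts), np.array(surv)


def brute_logrank_2group(time1, event1, time2, event2):
    """Two-group log-rank chi-square from observed-minus-expected sums."""
    t1, e1 = np.asarray(time1, float), np.asarray(event1, int)
    t2, e2 = np.asarray(time2, float), np.asarray(event2, int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(all_t[all_e == 1])):
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        d1 = int(((t1 == t) & (e1 == 1)).sum())
        d2 = int(((t2 == t) & (e2 == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2


def brute_bh(pvals):
    """Benjamini-Hochberg adjustment by sort-and-cummin."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(p[i] * m / rank, 1.0)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def brute_ssgsea_one_sample(values, gene_names, gene_set, exponent=0.25):
    """Literal running-sum enrichment score for one sample.

    Ranks genes (average ranks for ties, largest value -> rank N), walks the
    descending-expression list, and accumulates the difference between the
    weighted in-set and uniform out-of-set step functions.
    """
    n = len(values)
    # average ranks, largest value gets rank n
    idx = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[idx[j + 1]] == values[idx[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[idx[k]] = avg
        i = j + 1
    desc = sorted(range(n), key=lambda i: -ranks[i])
    in_set = [gene_names[i] in gene_set for i in desc]
    n_in = sum(in_set)
    w_total = sum(abs(ranks[desc[i]]) ** exponent for i in range(n) if in_set[i])
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in range(n):
        if in_set[i]:
            p_in += abs(ranks[desc[i]]) ** exponent / w_total
        else:
            p_out += 1.0 / (n - n_in)
        es += p_in - p_out
    return es


def brute_concordance_at_horizon(scores, time, event, horizon):
    """Case/control concordance at a horizon for a fully-observed cohort."""
    cases = [i for i in range(len(time)) if time[i] <= horizon and event[i] == 1]
    controls = [i for i in range(len(time)) if time[i] > horizon]
    num = 0.0
    for i in cases:
        for j in controls:
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / (len(cases) * len(controls))


def brute_pearson_chi2(table):
    """Pearson chi-square from expected counts, explicit loops."""
    table = np.asarray(table, float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            exp = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - exp) ** 2 / exp
    return chi2
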
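"""Independent literal-formula implementations used as test oracles.

Everything here is written as plain loops straight from the defining
formulas, sharing no code with the package, so that the optimised
implementations can be checked against them.
"""

import numpy as np
from scipy.special import ndtr


# ---------------------------------------------------------------------------
# pathway scoring
# ---------------------------------------------------------------------------

def zscore_oracle(values, gene_ids, sets_dict, denominator="sqrt"):
    G, S = values.shape
    mu = [float(np.mean(values[g])) for g in range(G)]
    sd = [float(np.std(values[g], ddof=1)) for g in range(G)]
    out = {}
    for name, genes in sets_dict.items():
        rows = [i for i, g in enumerate(gene_ids) if g in genes and sd[i] > 0]
        scores = []
        for j in range(S):
            total = sum((values[i, j] - mu[i]) / sd[i] for i in rows)
            d = np.sqrt(len(rows)) if denominator == "sqrt" else float(len(rows))
            scores.append(total / d)
        out[name] = scores
    return out


def ssgsea_oracle(values, gene_ids, sets_dict, alpha=0.25, normalize=True):
    """Step-by-step walk down the ranked list of every sample."""
    G, S = values.shape
    raw = {name: [] for name in sets_dict}
    for j in range(S):
        order = sorted(range(G), key=lambda i: (-values[i, j], gene_ids[i]))
        for name, genes in sets_dict.items():
            member = [gene_ids[i] in genes for i in order]
            n_in = sum(member)
            n_out = G - n_in
            denom_in = sum(float(G - pos) ** alpha
                           for pos in range(G) if member[pos])
            es = 0.0
            p_in = 0.0
            p_out = 0.0
            for pos in range(G):
                if member[pos]:
                    p_in += float(G - pos) ** alpha / denom_in
                else:
                    p_out += 1.0 / n_out
                es += p_in - p_out
            raw[name].append(es)
    mat = np.array([raw[name] for name in sets_dict])
    if normalize:
        rng = mat.max() - mat.min()
        if rng > 0:
            mat = mat / rng
    return {name: mat[k].tolist() for k, name in enumerate(sets_dict)}


def gsva_oracle(values, gene_ids, sets_dict, tau=1.0, es_mode="max_diff"):
    G, S = values.shape
    sd = [float(np.std(values[g], ddof=1)) for g in range(G)]
    kcdf = np.empty((G, S))
    for g in range(G):
        if sd[g] == 0:
            kcdf[g, :] = 0.5
            continue
        h = sd[g] / 4.0
        for j in range(S):
            kcdf[g, j] = np.mean([ndtr((values[g, j] - values[g, l]) / h)
                                  for l in range(S)])
    out = {name: [] for name in sets_dict}
    for j in range(S):
        order = sorted(range(G), key=lambda i: (-kcdf[i, j], gene_ids[i]))
        rho = {i: pos + 1 for pos, i in enumerate(order)}
        r = {i: abs(G / 2.0 - rho[i]) ** tau for i in range(G)}
        for name, genes in sets_dict.items():
            rows = {i for i, g in enumerate(gene_ids) if g in genes}
            denom_in = sum(r[i] for i in rows)
            n_out = G - len(rows)
            v = 0.0
            vmax, vmin = 0.0, 0.0
            v_extreme = 0.0
            for i in order:
                if i in rows:
                    v += r[i] / denom_in
                else:
                    v -= 1.0 / n_out
                vmax = max(vmax, v)
                vmin = min(vmin, v)
                if abs(v) > abs(v_extreme):
                    v_extreme = v
            out[name].append(vmax + vmin if es_mode == "max_diff" else v_extreme)
    return out


# ---------------------------------------------------------------------------
# survival metrics
# ---------------------------------------------------------------------------

def km_oracle(times, indicators):
    """Product-limit by explicit loop; returns a plain evaluator."""
    pts = sorted({t for t, d in zip(times, indicators) if d == 1})
    n = len(times)

    def s_hat(t):
        s = 1.0
        for u in pts:
            if u > t:
                break
            d_u = sum(1 for tt, dd in zip(times, indicators)
                      if tt == u and dd == 1)
            at_risk = sum(1 for tt in times if tt >= u)
            s *= 1.0 - d_u / at_risk
        return s

    return s_hat


def cindex_oracle(risk, time, event):
    """Exhaustive pair enumeration of the stated usability rules."""
    n = len(risk)
    num = 0.0
    pairs = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                pairs += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if pairs == 0:
        return None, 0
    return num / pairs, pairs


def brier_oracle(pi, time, event, t_star):
    """Term-by-term IPCW Brier score with the reverse-KM censoring
    distribution evaluated at left limits for events."""
    n = len(pi)
    g_hat = km_oracle(time, [1 - e for e in event])

    def g_left(t):
        # left limit: censoring survival just before t
        s = 1.0
        for u in sorted({u for u, e in zip(time, event) if e == 0}):
            if u >= t:
                break
            d_u = sum(1 for tt, ee in zip(time, event) if tt == u and ee == 0)
            at_risk = sum(1 for tt in time if tt >= u)
            s *= 1.0 - d_u / at_risk
        return s

    total = 0.0
    for i in range(n):
        if time[i] <= t_star and event[i] == 1:
            w = 1.0 / g_left(time[i])
            total += w * (0.0 - pi[i]) ** 2
        elif time[i] > t_star:
            w = 1.0 / g_hat(t_star)
            total += w * (1.0 - pi[i]) ** 2
    return total / n
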
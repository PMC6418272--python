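"""Independent naive reimplementations used as test oracles.

Everything here is written with plain Python loops and dictionaries,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math


def _step(a: float, net: float, rest: float, p) -> float:
    if net > 0:
        da = net * (p.a_max - a) - p.decay * (a - rest)
    else:
        da = net * (a - p.a_min) - p.decay * (a - rest)
    return min(max(a + da, p.a_min), p.a_max)


def naive_word_trace(entries, alphabet, params, stimulus, n_cycles):
    """Cycle-by-cycle word activations, recomputed unit by unit.

    Returns a list of dicts (one per cycle 1..n_cycles) mapping word ->
    activation; the resting state is the implicit cycle 0.
    """
    alphabet = sorted(alphabet)
    words = [w for w, _ in entries]
    logf = [math.log10(f + 1.0) for _, f in entries]
    lo, hi = params.rest_range
    mx, mn = max(logf), min(logf)
    rest = {
        w: (hi if mx == mn else lo + (lf - mn) / (mx - mn) * (hi - lo))
        for w, lf in zip(words, logf)
    }
    n_pos = max(len(w) for w in words)
    L = {(p, c): 0.0 for p in range(n_pos) for c in alphabet}
    # the realized resting state is clipped into the activation bounds
    W = {w: min(max(rest[w], params.a_min), params.a_max) for w in words}
    history = []
    for _ in range(n_cycles):
        lpos = {k: max(v, 0.0) for k, v in L.items()}
        wpos = {w: max(v, 0.0) for w, v in W.items()}
        newW = {}
        for w in words:
            net = 0.0
            for p, ch in enumerate(w):
                for c in alphabet:
                    if c == ch:
                        net += params.excite_letter_word * lpos[(p, c)]
                    else:
                        net -= params.inhibit_letter_word * lpos[(p, c)]
            for other in words:
                if other != w:
                    net -= params.inhibit_word_word * wpos[other]
            newW[w] = _step(W[w], net, rest[w], params)
        newL = {}
        for p in range(n_pos):
            for c in alphabet:
                net = 0.0
                for w in words:
                    if p < len(w) and w[p] == c:
                        net += params.feedback_word_letter * wpos[w]
                if p < len(stimulus):
                    net += params.input_clamp if stimulus[p] == c else -params.input_clamp
                newL[(p, c)] = _step(L[(p, c)], net, 0.0, params)
        L, W = newL, newW
        history.append(dict(W))
    return history


def naive_gla(history, window):
    total = 0.0
    for cycle in range(window):
        total += sum(max(a, 0.0) for a in history[cycle].values())
    return total / window


def naive_ortho(target, entries, target_freq):
    """Recount all orthographic measures by brute scanning."""
    ref = 0.0 if target_freq is None else target_freq
    nbrs = [
        (w, f)
        for w, f in entries
        if len(w) == len(target) and w != target
        and sum(1 for a, b in zip(w, target) if a != b) == 1
    ]
    tb = [target[i : i + 2] for i in range(len(target) - 1)]
    bic = 0
    bif = 0.0
    bin_ = 0
    for w, f in entries:
        if w == target:
            continue
        hits = 0
        for i in range(len(w) - 1):
            if w[i : i + 2] in tb:
                hits += 1
        if hits:
            bic += hits
            bin_ += 1
            bif += f
    return {
        "N": len(nbrs),
        "FN": sum(f for _, f in nbrs),
        "NHF": sum(1 for _, f in nbrs if f > ref),
        "FHN": sum(f for _, f in nbrs if f > ref),
        "BiC": bic,
        "BiF": bif,
        "BiN": bin_,
    }


def naive_rm_anova(Y):
    """Brute-force balanced 2x3 within-subject ANOVA from cell means.

    Y is a nested list [subject][lexicality][level]; returns a dict of
    (F, df1, df2) per effect plus contrast and simple-effect statistics.
    """
    n = len(Y)
    vals = [Y[s][l][j] for s in range(n) for l in range(2) for j in range(3)]
    grand = sum(vals) / len(vals)
    subj = [sum(Y[s][l][j] for l in range(2) for j in range(3)) / 6 for s in range(n)]
    A = [sum(Y[s][l][j] for s in range(n) for j in range(3)) / (3 * n) for l in range(2)]
    B = [sum(Y[s][l][j] for s in range(n) for l in range(2)) / (2 * n) for j in range(3)]
    AB = [[sum(Y[s][l][j] for s in range(n)) / n for j in range(3)] for l in range(2)]
    sA = [[sum(Y[s][l][j] for j in range(3)) / 3 for l in range(2)] for s in range(n)]
    sB = [[sum(Y[s][l][j] for l in range(2)) / 2 for j in range(3)] for s in range(n)]

    ss_a = 3 * n * sum((a - grand) ** 2 for a in A)
    ss_b = 2 * n * sum((b - grand) ** 2 for b in B)
    ss_ab = n * sum(
        (AB[l][j] - A[l] - B[j] + grand) ** 2 for l in range(2) for j in range(3)
    )
    ss_as = 3 * sum(
        (sA[s][l] - subj[s] - A[l] + grand) ** 2 for s in range(n) for l in range(2)
    )
    ss_bs = 2 * sum(
        (sB[s][j] - subj[s] - B[j] + grand) ** 2 for s in range(n) for j in range(3)
    )
    ss_total = sum((v - grand) ** 2 for v in vals)
    ss_subj = 6 * sum((s - grand) ** 2 for s in subj)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    def F(ss, df1, ss_err, df2):
        if ss == 0 and ss_err == 0:
            return 0.0
        return (ss / df1) / (ss_err / df2)

    out = {
        "lexicality": (F(ss_a, 1, ss_as, n - 1), 1, n - 1),
        "gla": (F(ss_b, 2, ss_bs, 2 * (n - 1)), 2, 2 * (n - 1)),
        "interaction": (F(ss_ab, 2, ss_abs, 2 * (n - 1)), 2, 2 * (n - 1)),
        "ss_gla": ss_b,
    }

    # pooled polynomial contrasts from per-subject scores
    for name, w in (("linear", (-1.0, 0.0, 1.0)), ("quadratic", (1.0, -2.0, 1.0))):
        wss = sum(x * x for x in w)
        scores = [sum(w[j] * sB[s][j] for j in range(3)) for s in range(n)]
        mean = sum(scores) / n
        ss_c = 2 * n * mean ** 2 / wss
        ss_e = 2 * sum((sc - mean) ** 2 for sc in scores) / wss
        out[name] = (F(ss_c, 1, ss_e, n - 1), 1, n - 1)
        out[f"ss_{name}"] = ss_c

    # per-lexicality simple effects (slice-wise error) and linear contrasts
    for l, lex in enumerate(("word", "nonword")):
        S = [[Y[s][l][j] for j in range(3)] for s in range(n)]
        g = sum(sum(row) for row in S) / (3 * n)
        lvl = [sum(S[s][j] for s in range(n)) / n for j in range(3)]
        sm = [sum(row) / 3 for row in S]
        ssb = n * sum((x - g) ** 2 for x in lvl)
        sse = sum(
            (S[s][j] - lvl[j] - sm[s] + g) ** 2 for s in range(n) for j in range(3)
        )
        out[f"simple_{lex}"] = (F(ssb, 2, sse, 2 * (n - 1)), 2, 2 * (n - 1))
        w = (-1.0, 0.0, 1.0)
        scores = [sum(w[j] * S[s][j] for j in range(3)) for s in range(n)]
        mean = sum(scores) / n
        ss_c = n * mean ** 2 / 2
        ss_e = sum((sc - mean) ** 2 for sc in scores) / 2
        out[f"linear_{lex}"] = (F(ss_c, 1, ss_e, n - 1), 1, n - 1)
    return out
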
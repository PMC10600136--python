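"""Independent brute-force oracles for the network coefficients.

These follow the written definitions literally with nested Python loops and
are deliberately separate from the package's vectorized implementations.
"""

import numpy as np

N = 10


def oracle_transition_matrix(S):
    S = np.asarray(S)
    n_t, n_v = S.shape
    T = np.empty((n_t - 1, n_v), dtype=int)
    for j in range(n_v):
        for i in range(n_t - 1):
            T[i, j] = 10 * (S[i, j] - 1) + S[i + 1, j]
    return T


def oracle_counts(S):
    T = oracle_transition_matrix(S)
    c = np.zeros(100, dtype=int)
    for j in range(T.shape[1]):
        for i in range(T.shape[0]):
            c[T[i, j] - 1] += 1
    return c


def _pre_dwell(S, i, j):
    """Frames spent in state S[i, j] counting backwards from frame i (0-based)."""
    n = 0
    s = S[i, j]
    while i - n >= 0 and S[i - n, j] == s:
        n += 1
    return n


def _post_dwell(S, i, j):
    n = 0
    s = S[i, j]
    while i + n < S.shape[0] and S[i + n, j] == s:
        n += 1
    return n


def oracle_dwell_sums(S):
    """Literal per-occurrence tally of the pre/post dwell sums (frames).

    Transition at 0-based step i spans frames (i, i+1); 1-based step index is
    i+1.  Pre sums run over steps 2..N_TS, post over 1..N_TS-1.  Within each
    maximal sequence of consecutive same-type occurrences (only possible for
    self-transition types) only the largest valid dwell value contributes.
    """
    S = np.asarray(S)
    n_t, n_v = S.shape
    n_ts = n_t - 1
    T = oracle_transition_matrix(S)
    pre_sum = np.zeros(100)
    post_sum = np.zeros(100)
    for j in range(n_v):
        # split the step sequence into maximal runs of identical type
        seqs = []
        start = 0
        for i in range(1, n_ts + 1):
            if i == n_ts or T[i, j] != T[start, j]:
                seqs.append((T[start, j], start, i))
                start = i
        for k, a, b in seqs:  # steps a..b-1 (0-based) all of type k
            pre_vals = [
                _pre_dwell(S, i, j) for i in range(a, b) if (i + 1) >= 2
            ]
            post_vals = [
                _post_dwell(S, i + 1, j) for i in range(a, b) if (i + 1) <= n_ts - 1
            ]
            if pre_vals:
                pre_sum[k - 1] += max(pre_vals)
            if post_vals:
                post_sum[k - 1] += max(post_vals)
    return pre_sum, post_sum


def oracle_dwell_times(S, frame_rate):
    c = oracle_counts(S)
    pre_sum, post_sum = oracle_dwell_sums(S)
    tau_pre = np.full(100, np.nan)
    tau_post = np.full(100, np.nan)
    for k in range(100):
        if c[k] > 0:
            tau_pre[k] = pre_sum[k] / c[k] / frame_rate
            tau_post[k] = post_sum[k] / c[k] / frame_rate
    return tau_pre, tau_post


def oracle_component_stats_ga(X, S):
    X = np.asarray(X, dtype=float)
    S = np.asarray(S)
    T = oracle_transition_matrix(S)
    c = oracle_counts(S)
    mu_pre = np.full(100, np.nan)
    mu_post = np.full(100, np.nan)
    flux = np.full(100, np.nan)
    for k in range(1, 101):
        if c[k - 1] == 0:
            continue
        s_pre = s_post = s_flux = 0.0
        for j in range(T.shape[1]):
            for i in range(T.shape[0]):
                if T[i, j] == k:
                    s_pre += X[i, j]
                    s_post += X[i + 1, j]
                    s_flux += X[i + 1, j] - X[i, j]
        mu_pre[k - 1] = s_pre / c[k - 1]
        mu_post[k - 1] = s_post / c[k - 1]
        flux[k - 1] = s_flux / c[k - 1]
    return mu_pre, mu_post, flux


def _occurrence_values(X, T, k, which):
    """(i, j, value) triples for type-k occurrences; which in {pre,post,diff}."""
    out = []
    for j in range(T.shape[1]):
        for i in range(T.shape[0]):
            if T[i, j] == k:
                if which == "pre":
                    v = X[i, j]
                elif which == "post":
                    v = X[i + 1, j]
                else:
                    v = X[i + 1, j] - X[i, j]
                out.append((i, j, v))
    return out


def oracle_component_stats_scheme(X, S, scheme):
    """TMSM / SMTM by literal two-stage averaging."""
    X = np.asarray(X, dtype=float)
    T = oracle_transition_matrix(np.asarray(S))
    results = []
    for which in ("pre", "post", "diff"):
        vec = np.full(100, np.nan)
        for k in range(1, 101):
            occ = _occurrence_values(X, T, k, which)
            if not occ:
                continue
            if scheme == "TMSM":
                inner = {}
                for i, j, v in occ:
                    inner.setdefault(i, []).append(v)
                vec[k - 1] = np.mean([np.mean(vs) for vs in inner.values()])
            elif scheme == "SMTM":
                inner = {}
                for i, j, v in occ:
                    inner.setdefault(j, []).append(v)
                vec[k - 1] = np.mean([np.mean(vs) for vs in inner.values()])
            else:
                raise ValueError(scheme)
        results.append(vec)
    return tuple(results)
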
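"""Compiled inner loops for the likelihood-critical paths.

The forward filter and the value-learning recursion are evaluated hundreds
of times per optimizer run, so they are compiled with numba when it is
importable; the pure-numpy implementations in :mod:`.sht` and
:mod:`.values` remain the reference path (used for predictive output and
wherever numba is unavailable), and the test suite asserts that the two
paths agree to near machine precision.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=False)
def value_traj_kernel(
    choices, stims, rewards, eta_s, eta_r, decay, config_weights, config_sel
):
    """Feature values before each trial; row T is the post-game state."""
    T = choices.shape[0]
    V = np.zeros((T + 1, 9))
    for t in range(T):
        c = choices[t]
        er = 0.0
        for p in range(9):
            er += config_weights[c, p] * V[t, p]
        pe = rewards[t] - er
        for p in range(9):
            V[t + 1, p] = decay * V[t, p]
        s = stims[t]
        f0 = s // 9
        f1 = (s % 9) // 3
        f2 = s % 3
        for i in range(3):
            f = f0 if i == 0 else (f1 if i == 1 else f2)
            pos = 3 * i + f
            eta = eta_s if config_sel[c, i] >= 0 else eta_r
            V[t + 1, pos] = V[t, pos] + eta * pe
    return V


@njit(cache=False)
def rl_loglik_kernel(choices, stims, rewards, beta, eta_s, eta_r, decay,
                     config_weights, config_sel):
    """Feature-RL game log-likelihood (softmax over all 64 configurations)."""
    T = choices.shape[0]
    v = np.zeros(9)
    er = np.zeros(64)
    total = 0.0
    for t in range(T):
        m = -1e300
        for c in range(64):
            e = 0.0
            for p in range(9):
                e += config_weights[c, p] * v[p]
            er[c] = beta * e
            if er[c] > m:
                m = er[c]
        z = 0.0
        for c in range(64):
            z += np.exp(er[c] - m)
        total += er[choices[t]] - m - np.log(z)
        # learning step
        cer = 0.0
        for p in range(9):
            cer += config_weights[choices[t], p] * v[p]
        pe = rewards[t] - cer
        new = np.empty(9)
        for p in range(9):
            new[p] = decay * v[p]
        s = stims[t]
        f0 = s // 9
        f1 = (s % 9) // 3
        f2 = s % 3
        for i in range(3):
            f = f0 if i == 0 else (f1 if i == 1 else f2)
            pos = 3 * i + f
            eta = eta_s if config_sel[choices[t], i] >= 0 else eta_r
            new[pos] = v[pos] + eta * pe
        v = new
    return total


@njit(cache=False)
def sht_filter_kernel(
    choices,
    rewards,
    prior,
    emit,  # (63, 64) choice distribution per hypothesis
    emit_nt,  # (64,) choice distribution while not testing
    theta_h,  # (63,) stay threshold per hypothesis
    beta_stay,
    use_value,  # 0 random-switch, 1 value-based switch
    beta_switch,
    hyp_vals,  # (T+1, 63) hypothesis values entering each trial boundary
    test_gate,  # 0/1
    beta_test,
    theta_test,
):
    """Exact forward filter over (hypothesis, adoption trial) states.

    Counters are deterministic given the adoption trial because rewards are
    observed; the not-testing state (test-gate variant) is a scalar mass.
    Returns the total log-likelihood (-inf on a zero-probability choice).
    """
    T = choices.shape[0]
    H = prior.shape[0]
    P = np.zeros((H, T))
    cum = np.zeros(T + 1, dtype=np.int64)
    for t in range(T):
        cum[t + 1] = cum[t] + rewards[t]

    def_best = -1.0e300
    if test_gate == 1:
        best = def_best
        for h in range(H):
            if prior[h] > 0.0 and hyp_vals[0, h] > best:
                best = hyp_vals[0, h]
        pt0 = _sigmoid(beta_test * (best - theta_test))
    else:
        pt0 = 1.0
    for h in range(H):
        P[h, 0] = prior[h] * pt0
    nt = 1.0 - pt0 if test_gate == 1 else 0.0

    ll = 0.0
    out = np.zeros(H)
    w = np.zeros(H)
    inc = np.zeros(H)
    for t in range(T):
        if t > 0:
            for h in range(H):
                out[h] = 0.0
            for k in range(t):
                ph = (cum[t] - cum[k] + 1.0) / (t - k + 2.0)
                for h in range(H):
                    if P[h, k] > 0.0:
                        ps = _sigmoid(beta_stay * (ph - theta_h[h]))
                        out[h] += P[h, k] * (1.0 - ps)
                        P[h, k] *= ps
            switch_total = 0.0
            for h in range(H):
                switch_total += out[h]
            if test_gate == 1:
                best = def_best
                for h in range(H):
                    if prior[h] > 0.0 and hyp_vals[t, h] > best:
                        best = hyp_vals[t, h]
                pt = _sigmoid(beta_test * (best - theta_test))
            else:
                pt = 1.0
            if switch_total > 0.0:
                # switch weights over candidate hypotheses
                if use_value == 1:
                    m = def_best
                    for h in range(H):
                        if prior[h] > 0.0:
                            x = beta_switch * hyp_vals[t, h]
                            if x > m:
                                m = x
                    tot = 0.0
                    for h in range(H):
                        if prior[h] > 0.0:
                            w[h] = np.exp(beta_switch * hyp_vals[t, h] - m)
                            tot += w[h]
                        else:
                            w[h] = 0.0
                else:
                    tot = 0.0
                    for h in range(H):
                        w[h] = prior[h]
                        tot += w[h]
                # incoming mass: sum_h out[h] * w[h'] / (tot - w[h]), h' != h
                ssum = 0.0
                for h in range(H):
                    inc[h] = 0.0
                for h in range(H):
                    if out[h] > 0.0:
                        denom = tot - w[h]
                        if denom > 1e-12 * tot:
                            ssum += out[h] / denom
                        else:
                            # dominant weight: renormalize excluding h exactly
                            if use_value == 1:
                                m2 = def_best
                                for h2 in range(H):
                                    if h2 != h and prior[h2] > 0.0:
                                        x = beta_switch * hyp_vals[t, h2]
                                        if x > m2:
                                            m2 = x
                                z2 = 0.0
                                for h2 in range(H):
                                    if h2 != h and prior[h2] > 0.0:
                                        z2 += np.exp(
                                            beta_switch * hyp_vals[t, h2] - m2
                                        )
                                for h2 in range(H):
                                    if h2 != h and prior[h2] > 0.0:
                                        inc[h2] += (
                                            out[h]
                                            * np.exp(
                                                beta_switch * hyp_vals[t, h2] - m2
                                            )
                                            / z2
                                        )
                            else:
                                z2 = tot - w[h]
                                if z2 > 0.0:
                                    for h2 in range(H):
                                        if h2 != h:
                                            inc[h2] += out[h] * w[h2] / z2
                for h in range(H):
                    denom = tot - w[h]
                    extra = 0.0
                    if out[h] > 0.0 and denom > 1e-12 * tot:
                        extra = out[h] / denom
                    inc[h] += w[h] * (ssum - extra)
                for h in range(H):
                    P[h, t] = pt * inc[h]
            if test_gate == 1:
                for h in range(H):
                    P[h, t] += pt * nt * prior[h]
                nt = (1.0 - pt) * (switch_total + nt)

        # emission of the observed choice
        c = choices[t]
        like = nt * emit_nt[c]
        for h in range(H):
            marg = 0.0
            for k in range(t + 1):
                marg += P[h, k]
            like += marg * emit[h, c]
        if like <= 0.0:
            return -np.inf
        ll += np.log(like)
        for h in range(H):
            scale = emit[h, c] / like
            for k in range(t + 1):
                P[h, k] *= scale
        nt *= emit_nt[c] / like
    return ll
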
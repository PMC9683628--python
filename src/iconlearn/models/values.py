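"""Shared feature-value learning machinery (Rescorla-Wagner with decay).

The nine feature values are kept as a flat length-9 vector (dimension-major:
``V[3*i + j]`` is feature ``j`` of dimension ``i``).  The expected reward of
a configuration is the sum of its selected features' values, with the
dimension mean substituted for unselected dimensions; this is encoded once
in :data:`iconlearn.task.CONFIG_FEATURE_WEIGHTS` so that the expected
reward of all 64 configurations is a single matrix-vector product.
"""

from __future__ import annotations

import numpy as np

from ..task import CONFIG_FEATURE_WEIGHTS, CONFIG_SEL, N_DIMS, N_FEATURES, RULE_ASSIGN

# boolean (63, 9) mask of each rule's constituent features
RULE_FEATURE_MASK = np.zeros((RULE_ASSIGN.shape[0], N_DIMS * N_FEATURES))
for _h, _assign in enumerate(RULE_ASSIGN):
    for _d, _f in enumerate(_assign):
        if _f >= 0:
            RULE_FEATURE_MASK[_h, _d * N_FEATURES + _f] = 1.0


def expected_rewards_all_configs(values: np.ndarray) -> np.ndarray:
    """ER of every configuration: selected features summed, dimension means elsewhere."""
    return CONFIG_FEATURE_WEIGHTS @ values


def hypothesis_values(values: np.ndarray) -> np.ndarray:
    """ER of every rule as the sum of its constituent feature values only."""
    return RULE_FEATURE_MASK @ values


def update_values(
    values: np.ndarray,
    choice_idx: int,
    stim_idx: int,
    reward: int,
    eta_selected: float,
    eta_random: float,
    decay: float,
) -> np.ndarray:
    """One Rescorla-Wagner step with decay of absent features.

    The prediction error is computed against the expected reward of the
    *choice* (dimension means filling unselected dimensions), while the
    update lands on the realized stimulus's three features; the six features
    not in the stimulus decay toward zero by the factor ``decay``.
    """
    pe = reward - float(CONFIG_FEATURE_WEIGHTS[choice_idx] @ values)
    sel = CONFIG_SEL[choice_idx]
    f0, rest = divmod(stim_idx, 9)
    f1, f2 = divmod(rest, 3)
    new = decay * values
    for i, f in enumerate((f0, f1, f2)):
        pos = i * N_FEATURES + f
        eta = eta_selected if sel[i] >= 0 else eta_random
        new[pos] = values[pos] + eta * pe
    return new


def value_trajectory(
    choices: np.ndarray,
    stims: np.ndarray,
    rewards: np.ndarray,
    eta_selected: float,
    eta_random: float,
    decay: float,
) -> np.ndarray:
    """Values *before* each trial, plus the post-game state.

    Returns an array of shape ``(T + 1, 9)``; row ``t`` is the value vector
    entering trial ``t`` (row 0 is all zeros), and row ``T`` the final state.
    """
    from ._kernels import HAVE_NUMBA, value_traj_kernel

    if HAVE_NUMBA:
        return value_traj_kernel(
            np.asarray(choices, dtype=np.int64),
            np.asarray(stims, dtype=np.int64),
            np.asarray(rewards, dtype=np.int64),
            float(eta_selected),
            float(eta_random),
            float(decay),
            CONFIG_FEATURE_WEIGHTS,
            CONFIG_SEL,
        )
    return _value_trajectory_py(
        choices, stims, rewards, eta_selected, eta_random, decay
    )


def _value_trajectory_py(
    choices, stims, rewards, eta_selected, eta_random, decay
) -> np.ndarray:
    """Reference implementation of :func:`value_trajectory`."""
    T = len(choices)
    out = np.zeros((T + 1, N_DIMS * N_FEATURES))
    v = out[0]
    for t in range(T):
        v = update_values(
            v, int(choices[t]), int(stims[t]), int(rewards[t]),
            eta_selected, eta_random, decay,
        )
        out[t + 1] = v
    return out


def log_softmax(utilities: np.ndarray, beta: float) -> np.ndarray:
    """Log of the softmax choice rule, computed with max-subtraction."""
    z = beta * utilities
    z = z - z.max()
    return z - np.log(np.exp(z).sum())
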
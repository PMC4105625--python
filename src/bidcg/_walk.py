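"""Numba kernel for the regulated random walk.

Kept separate so the hot loop stays minimal: a Markov walk on a weighted
graph in which a node is retired once it has been visited
`removal_threshold` times; the removal order and the step counts between
removals (recurrence times) are the walk's output.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def walk_kernel(W, removal_threshold, seed):  # pragma: no cover - numba
    """Run one regulated random walk on weight matrix W (zero diagonal).

    Returns (removal_order, recurrence_times), both int64 arrays of length n.
    Transition probability from the current node to active node j is
    proportional to W[cur, j]; if the current row carries no mass over the
    active set the walk restarts from a uniformly chosen active node.
    """
    np.random.seed(seed)
    n = W.shape[0]
    visits = np.zeros(n, np.int64)
    removal_order = np.empty(n, np.int64)
    rec_times = np.empty(n, np.int64)
    # compact active index list with swap-removal
    act = np.arange(n)
    pos = np.arange(n)  # pos[node] = index in act (valid while active)
    n_active = n

    cur = np.random.randint(0, n)
    steps_since = 0
    removed = 0
    while removed < n:
        if n_active == 1:
            # terminal node: forced self-steps until the threshold is met
            node = act[0]
            forced = removal_threshold - visits[node]
            if forced < 1:
                forced = 1
            steps_since += forced
            removal_order[removed] = node
            rec_times[removed] = steps_since
            removed += 1
            break
        # total active mass from the current position
        total = 0.0
        for k in range(n_active):
            total += W[cur, act[k]]
        if total > 0.0:
            r = np.random.random() * total
            acc = 0.0
            j = act[n_active - 1]
            for k in range(n_active):
                acc += W[cur, act[k]]
                if acc >= r:
                    j = act[k]
                    break
        else:
            # stranded: uniform restart among active nodes
            j = act[np.random.randint(0, n_active)]
        steps_since += 1
        visits[j] += 1
        cur = j
        if visits[j] >= removal_threshold:
            removal_order[removed] = j
            rec_times[removed] = steps_since
            steps_since = 0
            removed += 1
            # swap-remove j from the active list
            pj = pos[j]
            last = act[n_active - 1]
            act[pj] = last
            pos[last] = pj
            n_active -= 1
    return removal_order, rec_times
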
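"""Numba kernels for the stepping core.

One beetle sub-step = perceive -> move -> try-attack, operating in place
on flat beetle/tree arrays.  The kernels consume randomness exclusively
through ``rng.random()`` (uniform float64 in [0, 1)) so that the jitted
path, the pure-Python ``.py_func`` path and a scripted replacement RNG
all see the same draw protocol:

per time step
    Fisher-Yates shuffle of the active-beetle index buffer:
    for ``i = m-1 .. 1`` one draw ``u`` with ``j = int(u * (i + 1))``.
per beetle sub-step, in order
    1. perception tie-break: one draw, only when more than one candidate
       tree shares the maximal attractiveness at the minimal distance;
    2. random turn: one draw, only when no target was perceived
       (``delta = int(u * 3) - 1`` i.e. -45/0/+45 degrees).

No other randomness is consumed inside a run's stepping loop.

Direction indices 0..7 map to E, NE, N, NW, W, SW, S, SE on the
(col, row) lattice; a heading change of +/-1 is a 45-degree turn.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .population import (
    FLYING,
    ATTACKING,
    DIED_ENERGY,
    EMIGRATED,
)

#: Attack-window sentinel: windows at or beyond this never expire.
NEVER = np.int64(1) << 40

DIR_DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
DIR_DY = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)

#: Energy at or below this is treated as exhausted (absorbs float drift
#: from repeated subtraction of c = 1/efficiency).
ENERGY_EPS = 1e-9


@njit(cache=True)
def _attractiveness(pa_value, n_attackers, thr_value, capacity, a_pher, gain,
                    trigger):
    """Current attractiveness of one tree.

    Kairomone level PA until the aggregation pheromone activates; the
    active signal adds ``gain`` per attacker on top of PA up to the
    ceiling ``a_pher`` (``gain = inf`` jumps straight to the ceiling);
    zero at the capacity limit (repellents).  ``trigger`` is the
    attacker quorum at which the joint signal becomes effective
    (1 = from the first attacker on), or -1 for "only once the tree is
    overwhelmed", i.e. the attackers reached the resistance threshold.
    """
    if n_attackers == 0:
        return float(pa_value)
    if n_attackers >= capacity:
        return 0.0
    activation = thr_value if trigger < 0 else trigger
    if n_attackers < activation:
        return float(pa_value)
    a = pa_value + gain * n_attackers
    if a > a_pher:
        return a_pher
    return a


@njit(cache=True)
def _attack(
    i,
    c,
    r,
    clock,
    n_attackers,
    thresholds,
    infested,
    episode,
    attack_window,
    pend_tree,
    pend_deadline,
    pend_state,
    fate,
    tree_col,
    tree_row,
    beetle_episode,
):
    """Register beetle ``i`` as an attacker of tree (c, r).

    The first attacker of a fresh (non-infested) episode opens an
    aggregation window of ``attack_window`` steps on the tree; the tree
    becomes infested the moment its attacker count reaches the
    resistance threshold.  Beetles remember the episode they joined so
    that attackers of failed (expired) episodes can be resolved as
    resistance mortality at the end of the wave.
    """
    side = infested.shape[0]
    if n_attackers[c, r] == 0 and infested[c, r] == 0:
        tail = pend_state[1]
        pend_tree[tail] = c * side + r
        pend_deadline[tail] = clock + attack_window
        pend_state[1] = tail + 1
    n_attackers[c, r] += 1
    fate[i] = ATTACKING
    tree_col[i] = c
    tree_row[i] = r
    beetle_episode[i] = episode[c, r]
    if infested[c, r] == 0 and n_attackers[c, r] >= thresholds[c, r]:
        infested[c, r] = 1


@njit(cache=True)
def _expire_windows(clock, n_attackers, infested, episode,
                    pend_tree, pend_deadline, pend_state):
    """Fail every open attack episode whose window has run out.

    Entries are appended in deadline order, so a FIFO head pointer
    suffices.  An expired, still non-infested tree sheds its attackers
    (they are resolved as resistance mortality later) and becomes
    attackable again under a fresh episode.
    """
    side = infested.shape[0]
    head = pend_state[0]
    tail = pend_state[1]
    while head < tail and pend_deadline[head] <= clock:
        t = pend_tree[head]
        head += 1
        c = t // side
        r = t % side
        if infested[c, r] == 0 and n_attackers[c, r] > 0:
            episode[c, r] += 1
            n_attackers[c, r] = 0
    pend_state[0] = head


@njit(cache=True)
def _beetle_substep(
    i,
    clock,
    pa,
    n_attackers,
    capacity,
    a_pher,
    gain,
    trigger,
    prefer_nearest,
    kappa,
    thresholds,
    infested,
    episode,
    attack_window,
    pend_tree,
    pend_deadline,
    pend_state,
    off_dx,
    off_dy,
    off_d2,
    x,
    y,
    heading,
    energy,
    consumption,
    fate,
    steps_flown,
    tree_col,
    tree_row,
    beetle_episode,
    rng,
):
    """Advance beetle ``i`` by one sub-step (perceive, move, try-attack).

    Mutates the beetle arrays and the tree attacker counts in place.
    The perception scan visits offsets in (distance, dx, dy) order; a
    candidate qualifies when its current attractiveness A satisfies
    ``A >= 1`` and ``A >= kappa * E``.  The winner maximizes A with ties
    broken to the nearest tree (or, with ``prefer_nearest``, is the
    nearest qualifying tree with ties broken to the higher A); remaining
    ties resolve uniformly at random.
    """
    side = pa.shape[0]
    xi = x[i]
    yi = y[i]
    e = energy[i]

    # --- perceive ---------------------------------------------------
    best_a = -1.0
    best_d2 = np.int64(1) << 60
    n_ties = 0
    bx = -1
    by = -1
    for k in range(off_dx.shape[0]):
        tx = xi + off_dx[k]
        ty = yi + off_dy[k]
        if tx < 0 or tx >= side or ty < 0 or ty >= side:
            continue
        a = _attractiveness(pa[tx, ty], n_attackers[tx, ty], thresholds[tx, ty], capacity, a_pher, gain, trigger)
        if a < 1.0 or a < kappa * e:
            continue
        d2 = off_d2[k]
        if prefer_nearest:
            better = d2 < best_d2 or (d2 == best_d2 and a > best_a)
        else:
            better = a > best_a or (a == best_a and d2 < best_d2)
        if n_ties == 0 or better:
            best_a = a
            best_d2 = d2
            n_ties = 1
            bx = tx
            by = ty
        elif a == best_a and d2 == best_d2:
            n_ties += 1
    if n_ties > 1:
        pick = int(rng.random() * n_ties)
        seen = 0
        for k in range(off_dx.shape[0]):
            tx = xi + off_dx[k]
            ty = yi + off_dy[k]
            if tx < 0 or tx >= side or ty < 0 or ty >= side:
                continue
            a = _attractiveness(pa[tx, ty], n_attackers[tx, ty], thresholds[tx, ty], capacity, a_pher, gain, trigger)
            if a < 1.0 or a < kappa * e:
                continue
            if a == best_a and off_d2[k] == best_d2:
                if seen == pick:
                    bx = tx
                    by = ty
                    break
                seen += 1

    # --- target on the occupied patch: attack without moving --------
    if bx == xi and by == yi:
        _attack(i, xi, yi, clock, n_attackers, thresholds, infested, episode,
                attack_window, pend_tree, pend_deadline, pend_state,
                fate, tree_col, tree_row, beetle_episode)
        return

    # --- move -------------------------------------------------------
    if bx >= 0:
        # greedy chase: 8-direction step minimizing distance to target
        best_dir = 0
        best_dist = np.int64(1) << 60
        for d in range(8):
            ddx = xi + DIR_DX[d] - bx
            ddy = yi + DIR_DY[d] - by
            dist = ddx * ddx + ddy * ddy
            if dist < best_dist:
                best_dist = dist
                best_dir = d
        heading[i] = best_dir
    else:
        u = rng.random()
        heading[i] = (heading[i] + (int(u * 3.0) - 1) + 8) % 8
    nx = xi + DIR_DX[heading[i]]
    ny = yi + DIR_DY[heading[i]]
    e -= consumption[i]
    x[i] = nx
    y[i] = ny
    energy[i] = e
    steps_flown[i] += 1
    if nx < 0 or nx >= side or ny < 0 or ny >= side:
        fate[i] = EMIGRATED
        return

    # --- try attack at the new position -----------------------------
    a_here = _attractiveness(pa[nx, ny], n_attackers[nx, ny], thresholds[nx, ny], capacity, a_pher, gain, trigger)
    if a_here >= 1.0 and a_here >= kappa * e and n_attackers[nx, ny] < capacity:
        _attack(i, nx, ny, clock, n_attackers, thresholds, infested, episode,
                attack_window, pend_tree, pend_deadline, pend_state,
                fate, tree_col, tree_row, beetle_episode)
        return

    if e <= ENERGY_EPS:
        fate[i] = DIED_ENERGY


@njit(cache=True)
def _step_once(
    clock,
    pa,
    n_attackers,
    capacity,
    a_pher,
    gain,
    trigger,
    prefer_nearest,
    kappa,
    thresholds,
    infested,
    episode,
    attack_window,
    pend_tree,
    pend_deadline,
    pend_state,
    off_dx,
    off_dy,
    off_d2,
    x,
    y,
    heading,
    energy,
    consumption,
    fate,
    steps_flown,
    tree_col,
    tree_row,
    beetle_episode,
    start_step,
    active_buf,
    rng,
):
    """One global time step: activate cohorts, shuffle, sub-step each flyer.

    Expired attack windows are failed first, then active beetles
    (flying and ``start_step <= clock``) are collected in ascending id
    order and uniformly shuffled.  Tree attacker counts update
    immediately (asynchronously), so beetles later in the shuffled order
    see attacks made earlier in the same step.  Returns the number of
    beetles processed.
    """
    _expire_windows(clock, n_attackers, infested, episode,
                    pend_tree, pend_deadline, pend_state)
    n = fate.shape[0]
    m = 0
    for i in range(n):
        if fate[i] == FLYING and start_step[i] <= clock:
            active_buf[m] = i
            m += 1
    for i in range(m - 1, 0, -1):
        j = int(rng.random() * (i + 1))
        tmp = active_buf[i]
        active_buf[i] = active_buf[j]
        active_buf[j] = tmp
    for k in range(m):
        _beetle_substep(
            active_buf[k],
            clock,
            pa,
            n_attackers,
            capacity,
            a_pher,
            gain,
            trigger,
            prefer_nearest,
            kappa,
            thresholds,
            infested,
            episode,
            attack_window,
            pend_tree,
            pend_deadline,
            pend_state,
            off_dx,
            off_dy,
            off_d2,
            x,
            y,
            heading,
            energy,
            consumption,
            fate,
            steps_flown,
            tree_col,
            tree_row,
            beetle_episode,
            rng,
        )
    return m
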
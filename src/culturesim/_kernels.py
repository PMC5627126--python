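"""Compiled inner loops of the simulator.

State is held in flat arrays indexed by current individual slot:
``age`` (1..5), ``parent`` (current index of the living parent, -1 if none or
dead), ``variants`` with shape (5 trait slots, N) holding variant labels 1..5,
``born_in_sim`` (founders excluded from lifetime-event logging) and
``n_events`` (lifetime transmission events on the age-neutral trait, used for
the 5*p_w calibration).

Trait slots follow ``params.MODE_ORDER``: 0 vertical, 1 horizontal,
2 oblique, 3 age-neutral, 4 mixed.

Transmission events are sampled from per-(slot, age-group, variant) count
tables maintained incrementally, so a single event costs O(n_variants)
regardless of N: drawing a partner uniformly from an eligible set and copying
its variant is distributionally identical to drawing a variant from the set's
count vector.  Asynchronous updating is preserved because the count tables
are updated after every adoption.
"""

import numpy as np
from numba import njit

N_AGES = 5
N_VAR = 5
SLOT_V, SLOT_H, SLOT_O, SLOT_N, SLOT_M = 0, 1, 2, 3, 4


@njit(cache=True)
def seed_rng(seed):
    # numba's nrt random state is separate from the interpreter's
    np.random.seed(seed)


@njit(cache=True)
def mutate_variant(variant, mu, include_current):
    """Copy with fidelity 1-mu; otherwise a uniform random variant."""
    if mu > 0.0 and np.random.random() < mu:
        if include_current:
            return np.random.randint(1, N_VAR + 1)
        v = np.random.randint(1, N_VAR)
        if v >= variant:
            v += 1
        return v
    return variant


@njit(cache=True)
def init_population(N):
    """Founders: uniform random age group, variant 1 everywhere, no parent."""
    age = np.random.randint(1, N_AGES + 1, N)
    parent = np.full(N, -1, np.int64)
    variants = np.ones((N_VAR, N), np.int64)
    born_in_sim = np.zeros(N, np.bool_)
    n_events = np.zeros(N, np.int64)
    return age, parent, variants, born_in_sim, n_events


@njit(cache=True)
def demographic_step(age, parent, variants, born_in_sim, n_events,
                     p_death, mu, include_current, completed, n_completed):
    """Ageing, deaths and births restoring size N.

    Order: every survivor ages one class; individuals leaving class 5 are
    removed (they lived one full step in class 5, then die); the remaining
    individuals die independently with ``p_death``; parents are then drawn
    uniformly with replacement from survivors in classes 2-3 until size N is
    restored, each newborn entering class 1 with a mutated vertical copy of
    the parent's variants in every trait slot.

    Returns new state arrays, the updated completed-lifespan counter and an
    extinction flag (no eligible parent while below size N).
    """
    N = age.shape[0]
    new_idx = np.full(N, -1, np.int64)
    n_surv = 0
    for i in range(N):
        if age[i] + 1 > N_AGES:
            # survived all five classes; log lifetime events for non-founders
            if born_in_sim[i] and n_completed < completed.shape[0]:
                completed[n_completed] = n_events[i]
                n_completed += 1
            continue
        if p_death > 0.0 and np.random.random() < p_death:
            continue
        new_idx[i] = n_surv
        n_surv += 1

    new_age = np.empty(N, np.int64)
    new_parent = np.full(N, -1, np.int64)
    new_variants = np.empty((N_VAR, N), np.int64)
    new_born = np.zeros(N, np.bool_)
    new_events = np.zeros(N, np.int64)
    for i in range(N):
        j = new_idx[i]
        if j >= 0:
            new_age[j] = age[i] + 1
            p = parent[i]
            new_parent[j] = new_idx[p] if p >= 0 else -1
            for s in range(N_VAR):
                new_variants[s, j] = variants[s, i]
            new_born[j] = born_in_sim[i]
            new_events[j] = n_events[i]

    # eligible parents: current classes 2 and 3
    n_par = 0
    par_idx = np.empty(max(n_surv, 1), np.int64)
    for j in range(n_surv):
        if new_age[j] == 2 or new_age[j] == 3:
            par_idx[n_par] = j
            n_par += 1

    pos = n_surv
    if pos < N and n_par == 0:
        return (new_age, new_parent, new_variants, new_born, new_events,
                n_completed, True)
    while pos < N:
        p = par_idx[np.random.randint(0, n_par)]
        new_age[pos] = 1
        new_parent[pos] = p
        for s in range(N_VAR):
            new_variants[s, pos] = mutate_variant(new_variants[s, p], mu,
                                                  include_current)
        new_born[pos] = True
        new_events[pos] = 0
        pos += 1
    return (new_age, new_parent, new_variants, new_born, new_events,
            n_completed, False)


@njit(cache=True)
def count_table(age, variants):
    """Counts with shape (slot, age group, variant), 0-based indices."""
    N = age.shape[0]
    counts = np.zeros((N_VAR, N_AGES, N_VAR), np.int64)
    for i in range(N):
        a = age[i] - 1
        for s in range(N_VAR):
            counts[s, a, variants[s, i] - 1] += 1
    return counts


@njit(cache=True)
def transmission_step(age, parent, variants, n_events,
                      p_w, p_mix, mu, b, include_current, khat_global):
    """One round of asynchronous lifetime transmission events.

    Individuals are visited in a fresh random order.  For each non-vertical
    trait slot independently, with probability ``p_w`` an event occurs: the
    mixed slot resolves to oblique with probability ``p_mix`` (else
    horizontal); the partner set is taken against current state; a variant is
    drawn from the partner set's (possibly conformity-weighted) variant
    frequencies and passed through mutation.  Empty partner sets (or fully
    clamped conformity weights) make the event a no-op.

    Returns the post-step count table.
    """
    N = age.shape[0]
    counts = count_table(age, variants)
    order = np.random.permutation(N)
    pc = np.empty(N_VAR, np.float64)
    for oi in range(N):
        i = order[oi]
        ai = age[i] - 1
        for s in range(1, N_VAR):
            if p_w < 1.0 and np.random.random() >= p_w:
                continue
            rule = s
            if s == SLOT_M:
                rule = SLOT_O if np.random.random() < p_mix else SLOT_H

            if rule == SLOT_H:
                # same age group, excluding self
                for k in range(N_VAR):
                    pc[k] = counts[s, ai, k]
                pc[variants[s, i] - 1] -= 1
            elif rule == SLOT_O:
                # strictly older, excluding the living parent (always older)
                for k in range(N_VAR):
                    pc[k] = 0.0
                for a in range(ai + 1, N_AGES):
                    for k in range(N_VAR):
                        pc[k] += counts[s, a, k]
                p = parent[i]
                if p >= 0:
                    pc[variants[s, p] - 1] -= 1
            else:
                # age-neutral: everyone, excluding self
                for k in range(N_VAR):
                    tot = 0.0
                    for a in range(N_AGES):
                        tot += counts[s, a, k]
                    pc[k] = tot
                pc[variants[s, i] - 1] -= 1

            nstar = 0.0
            for k in range(N_VAR):
                nstar += pc[k]
            if nstar <= 0.0:
                continue

            if b > 0.0:
                khat = 0
                if khat_global:
                    for k in range(N_VAR):
                        tot = 0.0
                        for a in range(N_AGES):
                            tot += counts[s, a, k]
                        if tot > 0.0:
                            khat += 1
                else:
                    for k in range(N_VAR):
                        if pc[k] > 0.0:
                            khat += 1
                wsum = 0.0
                for k in range(N_VAR):
                    w = pc[k] / nstar + b * (khat * pc[k] / nstar - 1.0)
                    if w < 0.0:
                        w = 0.0
                    pc[k] = w
                    wsum += w
                if wsum <= 0.0:
                    continue
            else:
                wsum = nstar

            u = np.random.random() * wsum
            k = 0
            c = pc[0]
            while c < u and k < N_VAR - 1:
                k += 1
                c += pc[k]

            if s == SLOT_N:
                n_events[i] += 1
            new_v = mutate_variant(k + 1, mu, include_current)
            old_v = variants[s, i]
            if new_v != old_v:
                counts[s, ai, old_v - 1] -= 1
                counts[s, ai, new_v - 1] += 1
                variants[s, i] = new_v
    return counts


@njit(cache=True)
def simulate(N, mu, p_w, p_mix, b, p_death, burn_in, recorded, seed,
             include_current, khat_global, completed_capacity):
    """Full run: init, burn-in + recorded steps of (demography, transmission).

    Returns (trajectory with shape (recorded, slot, variant), final count
    table with shape (slot, age, variant), completed-lifespan event counts,
    survived flag).  On extinction the trajectory is truncated at the last
    completed step and survived is False.
    """
    np.random.seed(seed)
    age, parent, variants, born, n_events = init_population(N)
    completed = np.zeros(completed_capacity, np.int64)
    n_completed = 0
    traj = np.zeros((recorded, N_VAR, N_VAR), np.int64)
    final_counts = np.zeros((N_VAR, N_AGES, N_VAR), np.int64)
    for t in range(burn_in + recorded):
        (age, parent, variants, born, n_events,
         n_completed, extinct) = demographic_step(
            age, parent, variants, born, n_events, p_death, mu,
            include_current, completed, n_completed)
        if extinct:
            return traj, final_counts, completed[:n_completed], False
        counts = transmission_step(age, parent, variants, n_events,
                                   p_w, p_mix, mu, b, include_current,
                                   khat_global)
        if t >= burn_in:
            r = t - burn_in
            for s in range(N_VAR):
                for k in range(N_VAR):
                    c = 0
                    for a in range(N_AGES):
                        c += counts[s, a, k]
                    traj[r, s, k] = c
            if r == recorded - 1:
                final_counts = counts
    return traj, final_counts, completed[:n_completed], True


@njit(cache=True)
def one_step(age, parent, variants, p_death, mu, p_w, p_mix, b,
             include_current, khat_global, seed):
    """One full time step (demography then transmission) on given state.

    Returns (post-step count table, extinct flag).  Used for the one-step
    mutant-spread distribution.
    """
    np.random.seed(seed)
    N = age.shape[0]
    born = np.zeros(N, np.bool_)
    n_events = np.zeros(N, np.int64)
    completed = np.zeros(1, np.int64)
    (age, parent, variants, born, n_events, _nc, extinct) = demographic_step(
        age, parent, variants, born, n_events, p_death, mu, include_current,
        completed, 0)
    if extinct:
        return np.zeros((N_VAR, N_AGES, N_VAR), np.int64), True
    counts = transmission_step(age, parent, variants, n_events, p_w, p_mix,
                               mu, b, include_current, khat_global)
    return counts, False
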
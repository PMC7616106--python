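"""Independent brute-force oracles used by the test suite.

These re-derive expected values with naive anchor-interpolation loops and
textbook formulas, deliberately sharing no code with the package
implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm


def naive_trajectory(order, event_biomarker, event_z, z_max, n_biomarkers, stage):
    """Piece-wise linear expected z at an integer stage, by direct interpolation."""
    N = len(order)
    values = np.zeros(n_biomarkers)
    for b in range(n_biomarkers):
        anchors = [(0.0, 0.0)]
        for pos, ev in enumerate(order, start=1):
            if event_biomarker[ev] == b:
                anchors.append((float(pos), float(event_z[ev])))
        if z_max[b] > anchors[-1][1] and anchors[-1][0] < N:
            anchors.append((float(N), float(z_max[b])))
        xs = [a[0] for a in anchors]
        ys = [a[1] for a in anchors]
        if stage <= xs[0]:
            values[b] = ys[0]
        elif stage >= xs[-1]:
            values[b] = ys[-1]
        else:
            for k in range(len(xs) - 1):
                if xs[k] <= stage <= xs[k + 1]:
                    frac = (stage - xs[k]) / (xs[k + 1] - xs[k])
                    values[b] = ys[k] + frac * (ys[k + 1] - ys[k])
                    break
    return values


def naive_marginal_loglik(z_rows, order, event_biomarker, event_z, z_max, sigma):
    """Stage-averaged Gaussian likelihood, enumerating stages explicitly."""
    z_rows = np.atleast_2d(np.asarray(z_rows, dtype=float))
    n_bio = z_rows.shape[1]
    N = len(order)
    mus = np.stack(
        [
            naive_trajectory(order, event_biomarker, event_z, z_max, n_bio, k)
            for k in range(N + 1)
        ]
    )
    # likelihood per subject and stage: product of the biomarker densities
    dens = norm.pdf(z_rows[:, None, :], loc=mus[None, :, :], scale=sigma)
    return np.log(dens.prod(axis=2).mean(axis=1))


def all_valid_orderings(event_biomarker, event_z):
    """Every permutation of the events that keeps each biomarker's grid order."""
    n = len(event_biomarker)
    for perm in itertools.permutations(range(n)):
        ok = True
        for b in set(event_biomarker.tolist()):
            zs = [event_z[e] for e in perm if event_biomarker[e] == b]
            if zs != sorted(zs):
                ok = False
                break
        if ok:
            yield np.array(perm)


def brute_force_best_loglik(z_rows, event_biomarker, event_z, z_max, sigma):
    """Exhaustive maximum of the total marginal log-likelihood over orderings."""
    best = -np.inf
    best_order = None
    for order in all_valid_orderings(event_biomarker, event_z):
        ll = float(
            naive_marginal_loglik(
                z_rows, order, event_biomarker, event_z, z_max, sigma
            ).sum()
        )
        if ll > best:
            best, best_order = ll, order
    return best, best_order


def binomial_central_interval(n, p, coverage=0.99):
    """Central interval of Binomial(n, p) by direct quantiles."""
    from scipy.stats import binom

    alpha = (1.0 - coverage) / 2.0
    return binom.ppf(alpha, n, p), binom.ppf(1 - alpha, n, p)
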
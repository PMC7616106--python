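"""Linear z-score subtype-and-stage inference (SuStaIn) for lobar CT scores.

The model treats each of the 12 biomarkers (fibrosis and emphysema extent in
six lobes, z-scored by interobserver variability) as a monotonically
increasing piece-wise linear function of disease stage.  A *z-score event* is
the transition of a biomarker past one of its grid values z_1 < z_2 < ... and
a subtype is a full ordering of all events.  Stage k means the first k events
have occurred; a subject's likelihood marginalises over stages with a uniform
prior.  Fitting alternates expectation-maximisation over subtype memberships
with greedy single-event-relocation ascent over orderings, refined by
Metropolis-Hastings sampling; the subtype count is chosen by subject-level
cross-validated log-likelihood with a one-standard-error rule.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import kendalltau


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Max-shifted log-sum-exp (hot path; scipy's version is far slower)."""
    m = np.max(a, axis=axis, keepdims=True)
    with np.errstate(divide="ignore"):
        return np.squeeze(m, axis=axis) + np.log(
            np.sum(np.exp(a - m), axis=axis)
        )

from .errors import ConfigurationError, ValidationError
from .grouping import BIOMARKER_COLS, EMPHYSEMA_COLS

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class ZScoreMatrix:
    """Subjects x biomarkers of z-scores plus per-biomarker event metadata.

    ``event_grids[i]`` holds the strictly increasing z-score event values of
    biomarker ``i``; ``z_max[i]`` is the value the biomarker reaches at end
    stage (>= the last grid value; a terminal ramp exists only when strictly
    greater).
    """

    z: np.ndarray
    biomarkers: tuple[str, ...]
    event_grids: tuple[np.ndarray, ...]
    z_max: np.ndarray
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[1] != len(self.biomarkers):
            raise ValidationError("z must be (subjects x biomarkers)")
        if not np.all(np.isfinite(self.z)) or (self.z < 0).any():
            raise ValidationError("z-scores must be finite and non-negative")
        self.z_max = np.asarray(self.z_max, dtype=float)
        grids = []
        for i, g in enumerate(self.event_grids):
            g = np.asarray(g, dtype=float)
            if g.size == 0 or (np.diff(g) <= 0).any() or (g <= 0).any():
                raise ValidationError(
                    f"event grid of {self.biomarkers[i]} must be positive and strictly increasing"
                )
            if self.z_max[i] < g[-1]:
                raise ValidationError(
                    f"z_max of {self.biomarkers[i]} below last grid value"
                )
            grids.append(g)
        self.event_grids = tuple(grids)
        # canonical event enumeration: biomarker-major, grid order within
        self.event_biomarker = np.concatenate(
            [np.full(len(g), i, dtype=int) for i, g in enumerate(self.event_grids)]
        )
        self.event_z = np.concatenate(self.event_grids)

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return self.z.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event_biomarker.size)

    def subset(self, idx: np.ndarray) -> "ZScoreMatrix":
        ids = self.subject_ids[idx] if self.subject_ids is not None else None
        return ZScoreMatrix(
            self.z[idx], self.biomarkers, self.event_grids, self.z_max, ids
        )


@dataclass
class SubtypeModel:
    """Fitted state: orderings, mixture fractions, noise scales, MCMC samples."""

    n_subtypes: int
    orderings: list[np.ndarray]
    fractions: np.ndarray
    sigma: np.ndarray
    biomarkers: tuple[str, ...]
    event_grids: tuple[np.ndarray, ...]
    z_max: np.ndarray
    log_likelihood: float
    loglik_trace: list[float] = field(default_factory=list)
    mcmc_samples: np.ndarray | None = None  # (n_samples, C, N) event indices
    converged: bool = True
    cv_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "n_subtypes": self.n_subtypes,
            "orderings": [o.tolist() for o in self.orderings],
            "fractions": self.fractions.tolist(),
            "sigma": self.sigma.tolist(),
            "biomarkers": list(self.biomarkers),
            "event_grids": [g.tolist() for g in self.event_grids],
            "z_max": self.z_max.tolist(),
            "log_likelihood": self.log_likelihood,
            "converged": bool(self.converged),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class SubjectAssignment:
    """Posterior over (subtype, stage) per subject plus point summaries."""

    posterior: np.ndarray  # (n, C, N+1), rows sum to 1
    table: pd.DataFrame  # subject_id, map_subtype, map_stage, expected_stage, p_subtype_*


# ---------------------------------------------------------------------------
# z-scoring and cohort restriction


def compute_zscores(
    extents: pd.DataFrame,
    sd_map: Mapping[str, float],
    event_grids: Sequence[np.ndarray] | None = None,
    z_max: Sequence[float] | None = None,
    biomarkers: Sequence[str] = BIOMARKER_COLS,
) -> ZScoreMatrix:
    """Divide each biomarker's extent by its interobserver SD.

    Default event grids are the integer z-scores {1, 2, ..., z_max_i}, with
    z_max_i the 95th percentile of the observed z-scores rounded up to the
    next integer (at least 1).
    """
    biomarkers = tuple(biomarkers)
    z = np.empty((len(extents), len(biomarkers)))
    for j, b in enumerate(biomarkers):
        sd = sd_map.get(b)
        if sd is None or sd <= 0:
            raise ConfigurationError(f"interobserver SD must be > 0 for biomarker {b}")
        if b not in extents.columns:
            raise ValidationError(f"missing extent column {b}")
        z[:, j] = extents[b].to_numpy(dtype=float) / float(sd)
    if (z < 0).any():
        raise ValidationError("extents must be non-negative")
    if z_max is None:
        if len(extents) == 0:
            zm = np.ones(len(biomarkers))
        else:
            q95 = np.quantile(z, 0.95, axis=0)
            zm = np.maximum(1.0, np.ceil(q95 - 1e-9))
    else:
        zm = np.asarray(z_max, dtype=float)
    if event_grids is None:
        event_grids = tuple(np.arange(1.0, m + 0.5) for m in zm)
    ids = (
        extents["subject_id"].to_numpy()
        if "subject_id" in extents.columns
        else np.arange(len(extents))
    )
    return ZScoreMatrix(z, biomarkers, tuple(event_grids), zm, ids)


def restrict_to_emphysema(
    patients: pd.DataFrame, panels: pd.DataFrame
) -> pd.DataFrame:
    """Keep only subjects with emphysema scored in any lobe (extent > 0).

    Subjects without emphysema cannot progress along an emphysema trajectory,
    which would break the model's monotonic-increase assumption.
    """
    emph = panels.loc[:, list(EMPHYSEMA_COLS)].to_numpy(dtype=float)
    has_emph = (emph > 0).any(axis=1)
    keep_ids = set(panels.loc[has_emph, "subject_id"])
    out = patients[patients["subject_id"].isin(keep_ids)].copy()
    logger.info(
        "emphysema restriction excluded %d of %d subjects",
        len(patients) - len(out),
        len(patients),
    )
    return out


# ---------------------------------------------------------------------------
# orderings and trajectories


def is_valid_ordering(zm: ZScoreMatrix, order: np.ndarray) -> bool:
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(zm.n_events)):
        return False
    pos = np.empty(zm.n_events, dtype=int)
    pos[order] = np.arange(zm.n_events)
    start = 0
    for g in zm.event_grids:
        p = pos[start : start + len(g)]
        if (np.diff(p) <= 0).any():
            return False
        start += len(g)
    return True


def _repair_ordering(order: np.ndarray, event_biomarker: np.ndarray) -> np.ndarray:
    """Reassign each biomarker's events to its occupied slots in grid order."""
    order = np.asarray(order).copy()
    bio_of_slot = event_biomarker[order]
    for b in np.unique(event_biomarker):
        slots = np.nonzero(bio_of_slot == b)[0]
        order[slots] = np.nonzero(event_biomarker == b)[0]
    return order


def random_valid_ordering(zm: ZScoreMatrix, rng: np.random.Generator) -> np.ndarray:
    return _repair_ordering(rng.permutation(zm.n_events), zm.event_biomarker)


def trajectory_matrix(zm: ZScoreMatrix, order: np.ndarray) -> np.ndarray:
    """Expected z of every biomarker at every stage, shape (N+1, biomarkers).

    A biomarker is 0 before its first event, hits grid value z_r at the stage
    where event (i, r) occurs, and ramps to z_max at stage N only when z_max
    exceeds the last grid value; between anchors it is linearly interpolated.
    """
    N = zm.n_events
    pos = np.empty(N, dtype=float)
    pos[np.asarray(order)] = np.arange(1, N + 1)
    stages = np.arange(N + 1, dtype=float)
    T = np.empty((N + 1, zm.n_biomarkers))
    zero = np.zeros(1)
    start = 0
    for i, g in enumerate(zm.event_grids):
        p = pos[start : start + len(g)]
        # terminal ramp toward z_max only when there is room after the last event
        if zm.z_max[i] > g[-1] + 1e-12 and p[-1] < N:
            xp = np.concatenate((zero, p, (float(N),)))
            fp = np.concatenate((zero, g, (float(zm.z_max[i]),)))
        else:
            xp = np.concatenate((zero, p))
            fp = np.concatenate((zero, g))
        T[:, i] = np.interp(stages, xp, fp)
        start += len(g)
    return T


def trajectory_value(
    zm: ZScoreMatrix, order: np.ndarray, stage: int, biomarker: int
) -> float:
    """Expected z-score of one biomarker at one integer stage."""
    if not 0 <= stage <= zm.n_events:
        raise ValidationError(f"stage {stage} outside [0, {zm.n_events}]")
    return float(trajectory_matrix(zm, order)[stage, biomarker])


# ---------------------------------------------------------------------------
# likelihood


class _LikelihoodCache:
    """Precomputed subject terms for fast stage-marginal likelihood evaluation."""

    def __init__(self, zm: ZScoreMatrix, sigma: np.ndarray):
        sigma = np.asarray(sigma, dtype=float)
        if (sigma <= 0).any():
            raise ConfigurationError("noise SDs must be > 0")
        self.zm = zm
        self.sigma = sigma
        self.zs = zm.z / sigma  # scaled observations
        self.z_sq = 0.5 * np.einsum("nb,nb->n", self.zs, self.zs)
        self.const = -0.5 * zm.n_biomarkers * _LOG_2PI - float(np.sum(np.log(sigma)))
        self.log_n_stages = math.log(zm.n_events + 1)

    def stage_loglik(self, order: np.ndarray) -> np.ndarray:
        """(subjects x stages) Gaussian log-likelihood at each stage."""
        Ts = trajectory_matrix(self.zm, order) / self.sigma
        t_sq = 0.5 * np.einsum("kb,kb->k", Ts, Ts)
        return (
            self.zs @ Ts.T - t_sq[None, :] - self.z_sq[:, None] + self.const
        )

    def marginal(self, order: np.ndarray) -> np.ndarray:
        """Per-subject log marginal likelihood under a uniform stage prior."""
        return _lse(self.stage_loglik(order), axis=1) - self.log_n_stages

    def total(self, order: np.ndarray, weights: np.ndarray | None = None) -> float:
        m = self.marginal(order)
        return float(m.sum() if weights is None else weights @ m)

    def total_batch(
        self, orders: list[np.ndarray], weights: np.ndarray | None = None
    ) -> np.ndarray:
        """Total (weighted) log-likelihood of several candidate orderings in
        one vectorised pass — the greedy relocation scan's inner loop."""
        T = np.stack([trajectory_matrix(self.zm, o) for o in orders]) / self.sigma
        ll = (
            np.einsum("nb,wkb->wnk", self.zs, T)
            - 0.5 * np.einsum("wkb,wkb->wk", T, T)[:, None, :]
            - self.z_sq[None, :, None]
            + self.const
        )
        marg = _lse(ll, axis=2) - self.log_n_stages
        if weights is None:
            return marg.sum(axis=1)
        return marg @ weights


def subject_log_likelihood(
    zm: ZScoreMatrix, order: np.ndarray, sigma: np.ndarray | float = 1.0
) -> np.ndarray:
    """Log of the stage-averaged Gaussian likelihood, one value per subject.

    log[ (1/(N+1)) sum_k prod_i Normal(z_i; trajectory(k, i), sigma_i) ].
    """
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (zm.n_biomarkers,))
    return _LikelihoodCache(zm, sigma).marginal(order)


def mixture_log_likelihood(
    margs: np.ndarray, fractions: np.ndarray
) -> float:
    """Observed-data log-likelihood of the subtype mixture from (n x C) marginals."""
    with np.errstate(divide="ignore"):
        logf = np.log(fractions)
    return float(np.sum(_lse(margs + logf[None, :], axis=1)))


# ---------------------------------------------------------------------------
# optimisation over orderings


def _relocation_window(
    order: np.ndarray, event: int, event_biomarker: np.ndarray
) -> tuple[np.ndarray, int, int]:
    """Remove ``event`` from ``order``; return reduced order and the feasible
    insertion-slot range [lo, hi] that keeps within-biomarker monotonicity."""
    order = np.asarray(order)
    j = int(np.nonzero(order == event)[0][0])
    reduced = np.delete(order, j)
    b = event_biomarker[event]
    same = np.nonzero(event_biomarker == b)[0]
    r = int(np.nonzero(same == event)[0][0])
    lo, hi = 0, len(reduced)
    if r > 0:
        lo = int(np.nonzero(reduced == same[r - 1])[0][0]) + 1
    if r < len(same) - 1:
        hi = int(np.nonzero(reduced == same[r + 1])[0][0])
    return reduced, lo, hi


def greedy_ascent(
    cache: _LikelihoodCache,
    order: np.ndarray,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
    max_sweeps: int = 10,
) -> tuple[np.ndarray, float]:
    """Single-event relocation hill climbing on the (weighted) log-likelihood."""
    order = np.asarray(order).copy()
    ll = cache.total(order, weights)
    eb = cache.zm.event_biomarker
    for _ in range(max_sweeps):
        improved = False
        for event in rng.permutation(cache.zm.n_events):
            reduced, lo, hi = _relocation_window(order, int(event), eb)
            cands = [np.insert(reduced, pos, event) for pos in range(lo, hi + 1)]
            lls = cache.total_batch(cands, weights)
            j = int(np.argmax(lls))
            if lls[j] > ll + 1e-10:
                order, ll = cands[j], float(lls[j])
                improved = True
        if not improved:
            break
    return order, ll


def _mcmc_refine(
    cache: _LikelihoodCache,
    orderings: list[np.ndarray],
    fractions: np.ndarray,
    rng: np.random.Generator,
    iterations: int,
    thin: int | None = None,
) -> tuple[list[np.ndarray], float, np.ndarray]:
    """Metropolis-Hastings over orderings of all subtypes jointly.

    Proposal: relocate one event of one subtype uniformly within its feasible
    window (symmetric).  Mixture fractions are held fixed.  Returns the best
    (MAP) orderings visited, their mixture log-likelihood, and thinned samples.
    """
    C = len(orderings)
    orderings = [o.copy() for o in orderings]
    margs = np.column_stack([cache.marginal(o) for o in orderings])
    ll = mixture_log_likelihood(margs, fractions)
    best_orderings = [o.copy() for o in orderings]
    best_ll = ll
    thin = thin or max(1, iterations // 200)
    samples = []
    eb = cache.zm.event_biomarker
    for it in range(iterations):
        c = int(rng.integers(C))
        event = int(rng.integers(cache.zm.n_events))
        reduced, lo, hi = _relocation_window(orderings[c], event, eb)
        pos = int(rng.integers(lo, hi + 1))
        cand = np.insert(reduced, pos, event)
        cand_marg = cache.marginal(cand)
        new_margs = margs.copy()
        new_margs[:, c] = cand_marg
        cand_ll = mixture_log_likelihood(new_margs, fractions)
        if cand_ll >= ll or math.log(rng.random()) < cand_ll - ll:
            orderings[c], margs, ll = cand, new_margs, cand_ll
            if ll > best_ll:
                best_ll = ll
                best_orderings = [o.copy() for o in orderings]
        if (it + 1) % thin == 0:
            samples.append(np.stack(orderings))
    return best_orderings, best_ll, np.array(samples)


# ---------------------------------------------------------------------------
# fitting


def _fit_single(
    cache: _LikelihoodCache,
    rng: np.random.Generator,
    n_startpoints: int,
    weights: np.ndarray | None = None,
    init: np.ndarray | None = None,
    max_sweeps: int = 10,
) -> tuple[np.ndarray, float]:
    """Best-of-multistart greedy ascent for one subtype's ordering."""
    best_order, best_ll = None, -np.inf
    starts = []
    if init is not None:
        starts.append(np.asarray(init).copy())
    while len(starts) < max(1, n_startpoints):
        starts.append(random_valid_ordering(cache.zm, rng))
    for start in starts:
        order, ll = greedy_ascent(cache, start, rng, weights, max_sweeps)
        if ll > best_ll:
            best_order, best_ll = order, ll
    return best_order, best_ll


def _em(
    cache: _LikelihoodCache,
    orderings: list[np.ndarray],
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[list[np.ndarray], np.ndarray, float, list[float], bool]:
    """EM over mixture fractions/responsibilities with greedy ordering M-steps."""
    C = len(orderings)
    fractions = np.full(C, 1.0 / C)
    margs = np.column_stack([cache.marginal(o) for o in orderings])
    trace = [mixture_log_likelihood(margs, fractions)]
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            logpost = margs + np.log(fractions)[None, :]
        logpost -= logsumexp(logpost, axis=1, keepdims=True)
        gamma = np.exp(logpost)
        fractions = np.clip(gamma.mean(axis=0), 1e-12, None)
        fractions /= fractions.sum()
        for c in range(C):
            orderings[c], _ = greedy_ascent(
                cache, orderings[c], rng, weights=gamma[:, c], max_sweeps=2
            )
            margs[:, c] = cache.marginal(orderings[c])
        trace.append(mixture_log_likelihood(margs, fractions))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    return orderings, fractions, trace[-1], trace, converged


def fit_sustain(
    zm: ZScoreMatrix,
    n_subtypes: int,
    n_startpoints: int = 25,
    mcmc_iterations: int = 10_000,
    seed: int | None = None,
    sigma: np.ndarray | float = 1.0,
    em_max_iter: int = 30,
    em_tol: float = 1e-6,
    n_split_tries: int = 4,
) -> SubtypeModel:
    """Hierarchical fit of the C-subtype linear z-score model.

    The 1-subtype solution is a best-of-multistart greedy ascent; each
    C-subtype solution is initialised by splitting the (C-1)-solution's
    largest-variance cluster, refined by EM with greedy ordering M-steps, and
    finally polished by Metropolis-Hastings sampling over orderings.
    Deterministic for a fixed seed.  A fit that exhausts its EM iterations is
    returned flagged non-converged rather than raised.
    """
    if n_subtypes < 1:
        raise ConfigurationError("n_subtypes must be >= 1")
    if zm.n_subjects < 5 * n_subtypes:
        logger.warning(
            "fitting %d subtypes with only %d subjects (heuristic floor 5/subtype)",
            n_subtypes,
            zm.n_subjects,
        )
    rng = np.random.default_rng(seed)
    sigma = np.broadcast_to(
        np.asarray(sigma, dtype=float), (zm.n_biomarkers,)
    ).copy()
    cache = _LikelihoodCache(zm, sigma)

    order1, _ = _fit_single(cache, rng, n_startpoints)
    orderings = [order1]
    fractions = np.array([1.0])
    trace = [cache.total(order1)]
    converged = True

    for c in range(2, n_subtypes + 1):
        # split the largest-variance cluster of the (c-1)-subtype solution
        margs = np.column_stack([cache.marginal(o) for o in orderings])
        with np.errstate(divide="ignore"):
            assign_c = np.argmax(margs + np.log(fractions)[None, :], axis=1)
        cluster_var = [
            zm.z[assign_c == j].var(axis=0).sum() if (assign_c == j).sum() > 1 else -1.0
            for j in range(c - 1)
        ]
        split = int(np.argmax(cluster_var))
        members = np.nonzero(assign_c == split)[0]
        best: tuple | None = None
        for attempt in range(max(1, n_split_tries)):
            if len(members) >= 4:
                a = b = None
                if attempt == 0:
                    # informed split: 2-means on the members' z-rows starts EM
                    # in the right basin far more often than a random split
                    from scipy.cluster.vq import kmeans2

                    _, lab = kmeans2(
                        zm.z[members], 2, minit="++",
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    if (lab == 0).sum() >= 2 and (lab == 1).sum() >= 2:
                        a, b = members[lab == 0], members[lab == 1]
                if a is None:
                    half = rng.permutation(members)
                    a, b = half[: len(half) // 2], half[len(half) // 2 :]
                cache_a = _LikelihoodCache(zm.subset(a), sigma)
                cache_b = _LikelihoodCache(zm.subset(b), sigma)
                oa, _ = _fit_single(cache_a, rng, 3, init=orderings[split], max_sweeps=4)
                ob, _ = _fit_single(cache_b, rng, 3, init=orderings[split], max_sweeps=4)
            else:  # too few members to split informatively: random restart
                oa = orderings[split]
                ob = random_valid_ordering(zm, rng)
            init = [o.copy() for j, o in enumerate(orderings) if j != split]
            init += [oa.copy(), ob.copy()]
            fitted, fr, ll, tr, conv = _em(cache, init, rng, em_max_iter, em_tol)
            if best is None or ll > best[2]:
                best = (fitted, fr, ll, tr, conv)
        orderings, fractions, _, trace, converged = best

    samples = None
    if mcmc_iterations > 0:
        orderings, map_ll, samples = _mcmc_refine(
            cache, orderings, fractions, rng, mcmc_iterations
        )
        # one EM pass to re-sync fractions with the MAP orderings
        orderings, fractions, map_ll, _, _ = _em(cache, orderings, rng, 1, em_tol)
    margs = np.column_stack([cache.marginal(o) for o in orderings])
    final_ll = mixture_log_likelihood(margs, fractions)
    return SubtypeModel(
        n_subtypes=n_subtypes,
        orderings=[np.asarray(o) for o in orderings],
        fractions=fractions,
        sigma=sigma,
        biomarkers=zm.biomarkers,
        event_grids=zm.event_grids,
        z_max=zm.z_max,
        log_likelihood=final_ll,
        loglik_trace=list(trace),
        mcmc_samples=samples,
        converged=bool(converged),
    )


def select_n_subtypes(
    zm: ZScoreMatrix,
    candidates: Sequence[int],
    n_folds: int = 3,
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the subtype count by K-fold cross-validated log-likelihood.

    Per candidate C the model is fitted on each training fold and the held-out
    subjects' mixture log-likelihood is recorded.  The chosen C maximises the
    mean CV log-likelihood, with a one-standard-error rule breaking near-ties
    toward fewer subtypes.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ConfigurationError("candidates must be non-empty")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if len(candidates) == 1:
        table = pd.DataFrame(
            {
                "n_subtypes": candidates,
                "cv_loglik_mean": [np.nan],
                "cv_loglik_se": [np.nan],
                "n_evaluated": [0],
            }
        )
        return candidates[0], table
    rng = np.random.default_rng(seed)
    n = zm.n_subjects
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    fit_kwargs.setdefault("n_startpoints", 5)
    fit_kwargs.setdefault("mcmc_iterations", 500)
    fit_kwargs.setdefault("n_split_tries", 2)
    sigma = fit_kwargs.pop("sigma", 1.0)
    per_subject = {c: np.full(n, np.nan) for c in candidates}
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        for c in candidates:
            if len(train_idx) < c:
                logger.warning("fold %d skipped for C=%d: too few subjects", k, c)
                continue
            model = fit_sustain(
                zm.subset(train_idx),
                c,
                seed=int(rng.integers(2**31 - 1)),
                sigma=sigma,
                **fit_kwargs,
            )
            test_zm = zm.subset(test_idx)
            cache = _LikelihoodCache(test_zm, model.sigma)
            margs = np.column_stack([cache.marginal(o) for o in model.orderings])
            with np.errstate(divide="ignore"):
                ll = logsumexp(margs + np.log(model.fractions)[None, :], axis=1)
            per_subject[c][test_idx] = ll
    rows = []
    for c in candidates:
        vals = per_subject[c][~np.isnan(per_subject[c])]
        rows.append(
            {
                "n_subtypes": c,
                "cv_loglik_mean": vals.mean() if len(vals) else -np.inf,
                "cv_loglik_se": vals.std(ddof=1) / math.sqrt(len(vals))
                if len(vals) > 1
                else 0.0,
                "n_evaluated": len(vals),
            }
        )
    table = pd.DataFrame(rows)
    best_row = table.loc[table["cv_loglik_mean"].idxmax()]
    floor = best_row["cv_loglik_mean"] - best_row["cv_loglik_se"]
    chosen = int(table.loc[table["cv_loglik_mean"] >= floor, "n_subtypes"].min())
    return chosen, table


def assign(model: SubtypeModel, zm: ZScoreMatrix) -> SubjectAssignment:
    """Posterior over (subtype, stage), computed in log space.

    posterior(c, k) is proportional to fraction_c times the Gaussian
    likelihood of the subject's z-row at stage k of subtype c's trajectory.
    """
    cache = _LikelihoodCache(zm, model.sigma)
    C = model.n_subtypes
    n, K = zm.n_subjects, zm.n_events + 1
    logpost = np.empty((n, C, K))
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions)
    for c in range(C):
        logpost[:, c, :] = cache.stage_loglik(model.orderings[c]) + logf[c]
    flat = logpost.reshape(n, -1)
    flat = flat - logsumexp(flat, axis=1, keepdims=True)
    post = np.exp(flat).reshape(n, C, K)
    p_subtype = post.sum(axis=2)
    map_subtype = p_subtype.argmax(axis=1)
    stages = np.arange(K)
    expected_stage = np.einsum("nck,k->n", post, stages)
    map_flat = flat.argmax(axis=1)
    table = pd.DataFrame(
        {
            "subject_id": zm.subject_ids
            if zm.subject_ids is not None
            else np.arange(n),
            "map_subtype": map_subtype,
            "map_stage": map_flat % K,
            "expected_stage": expected_stage,
        }
    )
    for c in range(C):
        table[f"p_subtype_{c}"] = p_subtype[:, c]
    return SubjectAssignment(posterior=post, table=table)


# ---------------------------------------------------------------------------
# recovery metrics and brute-force enumeration


def ordering_kendall_tau(order_a: np.ndarray, order_b: np.ndarray) -> float:
    """Kendall rank correlation between the event positions of two orderings."""
    order_a, order_b = np.asarray(order_a), np.asarray(order_b)
    pos_a = np.empty(order_a.size, dtype=int)
    pos_b = np.empty(order_b.size, dtype=int)
    pos_a[order_a] = np.arange(order_a.size)
    pos_b[order_b] = np.arange(order_b.size)
    return float(kendalltau(pos_a, pos_b).statistic)


def best_label_permutation_accuracy(
    true_labels: np.ndarray, pred_labels: np.ndarray, n_labels: int
) -> tuple[float, tuple[int, ...]]:
    """Accuracy maximised over label permutations (handles label switching)."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    best_acc, best_perm = -1.0, None
    for perm in itertools.permutations(range(n_labels)):
        mapped = np.array(perm)[pred_labels]
        acc = float(np.mean(mapped == true_labels))
        if acc > best_acc:
            best_acc, best_perm = acc, perm
    return best_acc, best_perm


def enumerate_valid_orderings(zm: ZScoreMatrix):
    """Yield every ordering of the event set that respects within-biomarker
    grid order.  Feasible only for small event sets (<= ~10 events)."""
    counts = [len(g) for g in zm.event_grids]
    starts = np.cumsum([0] + counts[:-1])

    def rec(remaining: list[int], prefix: list[int]):
        if not any(remaining):
            yield np.array(prefix, dtype=int)
            return
        for b, left in enumerate(remaining):
            if left:
                nxt = int(starts[b] + counts[b] - left)
                remaining[b] -= 1
                prefix.append(nxt)
                yield from rec(remaining, prefix)
                prefix.pop()
                remaining[b] += 1

    yield from rec(list(counts), [])
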
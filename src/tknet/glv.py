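"""Generalized Lotka-Volterra community simulation.

The population model for species i is

    dx_i/dt = r_i x_i (1 - x_i / K_i) + x_i * sum_{j != i} A_ij x_j

logistic growth with explicit carrying capacity K_i plus additive pairwise
interactions A (zero diagonal; self-limitation lives in the logistic term).
Communities are integrated to steady state; species-removal experiments on
those steady states define ground-truth keystoneness as the mean Canberra
distance a species' absence induces in the rest of the community.

The integrator is a batched, clipped forward-Euler fixed-point solver:
thousands of initial conditions are advanced simultaneously as columns of
one state matrix, with per-column convergence detection and active-set
shrinking. Fixed points of the discretized map coincide with equilibria of
the ODE, so the step size only affects the transient, not the answer;
tests verify steady states against closed forms and an adaptive ODE solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GLVModel",
    "CommunitySample",
    "KeystonenessRecord",
    "klemm_eguiluz_adjacency",
    "sample_interaction_matrix",
    "simulate_to_steady_state",
    "pool_size_for_similarity",
    "sample_community",
    "canberra",
    "true_keystoneness",
    "scale_keystoneness",
    "random_glv_model",
    "make_hub_model",
]


# ---------------------------------------------------------------------------
# model container and interaction-matrix generators
# ---------------------------------------------------------------------------

@dataclass
class GLVModel:
    """A gLV community model: growth rates, carrying capacities, interactions."""

    r: np.ndarray  # (S,) growth rates, in (0, 1]
    K: np.ndarray  # (S,) carrying capacities, in (0, 100]
    A: np.ndarray  # (S, S) interaction matrix, zero diagonal
    topology: str = "uniform"  # "uniform" | "klemm_eguiluz"
    connectivity: float = np.nan
    neg_pct: float = np.nan
    pool_similarity: float = np.nan
    seed: int | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        S = self.r.size
        if self.K.shape != (S,) or self.A.shape != (S, S):
            raise ValueError("inconsistent model dimensions")
        if np.any(self.r <= 0) or np.any(self.K <= 0):
            raise ValueError("growth rates and carrying capacities must be positive")

    @property
    def S(self) -> int:
        return self.r.size


@dataclass
class CommunitySample:
    """A steady-state community: a species subset of the pool and abundances."""

    species_idx: np.ndarray  # indices into the model pool
    abundance: np.ndarray  # (len(species_idx),) steady-state abundances
    converged: bool
    n_attempts: int = 1

    def pool_vector(self, pool_size: int) -> np.ndarray:
        """Abundances embedded in the full pool coordinate system (absent = 0)."""
        x = np.zeros(pool_size)
        x[self.species_idx] = self.abundance
        return x


@dataclass
class KeystonenessRecord:
    species_id: int
    keystoneness: float  # mean Canberra distance over removal iterations
    n_iter: int
    n_failed: int = 0
    scaled_keystoneness: float = np.nan


def klemm_eguiluz_adjacency(S: int, m0: int, mu: float, rng) -> np.ndarray:
    """Undirected Klemm-Eguíluz network as a boolean (S, S) adjacency matrix.

    Growth starts from a fully connected core of ``m0`` active nodes; each
    new node links to every active node, except that with probability ``mu``
    a link is rewired to a uniformly random existing node. The new node
    becomes active and one active node is deactivated with probability
    inversely proportional to its degree. The result is simultaneously
    scale-free, clustered and small-world.
    """
    if not 1 <= m0 < S:
        raise ValueError("need 1 <= m0 < S")
    adj = np.zeros((S, S), dtype=bool)
    active = list(range(m0))
    for i in range(m0):
        for j in range(i + 1, m0):
            adj[i, j] = adj[j, i] = True
    degree = adj.sum(axis=1).astype(float)
    for new in range(m0, S):
        for a in list(active):
            target = a
            if rng.random() < mu:
                # rewire to a random non-neighbor existing node
                candidates = [v for v in range(new) if v != new and not adj[new, v]]
                if candidates:
                    target = candidates[rng.integers(len(candidates))]
            if not adj[new, target] and target != new:
                adj[new, target] = adj[target, new] = True
                degree[new] += 1
                degree[target] += 1
        active.append(new)
        weights = 1.0 / np.maximum(degree[active], 1.0)
        drop = rng.choice(len(active), p=weights / weights.sum())
        active.pop(int(drop))
    return adj


def sample_interaction_matrix(
    S: int,
    connectivity: float,
    neg_pct: float,
    topology: str = "uniform",
    rng=None,
    strength: float = 0.01,
    ke_mu: float = 0.1,
) -> np.ndarray:
    """Draw a gLV interaction matrix with the requested support structure.

    Off-diagonal support is either i.i.d. Bernoulli(``connectivity``)
    ("uniform") or derived from a Klemm-Eguíluz graph whose density targets
    ``connectivity`` ("klemm_eguiluz"); magnitudes are uniform on
    (0, ``strength``]; signs are negative with probability ``neg_pct``/100;
    the diagonal is zero (self-limitation is carried by the logistic term).
    """
    if not 0 <= connectivity <= 1:
        raise ValueError("connectivity must be in [0, 1]")
    if not 0 <= neg_pct <= 100:
        raise ValueError("neg_pct must be in [0, 100]")
    if topology not in ("uniform", "klemm_eguiluz"):
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(rng)
    if connectivity == 0 or S < 2:
        return np.zeros((S, S))
    if topology == "uniform":
        support = rng.random((S, S)) < connectivity
    else:
        m0 = max(1, int(round(connectivity * (S - 1) / 2.0)))
        m0 = min(m0, S - 1)
        support = klemm_eguiluz_adjacency(S, m0, ke_mu, rng)
    np.fill_diagonal(support, False)
    A = np.zeros((S, S))
    magnitudes = rng.uniform(0.0, strength, size=(S, S))
    signs = np.where(rng.random((S, S)) < neg_pct / 100.0, -1.0, 1.0)
    A[support] = (magnitudes * signs)[support]
    return A


# ---------------------------------------------------------------------------
# batched steady-state integration
# ---------------------------------------------------------------------------

def simulate_to_steady_state(
    r: np.ndarray,
    K: np.ndarray,
    A: np.ndarray,
    x0: np.ndarray,
    t_max: float = 400.0,
    dt: float = 0.2,
    tol: float = 1e-4,
    extinction_eps: float = 1e-4,
    check_every: int = 25,
    blowup: float = 1e8,
):
    """Integrate gLV dynamics to steady state for a batch of initial states.

    Parameters
    ----------
    x0 : ndarray
        Either a single state of shape (S,) or a batch (S, B); each column
        is integrated independently under the same model.
    tol : float
        Convergence criterion: max_i |dx_i/dt| < tol * max_i x_i per column.
    extinction_eps : float
        Abundances below this are clamped to zero at each check point
        (species extinction).

    Returns
    -------
    x : ndarray, same shape as ``x0`` — final states (failed columns NaN)
    converged : bool or (B,) bool
    failed : bool or (B,) bool — non-finite/diverging integrations
    """
    r = np.asarray(r, dtype=float).reshape(-1, 1)
    K = np.asarray(K, dtype=float).reshape(-1, 1)
    A = np.asarray(A, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    single = x0.ndim == 1
    X = x0.reshape(-1, 1).copy() if single else x0.copy()
    if np.any(X < 0):
        raise ValueError("initial abundances must be non-negative")
    S, B = X.shape
    if A.shape != (S, S):
        raise ValueError("interaction matrix does not match state dimension")

    converged = np.zeros(B, dtype=bool)
    failed = np.zeros(B, dtype=bool)
    active = np.arange(B)
    Xa = X[:, active]
    n_steps = int(np.ceil(t_max / dt))

    # diverging columns overflow between checks by design; they are flagged
    # and dropped at the next check point, so the FP warnings are suppressed
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(n_steps):
            growth = r * (1.0 - Xa / K) + A @ Xa
            F = Xa * growth
            Xa += dt * F
            np.maximum(Xa, 0.0, out=Xa)
            if (step + 1) % check_every == 0 or step == n_steps - 1:
                Xa[Xa < extinction_eps] = 0.0
                with np.errstate(invalid="ignore"):
                    bad = ~np.isfinite(Xa).all(axis=0) | (Xa.max(axis=0) > blowup)
                Xa[:, bad] = 0.0  # park failed columns; they are flagged below
                # recompute the drift at the clamped state for the convergence test
                F = Xa * (r * (1.0 - Xa / K) + A @ Xa)
                scale = np.maximum(Xa.max(axis=0), 1e-8)
                done = np.abs(F).max(axis=0) < tol * scale
                done &= ~bad
                if bad.any() or done.any():
                    X[:, active] = Xa
                    failed[active[bad]] = True
                    converged[active[done]] = True
                    keep = ~(bad | done)
                    active = active[keep]
                    if active.size == 0:
                        break
                    Xa = np.ascontiguousarray(Xa[:, keep])
    if active.size:
        X[:, active] = Xa
    X[:, failed] = np.nan
    if single:
        return X[:, 0], bool(converged[0]), bool(failed[0])
    return X, converged, failed


# ---------------------------------------------------------------------------
# community sampling
# ---------------------------------------------------------------------------

def pool_size_for_similarity(n_species: int, similarity: float) -> int:
    """Pool size giving an expected pairwise Jaccard overlap ``similarity``.

    Two random ``n``-subsets of a pool of size P share m = n²/P species on
    average, giving an expected Jaccard index m/(2n−m). Solving for P:
    P = n(1+s)/(2s).
    """
    if not 0 < similarity <= 1:
        raise ValueError("similarity must be in (0, 1]")
    return max(n_species, int(round(n_species * (1.0 + similarity) / (2.0 * similarity))))


def sample_community(
    model: GLVModel,
    n_species: int,
    rng=None,
    max_retries: int = 10,
    **sim_kwargs,
) -> CommunitySample:
    """Draw a random species subset of the pool and integrate it to steady state.

    Initial abundances are uniform on (0, K_i) per species. Non-converged or
    failed integrations are retried with fresh initial conditions up to
    ``max_retries`` times.
    """
    rng = np.random.default_rng(rng)
    if not 1 <= n_species <= model.S:
        raise ValueError("n_species must be within the pool size")
    for attempt in range(1, max_retries + 1):
        idx = np.sort(rng.choice(model.S, size=n_species, replace=False))
        r, K = model.r[idx], model.K[idx]
        A = model.A[np.ix_(idx, idx)]
        x0 = rng.uniform(0.0, 1.0, size=n_species) * K
        x, ok, bad = simulate_to_steady_state(r, K, A, x0, **sim_kwargs)
        if ok and not bad:
            return CommunitySample(species_idx=idx, abundance=x, converged=True, n_attempts=attempt)
    raise RuntimeError(f"no converged community found in {max_retries} attempts")


# ---------------------------------------------------------------------------
# keystoneness
# ---------------------------------------------------------------------------

def canberra(x, y) -> float:
    """Canberra distance Σ|x−y|/(x+y) with 0/0 terms defined as 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Canberra distance expects non-negative coordinates")
    denom = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, np.abs(x - y) / denom, 0.0)
    return float(terms.sum())


def true_keystoneness(
    model: GLVModel,
    sample: CommunitySample,
    n_iter: int = 1000,
    rng=None,
    include_removed: bool = False,
    **sim_kwargs,
) -> list:
    """Ground-truth keystoneness by in-turn species removal.

    Each species of the community is removed (its abundance pinned at the
    absorbing zero state) and the remaining community re-integrated from a
    fresh uniform random initial condition; the Canberra distance between
    the original steady state and the post-removal steady state — over the
    surviving species' coordinates by default — is averaged over ``n_iter``
    such iterations. All removals × iterations are integrated as one batch.
    """
    if not sample.converged:
        raise ValueError("reference community did not converge")
    rng = np.random.default_rng(rng)
    idx = sample.species_idx
    S = idx.size
    r, K = model.r[idx], model.K[idx]
    A = model.A[np.ix_(idx, idx)]
    x_ref = sample.abundance

    # batch layout: block i (n_iter columns) has species i removed
    X0 = rng.uniform(0.0, 1.0, size=(S, S * n_iter)) * K[:, None]
    for i in range(S):
        X0[i, i * n_iter : (i + 1) * n_iter] = 0.0
    X, ok, bad = simulate_to_steady_state(r, K, A, X0, **sim_kwargs)

    records = []
    keep_mask = np.ones(S, dtype=bool)
    for i in range(S):
        cols = np.arange(i * n_iter, (i + 1) * n_iter)
        usable = cols[ok[cols] & ~bad[cols]]
        if include_removed:
            ref, sel = x_ref, slice(None)
        else:
            keep_mask[:] = True
            keep_mask[i] = False
            ref, sel = x_ref[keep_mask], keep_mask.copy()
        dists = [canberra(ref, X[sel, c]) for c in usable]
        score = float(np.mean(dists)) if dists else np.nan
        records.append(
            KeystonenessRecord(
                species_id=int(idx[i]),
                keystoneness=score,
                n_iter=len(usable),
                n_failed=n_iter - len(usable),
            )
        )
    return records


def scale_keystoneness(records: list) -> list:
    """Min-max scale keystoneness over the evaluated set into [0, 1]."""
    vals = np.array([r.keystoneness for r in records], dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return records
    lo, hi = float(finite.min()), float(finite.max())
    for rec in records:
        if not np.isfinite(rec.keystoneness):
            continue
        if hi == lo:
            rec.scaled_keystoneness = 0.5
        else:
            rec.scaled_keystoneness = (rec.keystoneness - lo) / (hi - lo)
    return records


# ---------------------------------------------------------------------------
# random study-condition models
# ---------------------------------------------------------------------------

def random_glv_model(
    rng=None,
    n_species: int | None = None,
    connectivity_range=(0.005, 0.7),
    neg_pct_range=(0.0, 100.0),
    r_range=(0.05, 1.0),
    K_range=(1.0, 100.0),
    similarity_range=(0.4, 0.95),
    n_species_range=(10, 100),
    interaction_gamma: float = 0.5,
) -> tuple:
    """Draw one community model from the study's parameter ranges.

    Growth rates are uniform in (0, 1] and carrying capacities in (0, 100]
    (floored at 0.05 and 1 to avoid degenerate timescales), connectivity in
    [0.005, 0.7], negative-edge percentage in [0, 100], sample similarity in
    [0.4, 0.95], community size in [10, 100], and the topology is uniform or
    Klemm-Eguíluz with equal probability. Interaction magnitudes are scaled
    so that the expected interaction pressure on a species is
    ``interaction_gamma`` times the mean self-limitation slope mean(r/K) —
    strong enough to matter, weak enough that most communities stabilize.

    Returns ``(model, n_species)``.
    """
    rng = np.random.default_rng(rng)
    if n_species is None:
        n_species = int(rng.integers(n_species_range[0], n_species_range[1] + 1))
    similarity = rng.uniform(*similarity_range)
    pool = pool_size_for_similarity(n_species, similarity)
    connectivity = rng.uniform(*connectivity_range)
    neg_pct = rng.uniform(*neg_pct_range)
    topology = "uniform" if rng.random() < 0.5 else "klemm_eguiluz"
    r = rng.uniform(*r_range, size=pool)
    K = rng.uniform(*K_range, size=pool)
    # mean |A_ij| is strength/2 over c*(S-1) partners per species
    mean_slope = float(np.mean(r / K))
    strength = 2.0 * interaction_gamma * mean_slope / max(connectivity * (pool - 1), 1e-9)
    A = sample_interaction_matrix(pool, connectivity, neg_pct, topology, rng, strength=strength)
    model = GLVModel(
        r=r,
        K=K,
        A=A,
        topology=topology,
        connectivity=connectivity,
        neg_pct=neg_pct,
        pool_similarity=similarity,
    )
    return model, n_species


def make_hub_model(
    S: int = 15,
    rng=None,
    hub_strength: float = 0.01,
    background_strength: float = 0.002,
    background_connectivity: float = 0.2,
) -> GLVModel:
    """Engineered community with one strongly interacting hub species.

    Species 0 suppresses every other species with interaction strength
    ``hub_strength`` (well above the background), so its removal releases
    the rest of the community — a planted keystone used as ground truth in
    tests. The default strength depresses, but does not exterminate, the
    other species.
    """
    rng = np.random.default_rng(rng)
    r = rng.uniform(0.4, 1.0, size=S)
    K = rng.uniform(20.0, 60.0, size=S)
    A = sample_interaction_matrix(
        S, background_connectivity, 50.0, "uniform", rng, strength=background_strength
    )
    A[1:, 0] = -hub_strength  # hub suppresses everyone
    A[0, 1:] = 0.0  # hub itself is self-regulated only
    return GLVModel(r=r, K=K, A=A, topology="uniform", connectivity=background_connectivity, neg_pct=50.0)
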
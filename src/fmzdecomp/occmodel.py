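"""Two-drug multi-component receptor-occupancy model and its fit.

The model: total occupancy observed for drug j at cluster i is a
mixture of single-site occupancy curves,

    Occ_{j,k} = C_p / (C_p + K_i[j,k])                (per component k)
    Occ_hat_{i,j} = sum_k f_{i,k} * Occ_{j,k}         (drug j's displaceable k)

with cluster-specific fractional contributions f_{i,k} on the unit
simplex (component N is displaced by neither drug) and global, drug- and
component-specific inhibition constants K_i.  Fractions are
reparameterized through cumulative ratios v in [0,1]^{N-1}, a bijection
onto the simplex, so box constraints suffice.

Fitting uses variable projection: an outer bounded least-squares search
over the (at most four) log K_i parameters, with the per-cluster
simplex-constrained linear subproblem solved exactly at every outer
evaluation by enumerating the faces of the simplex (N <= 4, so at most
15 candidate supports per cluster).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # circular at runtime: preprocess depends on synth
    from .preprocess import OccupancyDataset

DRUG_A = "A"
DRUG_B = "B"

SIMPLEX_TOL = 1e-8


# ---------------------------------------------------------------------------
# Model configurations


@dataclass(frozen=True)
class ModelConfig:
    """A model family member: N components and per-drug displaceable sets.

    Component indices are 1-based; component ``n_components`` is the
    non-displaceable one and may not appear in any drug's set.  Drug A's
    displaceable set is at least as large as drug B's (drug A is the
    broader-spectrum compound).
    """

    name: str
    n_components: int
    displaceable: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        n = self.n_components
        if not 2 <= n <= 4:
            raise ValueError(f"n_components must be in [2, 4], got {n}")
        object.__setattr__(
            self, "displaceable", {d: tuple(sorted(ks)) for d, ks in self.displaceable.items()}
        )
        covered: set[int] = set()
        for drug, comps in self.displaceable.items():
            if len(comps) == 0:
                raise ValueError(f"drug {drug} must displace at least one component")
            if len(set(comps)) != len(comps):
                raise ValueError(f"drug {drug} has duplicate component indices")
            if any(not 1 <= k <= n - 1 for k in comps):
                raise ValueError(
                    f"drug {drug} component indices must be in [1, {n - 1}] "
                    "(the last component is non-displaceable)"
                )
            covered.update(comps)
        if DRUG_A in self.displaceable and DRUG_B in self.displaceable:
            if len(self.displaceable[DRUG_A]) < len(self.displaceable[DRUG_B]):
                raise ValueError(
                    "drug A's displaceable-component count must be >= drug B's"
                )
        if covered != set(range(1, n)):
            raise ValueError(
                "every component except the last must be displaced by at least one drug"
            )

    @property
    def drugs(self) -> list[str]:
        return sorted(self.displaceable)

    @property
    def n_ki(self) -> int:
        return sum(len(v) for v in self.displaceable.values())

    def n_par(self, n_clusters: int) -> int:
        """Literal parameter count of the fit: global K_i plus the
        (N-1) free fraction parameters of every cluster."""
        return self.n_ki + n_clusters * (self.n_components - 1)


#: Two components: only the lumped high-affinity occupancy is quantified.
M2A = ModelConfig("M2a", 2, {DRUG_A: (1,), DRUG_B: (1,)})
#: Three components: drug A occupies components 1 and 2, drug B only 1.
M3C = ModelConfig("M3c", 3, {DRUG_A: (1, 2), DRUG_B: (1,)})


def named_configs() -> dict[str, ModelConfig]:
    return {c.name: c for c in (M2A, M3C)}


def get_config(name: str) -> ModelConfig:
    try:
        return named_configs()[name]
    except KeyError:
        raise KeyError(
            f"unknown model configuration '{name}'; known: {sorted(named_configs())}"
        ) from None


def enumerate_configs() -> list[ModelConfig]:
    """All admissible configurations with prefix displaceable sets.

    Admissibility: 2-4 total components including one non-displaceable;
    each drug displaces a prefix {1..n_j} of the component list; drug A
    displaces at least as many components as drug B.
    """
    out = []
    for n in range(2, 5):
        n_a = n - 1  # drug A must cover every displaceable component
        for n_b in range(1, n_a + 1):
            out.append(
                ModelConfig(
                    f"N{n}_A{n_a}_B{n_b}",
                    n,
                    {DRUG_A: tuple(range(1, n_a + 1)), DRUG_B: tuple(range(1, n_b + 1))},
                )
            )
    return out


# ---------------------------------------------------------------------------
# Occupancy predictions and the simplex reparameterization


def predict_component_occupancy(cp: float, ki: float) -> float:
    """Single-site occupancy C_p / (C_p + K_i)."""
    if np.any(np.asarray(ki) <= 0):
        raise ValueError("K_i must be > 0")
    if np.any(np.asarray(cp) < 0):
        raise ValueError("C_p must be >= 0")
    return cp / (cp + ki)


def predict_total_occupancy(
    f: Sequence[float],
    config: ModelConfig,
    drug: str,
    cp: float,
    ki: Mapping[str, Mapping[int, float]],
) -> float:
    """Mixture prediction: sum of f_k * Occ_{j,k} over drug j's components."""
    f = np.asarray(f, dtype=float)
    if len(f) != config.n_components:
        raise ValueError("fraction vector length does not match the configuration")
    if f.min() < -SIMPLEX_TOL or abs(f.sum() - 1.0) > SIMPLEX_TOL:
        raise ValueError("f is not on the unit simplex")
    if drug not in config.displaceable:
        raise ValueError(f"drug '{drug}' is not part of configuration {config.name}")
    total = 0.0
    for k in config.displaceable[drug]:
        total += f[k - 1] * predict_component_occupancy(cp, ki[drug][k])
    return total


def f_to_v(f: Sequence[float]) -> np.ndarray:
    """Cumulative-ratio transform of a simplex vector (length N -> N-1).

    v_k = (sum_{q<=k} f_q) / (sum_{q<=k+1} f_q); a zero denominator
    (all leading fractions zero) yields v_k = 0 by convention — every v
    on that degenerate face maps back to the same f.
    """
    f = np.asarray(f, dtype=float)
    if f.min() < -SIMPLEX_TOL:
        raise ValueError("fractions must be non-negative")
    cs = np.cumsum(f)
    num, den = cs[:-1], cs[1:]
    v = np.zeros(len(f) - 1)
    np.divide(num, den, out=v, where=den > 0)
    return np.clip(v, 0.0, 1.0)


def v_to_f(v: Sequence[float]) -> np.ndarray:
    """Inverse transform: v in [0,1]^{N-1} -> simplex vector of length N.

    f_k = prod_{q=k..N} v_q - prod_{q=k-1..N} v_q with v_0 = 0, v_N = 1.
    """
    v = np.asarray(v, dtype=float)
    if v.size and (v.min() < -SIMPLEX_TOL or v.max() > 1 + SIMPLEX_TOL):
        raise ValueError("v components must lie in [0, 1]")
    ext = np.concatenate([[0.0], np.clip(v, 0.0, 1.0), [1.0]])  # v_0 .. v_N
    # suffix[q] = prod_{r=q..N} ext[r]; f_k = suffix[k] - suffix[k-1]
    suffix = np.cumprod(ext[::-1])[::-1]
    f = suffix[1:] - suffix[:-1]
    # suffix[0] contains the v_0 = 0 factor, so the sum telescopes to 1
    return f


# ---------------------------------------------------------------------------
# Parameter packing: theta = per drug (log K_first, then log-increments)


def _theta_size(config: ModelConfig) -> int:
    return config.n_ki


def pack_ki(config: ModelConfig, ki: Mapping[str, Mapping[int, float]]) -> np.ndarray:
    theta = []
    for drug in config.drugs:
        comps = config.displaceable[drug]
        logk = np.log([ki[drug][k] for k in comps])
        theta.append(logk[0])
        theta.extend(np.diff(logk))
    return np.asarray(theta)


def unpack_ki(config: ModelConfig, theta: np.ndarray) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    pos = 0
    for drug in config.drugs:
        comps = config.displaceable[drug]
        n = len(comps)
        logk = np.cumsum(theta[pos : pos + n])
        out[drug] = {k: float(np.exp(lk)) for k, lk in zip(comps, logk)}
        pos += n
    return out


def _theta_bounds(config: ModelConfig, ki_bounds: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    span = np.log(ki_bounds[1] / ki_bounds[0])
    for drug in config.drugs:
        n = len(config.displaceable[drug])
        lo.append(np.log(ki_bounds[0]))
        hi.append(np.log(ki_bounds[1]))
        # ascending-K_i identifiability: increments are non-negative
        lo.extend([0.0] * (n - 1))
        hi.extend([span] * (n - 1))
    return np.asarray(lo), np.asarray(hi)


def occupancy_matrix(
    config: ModelConfig,
    drugs: np.ndarray,
    exposures: np.ndarray,
    ki: Mapping[str, Mapping[int, float]],
) -> np.ndarray:
    """Per-occasion, per-component occupancy matrix A (n_occ x N).

    A[o, k-1] = Occ_{j(o),k} if occasion o's drug displaces component k,
    else 0; the non-displaceable column is identically 0.
    """
    n_occ = len(drugs)
    a = np.zeros((n_occ, config.n_components))
    for drug in config.drugs:
        rows = np.flatnonzero(drugs == drug)
        for k in config.displaceable[drug]:
            kij = ki[drug][k]
            a[rows, k - 1] = exposures[rows] / (exposures[rows] + kij)
    return a


# ---------------------------------------------------------------------------
# Exact per-cluster simplex-constrained linear least squares


def solve_fractions(a: np.ndarray, y: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ||A f - y||^2 over the unit simplex, exactly, per cluster.

    Enumerates every non-empty support (face of the simplex); on each
    face the equality-constrained least-squares problem is linear and is
    solved for all clusters at once; the best feasible face wins.
    Vertices are always feasible, so a solution always exists.

    Parameters
    ----------
    a
        (n_occ, N) per-component occupancy matrix shared by all clusters.
    y
        (M, n_occ) observed pooled occupancies.

    Returns
    -------
    (M, N) fractions on the simplex, and (M,) residual sums of squares.
    """
    n_occ, n_comp = a.shape
    y = np.atleast_2d(y)
    m = y.shape[0]
    best_ssr = np.full(m, np.inf)
    best_f = np.zeros((m, n_comp))
    yt = y.T  # (n_occ, M)

    for size in range(1, n_comp + 1):
        for support in itertools.combinations(range(n_comp), size):
            a_s = a[:, support]  # (n_occ, s)
            if size == 1:
                pred = a_s[:, 0:1]  # (n_occ, 1)
                ssr = ((pred - yt) ** 2).sum(0)
                f_s = np.ones((m, 1))
            else:
                c = a_s[:, 0:1]  # (n_occ, 1)
                mdiff = a_s[:, 1:] - c  # (n_occ, s-1)
                t = np.linalg.pinv(mdiff) @ (yt - c)  # (s-1, M)
                resid = c + mdiff @ t - yt
                ssr = (resid**2).sum(0)
                f_rest = t.T  # (M, s-1)
                f_first = 1.0 - f_rest.sum(1, keepdims=True)
                f_s = np.hstack([f_first, f_rest])
            feasible = (f_s >= -tol).all(1)
            better = feasible & (ssr < best_ssr - 1e-15)
            if better.any():
                best_ssr[better] = ssr[better]
                best_f[better] = 0.0
                best_f[np.ix_(better, list(support))] = f_s[better]

    best_f = np.clip(best_f, 0.0, None)
    best_f /= best_f.sum(1, keepdims=True)
    return best_f, best_ssr


# ---------------------------------------------------------------------------
# Full fit


@dataclass
class FitOptions:
    max_outer_iter: int = 500
    ftol: float = 1e-10
    xtol: float = 1e-12
    ki_bounds: tuple[float, float] = (1e-3, 1e5)
    n_starts: int = 1
    seed: int = 0
    theta0: np.ndarray | None = None  # explicit start, overrides init heuristic


@dataclass
class FitResult:
    """Fitted global affinities plus per-cluster fractions."""

    config: ModelConfig
    ki: dict[str, dict[int, float]]
    fractions: np.ndarray  # (M, N) simplex rows
    v: np.ndarray  # (M, N-1)
    ssr: float
    n_obs: int
    n_par: int
    converged: bool
    n_iter: int
    ki_ci: dict[str, dict[int, tuple[float, float]]]
    theta: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    ssr_history: list[float] = field(repr=False, default_factory=list)

    @property
    def mse(self) -> float:
        return self.ssr / self.n_obs


def init_parameters(
    config: ModelConfig, dataset: "OccupancyDataset"
) -> tuple[np.ndarray, np.ndarray]:
    """Initial outer parameters and per-cluster v.

    K_i starting values are staggered so lower-index components receive
    higher affinity (lower K_i), spaced geometrically across the inner
    quantiles of each drug's exposure range; v starts at the transform
    of uniform fractions f = 1/N (inert under variable projection but
    exposed for direct optimizers).
    """
    design = dataset.design
    theta = []
    for drug in config.drugs:
        cp = design.exposures[design.drug_labels == drug]
        comps = config.displaceable[drug]
        n = len(comps)
        lo, hi = np.quantile(np.log(cp), [0.2, 0.8])
        if n == 1:
            logk = np.array([0.5 * (lo + hi)])
        else:
            logk = np.linspace(lo, hi, n)
        theta.append(logk[0])
        theta.extend(np.diff(logk))
    f0 = np.full(config.n_components, 1.0 / config.n_components)
    v0 = np.tile(f_to_v(f0), (dataset.n_clusters, 1))
    return np.asarray(theta), v0


def _check_design(dataset: "OccupancyDataset", config: ModelConfig) -> None:
    design = dataset.design
    for drug in config.drugs:
        cp = design.exposures[design.drug_labels == drug]
        if len(cp) < 2 or len(np.unique(cp)) < 2:
            raise ValueError(
                f"degenerate design: drug {drug} needs >= 2 occasions with distinct exposures"
            )


def fit_model(
    config: ModelConfig, dataset: "OccupancyDataset", options: FitOptions | None = None
) -> FitResult:
    """Fit the occupancy model by nested non-linear least squares.

    The outer problem searches over log K_i (ascending within each drug
    by construction); for every outer evaluation the per-cluster
    fractions are profiled out exactly by `solve_fractions`.
    """
    opts = options or FitOptions()
    _check_design(dataset, config)
    y = dataset.occupancy
    drugs = dataset.design.drug_labels
    cp = dataset.design.exposures
    history: list[float] = []

    def residuals(theta: np.ndarray) -> np.ndarray:
        ki = unpack_ki(config, theta)
        a = occupancy_matrix(config, drugs, cp, ki)
        f, ssr = solve_fractions(a, y)
        history.append(float(ssr.sum()))
        return (f @ a.T - y).ravel()

    theta0, _ = init_parameters(config, dataset)
    if opts.theta0 is not None:
        theta0 = np.asarray(opts.theta0, dtype=float)
    lo, hi = _theta_bounds(config, opts.ki_bounds)
    starts = [np.clip(theta0, lo, hi)]
    if opts.n_starts > 1:
        rng = np.random.default_rng(opts.seed)
        for _ in range(opts.n_starts - 1):
            starts.append(np.clip(theta0 + rng.normal(0.0, 0.7, theta0.shape), lo, hi))

    best = None
    for x0 in starts:
        res = least_squares(
            residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=opts.ftol,
            xtol=opts.xtol,
            gtol=1e-12,
            max_nfev=opts.max_outer_iter * (len(x0) + 1),
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None

    theta = best.x
    ki = unpack_ki(config, theta)
    a = occupancy_matrix(config, drugs, cp, ki)
    fractions, ssr_clusters = solve_fractions(a, y)
    ssr = float(ssr_clusters.sum())
    v = np.vstack([f_to_v(f) for f in fractions])
    n_obs = dataset.n_obs
    n_par = config.n_par(dataset.n_clusters)
    ci = _ki_confidence_intervals(config, theta, best.jac, ssr, n_obs, n_par)

    return FitResult(
        config=config,
        ki=ki,
        fractions=fractions,
        v=v,
        ssr=ssr,
        n_obs=n_obs,
        n_par=n_par,
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
        ki_ci=ci,
        theta=theta,
        ssr_history=history,
    )


def _ki_confidence_intervals(
    config: ModelConfig,
    theta: np.ndarray,
    jac: np.ndarray,
    ssr: float,
    n_obs: int,
    n_par: int,
) -> dict[str, dict[int, tuple[float, float]]]:
    """Approximate 95% CIs for each K_i from the outer-problem Jacobian.

    The covariance of theta is s^2 (J'J)^-1 with s^2 = SSR/(n - p); log
    K_i values are cumulative sums of theta within each drug, so their
    variances follow by the delta method.  Degenerate cases yield NaN.
    """
    out: dict[str, dict[int, tuple[float, float]]] = {}
    dof = n_obs - n_par
    if dof <= 0 or ssr <= 0:
        cov = None
    else:
        try:
            cov = np.linalg.pinv(jac.T @ jac) * (ssr / dof)
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = None
    pos = 0
    for drug in config.drugs:
        comps = config.displaceable[drug]
        n = len(comps)
        logk = np.cumsum(theta[pos : pos + n])
        out[drug] = {}
        for i, k in enumerate(comps):
            if cov is None:
                out[drug][k] = (float("nan"), float("nan"))
            else:
                sel = np.zeros(len(theta))
                sel[pos : pos + i + 1] = 1.0
                sd = float(np.sqrt(max(sel @ cov @ sel, 0.0)))
                out[drug][k] = (float(np.exp(logk[i] - 1.96 * sd)), float(np.exp(logk[i] + 1.96 * sd)))
        pos += n
    return out
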
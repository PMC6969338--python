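"""Maximum-likelihood ACE variance decomposition for twin pairs.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C) and unique environmental (E)
components.  Each twin pair is modeled as a draw from a bivariate normal
with common mean mu and covariance

    [[a^2 + c^2 + e^2,  phi a^2 + c^2],
     [phi a^2 + c^2,    a^2 + c^2 + e^2]]

where the genetic cross-twin correlation phi is 1 for monozygotic (MZ)
and 0.5 for dizygotic (DZ) pairs, and the shared-environment correlation
is 1 for both.  A single grand mean and a common total variance are
assumed across zygosity groups and birth order.

Parameterization is by unconstrained path coefficients (a, c, e); squares
are variances, so non-negativity needs no constrained optimizer, and the
sign ambiguity is resolved by reporting squared, standardized shares
a2 + c2 + e2 = 1.  The likelihood depends on the data only through
per-group sufficient statistics, so evaluations are O(1) after one pass
over the pairs; the mean and total variance have closed-form maximizers
given the two implied cross-twin correlations, which makes profile
likelihoods cheap.

Confidence intervals are profile-likelihood intervals: the bounds are
where twice the profile log-likelihood drop crosses the chi-square(1)
quantile, re-optimizing all nuisance parameters at each fixed value of
the target share, clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError, InsufficientDataError, ValidationError

PHI_MZ = 1.0
PHI_DZ = 0.5
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class TwinPairTable:
    """Complete twin pairs for one phenotype, split by zygosity.

    ``mz`` and ``dz`` are (n, 2) arrays; row order is (twin1, twin2) by
    birth order.
    """

    mz: np.ndarray
    dz: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.atleast_2d(np.asarray(self.mz, dtype=float))
        self.dz = np.atleast_2d(np.asarray(self.dz, dtype=float))
        for name, arr in (("mz", self.mz), ("dz", self.dz)):
            if arr.size and arr.shape[1] != 2:
                raise ValidationError(f"{name} must be an (n, 2) array")
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} contains non-finite values")

    @property
    def n_mz(self) -> int:
        return 0 if self.mz.size == 0 else self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return 0 if self.dz.size == 0 else self.dz.shape[0]

    def values(self) -> np.ndarray:
        parts = [a.ravel() for a in (self.mz, self.dz) if a.size]
        return np.concatenate(parts) if parts else np.empty(0)


@dataclass
class ACEEstimate:
    """Standardized variance shares with fit diagnostics."""

    a2: float
    c2: float
    e2: float
    raw_var: float
    mu: float
    loglik: float
    n_mz: int
    n_dz: int
    converged: bool
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def implied_r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def implied_r_dz(self) -> float:
        return PHI_DZ * self.a2 + self.c2


# -- likelihood -------------------------------------------------------------


def _suffstats(arr: np.ndarray) -> tuple[int, float, float, float]:
    """(n, sum(x+y), sum(x^2+y^2), sum(x*y)) for an (n, 2) pair array."""
    if arr.size == 0:
        return 0, 0.0, 0.0, 0.0
    x, y = arr[:, 0], arr[:, 1]
    return arr.shape[0], float((x + y).sum()), float((x * x + y * y).sum()), float((x * y).sum())


def _group_loglik(
    ss: tuple[int, float, float, float], mu: float, var: float, r: float
) -> float:
    """Bivariate-normal log-likelihood of one zygosity group.

    Mean (mu, mu), covariance var*[[1, r], [r, 1]]; requires var > 0 and
    |r| < 1 (positive definiteness).
    """
    n, s1, s2, s12 = ss
    if n == 0:
        return 0.0
    if var <= 0 or not -1.0 < r < 1.0:
        return -np.inf
    quad = (
        s2 - 2.0 * mu * s1 + 2.0 * n * mu * mu
        - 2.0 * r * (s12 - mu * s1 + n * mu * mu)
    ) / (1.0 - r * r)
    return -n * _LOG_2PI - 0.5 * n * np.log(var * var * (1.0 - r * r)) - quad / (2.0 * var)


def ace_neg_loglik(
    params: tuple[float, float, float, float], data: TwinPairTable
) -> float:
    """Negative log-likelihood at path coefficients (a, c, e) and mean mu.

    Raises a domain error when the implied pair covariance is not
    positive definite (e.g. e = 0).
    """
    a, c, e, mu = params
    if data.n_mz + data.n_dz == 0:
        raise InsufficientDataError("empty pair table")
    var = a * a + c * c + e * e
    cov_mz = PHI_MZ * a * a + c * c
    cov_dz = PHI_DZ * a * a + c * c
    if var <= 0 or abs(cov_mz) >= var or abs(cov_dz) >= var:
        raise DegenerateDataError("implied covariance is not positive definite")
    ll = _group_loglik(_suffstats(data.mz), mu, var, cov_mz / var)
    ll += _group_loglik(_suffstats(data.dz), mu, var, cov_dz / var)
    return -ll


def _profiled_loglik(
    ss_mz: tuple[int, float, float, float],
    ss_dz: tuple[int, float, float, float],
    r_mz: float,
    r_dz: float,
) -> tuple[float, float, float]:
    """(max loglik, mu_hat, var_hat) given the two implied correlations.

    Both the grand mean and the total variance have closed-form
    maximizers once the correlations are fixed.
    """
    n_mz, s1_mz = ss_mz[0], ss_mz[1]
    n_dz, s1_dz = ss_dz[0], ss_dz[1]
    n_tot = n_mz + n_dz
    if not (-1.0 < r_mz < 1.0 and -1.0 < r_dz < 1.0):
        return -np.inf, np.nan, np.nan
    w_mz, w_dz = 1.0 / (1.0 + r_mz), 1.0 / (1.0 + r_dz)
    mu = (w_mz * s1_mz + w_dz * s1_dz) / (2.0 * (w_mz * n_mz + w_dz * n_dz))

    def quad(ss, r):
        n, s1, s2, s12 = ss
        if n == 0:
            return 0.0
        return (
            s2 - 2.0 * mu * s1 + 2.0 * n * mu * mu
            - 2.0 * r * (s12 - mu * s1 + n * mu * mu)
        ) / (1.0 - r * r)

    q_tot = quad(ss_mz, r_mz) + quad(ss_dz, r_dz)
    if q_tot <= 0:
        return -np.inf, mu, np.nan
    var = q_tot / (2.0 * n_tot)
    ll = (
        -n_tot * _LOG_2PI
        - 0.5 * n_mz * np.log(var * var * (1.0 - r_mz * r_mz))
        - 0.5 * n_dz * np.log(var * var * (1.0 - r_dz * r_dz))
        - n_tot
    )
    return float(ll), float(mu), float(var)


def _shares_loglik(ss_mz, ss_dz, sa: float, sc: float) -> float:
    """Profiled loglik as a function of the (a2, c2) point on the simplex."""
    se = 1.0 - sa - sc
    if sa < 0 or sc < 0 or se <= 0:
        return -np.inf
    return _profiled_loglik(ss_mz, ss_dz, sa + sc, PHI_DZ * sa + sc)[0]


# -- estimation -------------------------------------------------------------


def falconer_estimates(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Closed-form (A, C, E) shares from the two within-twin correlations.

    A = 2(rMZ - rDZ), C = 2 rDZ - rMZ, E = 1 - rMZ, each clipped to
    [0, 1] and renormalized to sum to one (for use as an optimizer
    start and as a cross-check).
    """
    if abs(r_mz) > 1 or abs(r_dz) > 1:
        raise ValidationError("correlations must lie in [-1, 1]")
    raw = np.array([2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz, 1.0 - r_mz])
    clipped = np.clip(raw, 0.0, 1.0)
    total = clipped.sum()
    if total == 0:
        return (1.0 / 3, 1.0 / 3, 1.0 / 3)
    a, c, e = clipped / total
    return float(a), float(c), float(e)


_CORNER_STARTS = (
    (0.8, 0.1, 0.1),
    (0.1, 0.8, 0.1),
    (0.05, 0.05, 0.9),
    (1.0 / 3, 1.0 / 3, 1.0 / 3),
)


def _pair_correlation(arr: np.ndarray) -> float:
    if arr.shape[0] < 3:
        return 0.0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
    return float(r) if np.isfinite(r) else 0.0


def fit_ace(data: TwinPairTable, ci: bool = False, level: float = 0.95) -> ACEEstimate:
    """Fit the ACE model by deterministic multi-start maximum likelihood.

    Starts are the Falconer point plus four fixed corner points of the
    share simplex.  Each start is optimized over the path coefficients
    (a, c, e, mu) by quasi-Newton descent; the winner is polished in
    standardized-share space with the mean and total variance profiled
    out in closed form.  Deterministic given the data.
    """
    if data.n_mz < 2 or data.n_dz < 2:
        raise InsufficientDataError("need at least 2 complete pairs per zygosity")
    values = data.values()
    total_var = float(np.var(values, ddof=1))
    if total_var <= 0:
        raise DegenerateDataError("zero phenotypic variance")
    ss_mz, ss_dz = _suffstats(data.mz), _suffstats(data.dz)
    mu0 = float(values.mean())

    starts = [falconer_estimates(_pair_correlation(data.mz), _pair_correlation(data.dz))]
    starts.extend(_CORNER_STARTS)

    def nll_paths(x):
        a, c, e, mu = x
        var = a * a + c * c + e * e
        if var <= 0 or e == 0:
            return np.inf
        r_mz = (a * a + c * c) / var
        r_dz = (PHI_DZ * a * a + c * c) / var
        ll = _group_loglik(ss_mz, mu, var, r_mz) + _group_loglik(ss_dz, mu, var, r_dz)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    any_converged = False
    for sa, sc, se in starts:
        se = max(se, 1e-6)
        x0 = np.array(
            [np.sqrt(sa * total_var), np.sqrt(sc * total_var), np.sqrt(se * total_var), mu0]
        )
        res = optimize.minimize(nll_paths, x0, method="L-BFGS-B",
                                options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)

    a, c, e, _ = best.x
    var = a * a + c * c + e * e
    sa0, sc0 = (a * a) / var, (c * c) / var

    # polish on the share simplex with (mu, var) profiled in closed form
    def neg_profile(x):
        return -_shares_loglik(ss_mz, ss_dz, x[0], x[1])

    polish = optimize.minimize(
        neg_profile, np.array([sa0, sc0]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    sa, sc = np.clip(polish.x, 0.0, 1.0)
    if sa + sc >= 1.0:  # renormalize onto the open simplex
        scale = (1.0 - 1e-9) / (sa + sc)
        sa, sc = sa * scale, sc * scale
    ll, mu_hat, var_hat = _profiled_loglik(ss_mz, ss_dz, sa + sc, PHI_DZ * sa + sc)
    converged = bool(any_converged or polish.success) and np.isfinite(ll)

    est = ACEEstimate(
        a2=float(sa),
        c2=float(sc),
        e2=float(1.0 - sa - sc),
        raw_var=var_hat,
        mu=mu_hat,
        loglik=float(ll),
        n_mz=data.n_mz,
        n_dz=data.n_dz,
        converged=converged,
    )
    if ci:
        for comp in ("a2", "c2", "e2"):
            est.ci[comp] = profile_ci(est, data, comp, level=level)
    return est


# -- profile-likelihood confidence intervals --------------------------------


def _profile_at(ss_mz, ss_dz, component: str, q: float) -> float:
    """Max loglik with one standardized share fixed at q, others free.

    The remaining share mass 1-q is split between the other two
    components by a 1-D bounded optimization; mean and variance are
    profiled in closed form.
    """
    if not 0.0 <= q <= 1.0:
        return -np.inf

    def shares(t: float) -> tuple[float, float]:
        rest = 1.0 - q
        if component == "a2":
            return q, t * rest
        if component == "c2":
            return t * rest, q
        return t * rest, (1.0 - t) * rest  # e2 fixed: split between a2, c2

    if component == "e2":
        def obj(t):
            sa, sc = shares(t)
            r_mz, r_dz = sa + sc, PHI_DZ * sa + sc
            return -_profiled_loglik(ss_mz, ss_dz, r_mz, r_dz)[0]
    else:
        def obj(t):
            sa, sc = shares(t)
            se = 1.0 - sa - sc
            if se <= 0:
                return np.inf
            return -_profiled_loglik(ss_mz, ss_dz, sa + sc, PHI_DZ * sa + sc)[0]

    res = optimize.minimize_scalar(obj, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                                   options={"xatol": 1e-8})
    # guard against a local dip: check the endpoints too
    candidates = [res.fun, obj(0.0), obj(1.0 - 1e-9)]
    return float(-min(candidates))


def profile_ci(
    fit: ACEEstimate,
    data: TwinPairTable,
    component: str,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood CI for one standardized share, clipped to [0, 1].

    Endpoints are where 2*(max loglik - profile loglik) crosses the
    chi-square(1) quantile (3.841 at the 95% level).  When the boundary
    lies inside the interval the bound is reported as exactly 0 (or 1).
    """
    if component not in ("a2", "c2", "e2"):
        raise ValidationError(f"unknown component: {component!r}")
    if not fit.converged:
        raise ValidationError("cannot profile an unconverged fit")
    ss_mz, ss_dz = _suffstats(data.mz), _suffstats(data.dz)
    drop = stats.chi2.ppf(level, df=1) / 2.0
    point = getattr(fit, component)

    def g(q: float) -> float:
        lp = _profile_at(ss_mz, ss_dz, component, q)
        if not np.isfinite(lp):
            return 1e12
        return (fit.loglik - lp) - drop

    try:
        eps = 1e-9
        if g(eps) <= 0:
            lo = 0.0
        else:
            lo = float(optimize.brentq(g, eps, max(point, eps), xtol=1e-6))
        if g(1.0 - eps) <= 0:
            hi = 1.0
        else:
            hi = float(optimize.brentq(g, min(point, 1.0 - eps), 1.0 - eps, xtol=1e-6))
    except ValueError:
        warnings.warn(
            f"profile CI for {component} failed to bracket; returning [0, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
        return (0.0, 1.0)
    return (min(lo, point), max(hi, point))


def bootstrap_ci(
    data: TwinPairTable,
    component: str,
    level: float = 0.95,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric pair-resampling percentile CI (sensitivity check)."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        mz = data.mz[rng.integers(0, data.n_mz, size=data.n_mz)]
        dz = data.dz[rng.integers(0, data.n_dz, size=data.n_dz)]
        try:
            est = fit_ace(TwinPairTable(mz=mz, dz=dz))
        except (DegenerateDataError, InsufficientDataError):
            continue
        vals.append(getattr(est, component))
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(vals, alpha)),
        float(np.quantile(vals, 1.0 - alpha)),
    )
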
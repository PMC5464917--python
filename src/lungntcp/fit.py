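"""Maximum-likelihood estimation of LKB parameters from (DVH, outcome) pairs.

The objective is the Bernoulli log-likelihood of the binary injury outcomes
under per-patient NTCPs,

    LL(n, m, TD50) = sum_i [ y_i ln p_i + (1 - y_i) ln(1 - p_i) ],
    p_i = Phi((EUD_i(n) - TD50) / (m TD50)),

clipped to a small probability floor so extreme trial parameters keep the
objective finite. Optimization runs in log-parameter coordinates over a box,
using safeguarded Newton iterations (central-difference gradient/Hessian,
step-halving, steepest-ascent fallback when the Hessian is not negative
definite) from a deterministic multi-start lattice plus the classical
whole-lung literature triple. The likelihood surface has a notoriously flat
ridge in ``n``; the multi-start plus explicit tie-breaking (smaller TD50,
then smaller m) keeps refits bit-reproducible.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .cohort import Cohort
from .dvh import _as_differential
from .errors import DegenerateDataError, ParameterError
from .lkb import LKBParameters

_HISTORICAL_START = LKBParameters(n=0.87, m=0.18, td50_1_gy=24.5)


@dataclass(frozen=True)
class FitConfig:
    """Box bounds, start lattice and stopping rules for :func:`fit_mle`."""

    n_bounds: tuple[float, float] = (0.01, 5.0)
    m_bounds: tuple[float, float] = (0.01, 5.0)
    td50_bounds: tuple[float, float] = (1.0, 100.0)
    lattice: int = 3  # interior lattice points per free dimension (log space)
    extra_starts: tuple[LKBParameters, ...] = (_HISTORICAL_START,)
    grad_tol: float = 1e-6
    rel_tol: float = 1e-10
    tie_tol: float = 1e-8
    max_iter: int = 200
    fd_step: float = 1e-4  # central-difference step in log coordinates
    probability_floor: float = 1e-12
    fixed_n: float | None = None  # freeze the volume exponent at this value

    def __post_init__(self) -> None:
        for lo, hi in (self.n_bounds, self.m_bounds, self.td50_bounds):
            if not (0 < lo < hi):
                raise ParameterError("bounds must satisfy 0 < lo < hi")
        if self.lattice < 1:
            raise ParameterError("lattice must have at least one point per dimension")
        if self.fixed_n is not None and self.fixed_n <= 0:
            raise ParameterError("fixed_n must be positive")

    def to_json(self) -> str:
        d = {
            "n_bounds": list(self.n_bounds),
            "m_bounds": list(self.m_bounds),
            "td50_bounds": list(self.td50_bounds),
            "lattice": self.lattice,
            "extra_starts": [
                {"n": p.n, "m": p.m, "td50_1_gy": p.td50_1_gy} for p in self.extra_starts
            ],
            "grad_tol": self.grad_tol,
            "rel_tol": self.rel_tol,
            "tie_tol": self.tie_tol,
            "max_iter": self.max_iter,
            "fd_step": self.fd_step,
            "probability_floor": self.probability_floor,
            "fixed_n": self.fixed_n,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "FitConfig":
        d = json.loads(text)
        d["n_bounds"] = tuple(d["n_bounds"])
        d["m_bounds"] = tuple(d["m_bounds"])
        d["td50_bounds"] = tuple(d["td50_bounds"])
        d["extra_starts"] = tuple(LKBParameters(**p) for p in d["extra_starts"])
        return cls(**d)


@dataclass
class FitResult:
    """A fitted LKB triple with likelihood value and optimisation provenance."""

    params: LKBParameters
    log_likelihood: float
    converged: bool
    iterations: int
    start_points: list[LKBParameters]
    best_start: LKBParameters
    standard_errors: tuple[float, float, float] | None
    probability_floor: float
    information_condition: float | None
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "params": {"n": self.params.n, "m": self.params.m, "td50_1_gy": self.params.td50_1_gy},
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "iterations": self.iterations,
            "start_points": [
                {"n": p.n, "m": p.m, "td50_1_gy": p.td50_1_gy} for p in self.start_points
            ],
            "best_start": {
                "n": self.best_start.n,
                "m": self.best_start.m,
                "td50_1_gy": self.best_start.td50_1_gy,
            },
            "standard_errors": list(self.standard_errors) if self.standard_errors else None,
            "probability_floor": self.probability_floor,
            "information_condition": self.information_condition,
            "flags": self.flags,
        }
        return json.dumps(d, indent=2)


class LikelihoodData:
    """Padded per-patient differential DVH arrays for fast vectorised EUDs.

    Caches EUD vectors by the exact float value of ``n`` — finite-difference
    sweeps over (m, TD50) re-use the same n repeatedly.
    """

    def __init__(self, cohort: Cohort):
        cohort.require_nonempty()
        logd_rows, logv_rows = [], []
        for r in cohort:
            d = _as_differential(r.dvh)
            mask = (d.volumes > 0) & (d.doses_gy > 0)
            logd_rows.append(np.log(d.doses_gy[mask]))
            logv_rows.append(np.log(d.volumes[mask]))
        width = max((row.size for row in logd_rows), default=0)
        width = max(width, 1)
        P = len(logd_rows)
        self.logd = np.full((P, width), -np.inf)
        self.logv = np.full((P, width), -np.inf)
        for i, (ld, lv) in enumerate(zip(logd_rows, logv_rows)):
            self.logd[i, : ld.size] = ld
            self.logv[i, : lv.size] = lv
        self.empty = np.array([row.size == 0 for row in logd_rows])
        self.y = cohort.outcomes()
        self._eud_cache: dict[float, np.ndarray] = {}

    def euds(self, n: float) -> np.ndarray:
        cached = self._eud_cache.get(n)
        if cached is not None:
            return cached
        a = self.logv + self.logd / n
        mx = np.max(a, axis=1)
        safe = np.isfinite(mx)
        lse = np.full(mx.shape, -np.inf)
        if safe.any():
            rows = a[safe] - mx[safe, None]
            lse[safe] = mx[safe] + np.log(np.exp(rows).sum(axis=1))
        out = np.where(safe, np.exp(n * lse), 0.0)
        if len(self._eud_cache) > 128:
            self._eud_cache.clear()
        self._eud_cache[n] = out
        return out

    def log_likelihood(self, n: float, m: float, td50: float, floor: float) -> float:
        e = self.euds(n)
        p = ndtr((e - td50) / (m * td50))
        p = np.clip(p, floor, 1.0 - floor)
        return float(self.y @ np.log(p) + (1.0 - self.y) @ np.log1p(-p))


def log_likelihood(params: LKBParameters, cohort: Cohort) -> float:
    """Bernoulli log-likelihood of the cohort's outcomes under ``params``."""
    data = LikelihoodData(cohort)
    return data.log_likelihood(params.n, params.m, params.td50_1_gy, 1e-12)


def _grad_hess(f, z: np.ndarray, h: float):
    """Central-difference gradient and Hessian of scalar ``f`` at ``z``."""
    k = z.size
    f0 = f(z)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        fp[i] = f(z + e)
        fm[i] = f(z - e)
    g = (fp - fm) / (2 * h)
    H = np.empty((k, k))
    for i in range(k):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(z + ei + ej) - f(z + ei - ej) - f(z - ei + ej) + f(z - ei - ej)
            ) / (4 * h**2)
    return f0, g, H


def _ascend(f, z0: np.ndarray, lo: np.ndarray, hi: np.ndarray, cfg: FitConfig):
    """Safeguarded Newton ascent of ``f`` inside the box [lo, hi] (log coords)."""
    z = np.clip(z0, lo, hi)
    ll = f(z)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        _, g, H = _grad_hess(f, z, cfg.fd_step)
        if np.max(np.abs(g)) < cfg.grad_tol:
            converged = True
            break
        try:
            # ascent requires -H positive definite; Cholesky doubles as the test
            np.linalg.cholesky(-H)
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = g / max(1.0, np.max(np.abs(g)))  # steepest-ascent fallback
        norm = np.max(np.abs(step))
        if norm > 2.0:  # cap jumps in log space
            step *= 2.0 / norm
        s = 1.0
        accepted = False
        for _ in range(40):
            zn = np.clip(z + s * step, lo, hi)
            lln = f(zn)
            if lln > ll:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True  # no ascent direction improves: at a (boxed) optimum
            break
        improved = lln - ll
        z, ll = zn, lln
        if improved <= cfg.rel_tol * (1.0 + abs(ll)):
            converged = True
            break
    return z, ll, it, converged


def _start_lattice(cfg: FitConfig) -> list[tuple[float, ...]]:
    """Deterministic interior lattice in log space plus the extra starts."""
    free_bounds = ([cfg.n_bounds] if cfg.fixed_n is None else []) + [
        cfg.m_bounds,
        cfg.td50_bounds,
    ]
    axes = []
    for lo, hi in free_bounds:
        llo, lhi = np.log(lo), np.log(hi)
        fracs = (np.arange(1, cfg.lattice + 1)) / (cfg.lattice + 1)
        axes.append(llo + fracs * (lhi - llo))
    lattice = [tuple(pt) for pt in itertools.product(*axes)]
    for p in cfg.extra_starts:
        if cfg.fixed_n is None:
            pt = (np.log(p.n), np.log(p.m), np.log(p.td50_1_gy))
        else:
            pt = (np.log(p.m), np.log(p.td50_1_gy))
        lattice.append(pt)
    return lattice


def _observed_information(data, params: LKBParameters, floor: float, fixed_n: bool):
    """Observed information (negative Hessian of LL in natural parameters)."""
    theta = np.array(
        [params.m, params.td50_1_gy] if fixed_n else [params.n, params.m, params.td50_1_gy]
    )

    def f(th):
        if fixed_n:
            return data.log_likelihood(params.n, th[0], th[1], floor)
        return data.log_likelihood(th[0], th[1], th[2], floor)

    k = theta.size
    H = np.empty((k, k))
    hs = 1e-4 * np.maximum(np.abs(theta), 1e-3)
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = hs[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / hs[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = hs[i]
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return -H


def fit_mle(cohort: Cohort, config: FitConfig | None = None) -> FitResult:
    """Fit the LKB triple to a cohort by multi-start safeguarded Newton MLE.

    Requires at least one event and one non-event. Ties between starts
    (log-likelihood difference below ``tie_tol``) break toward smaller TD50,
    then smaller m, so refits are bit-reproducible. Standard errors come
    from the observed-information inverse and are asymptotic — unreliable
    at the event counts typical of a single-institution cohort.
    """
    cfg = config or FitConfig()
    data = LikelihoodData(cohort)
    n_events = int(data.y.sum())
    if n_events == 0 or n_events == data.y.size:
        raise DegenerateDataError(
            "MLE needs both events and non-events in the cohort"
        )
    floor = cfg.probability_floor
    fixed = cfg.fixed_n is not None

    if fixed:
        lo = np.log([cfg.m_bounds[0], cfg.td50_bounds[0]])
        hi = np.log([cfg.m_bounds[1], cfg.td50_bounds[1]])

        def objective(z):
            return data.log_likelihood(cfg.fixed_n, np.exp(z[0]), np.exp(z[1]), floor)

    else:
        lo = np.log([cfg.n_bounds[0], cfg.m_bounds[0], cfg.td50_bounds[0]])
        hi = np.log([cfg.n_bounds[1], cfg.m_bounds[1], cfg.td50_bounds[1]])

        def objective(z):
            return data.log_likelihood(np.exp(z[0]), np.exp(z[1]), np.exp(z[2]), floor)

    starts = _start_lattice(cfg)
    start_params: list[LKBParameters] = []
    best = None  # (ll, td50, m, z, iters, converged, start_param)
    total_iters = 0
    any_converged = False
    for z0 in starts:
        z0 = np.asarray(z0, dtype=float)
        if fixed:
            sp = LKBParameters(cfg.fixed_n, float(np.exp(z0[0])), float(np.exp(z0[1])))
        else:
            sp = LKBParameters(*np.exp(z0))
        start_params.append(sp)
        z, ll, iters, conv = _ascend(objective, z0, lo, hi, cfg)
        total_iters += iters
        any_converged = any_converged or conv
        if fixed:
            cand = (ll, float(np.exp(z[1])), float(np.exp(z[0])), z, conv, sp)
        else:
            cand = (ll, float(np.exp(z[2])), float(np.exp(z[1])), z, conv, sp)
        if best is None:
            best = cand
        else:
            d = cand[0] - best[0]
            if d > cfg.tie_tol:
                best = cand
            elif abs(d) <= cfg.tie_tol:
                # tie: smaller TD50, then smaller m
                if (cand[1], cand[2]) < (best[1], best[2]):
                    best = cand

    ll, td50, m, z, conv, best_start = best
    if fixed:
        params = LKBParameters(cfg.fixed_n, m, td50)
    else:
        params = LKBParameters(float(np.exp(z[0])), m, td50)

    flags: list[str] = []
    ses = None
    info_cond = None
    try:
        info = _observed_information(data, params, floor, fixed)
        info_cond = float(np.linalg.cond(info))
        if info_cond > 1e8 or not np.isfinite(info_cond):
            flags.append("information_near_singular")
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.all(diag > 0):
            se = np.sqrt(diag)
            if fixed:
                ses = (float("nan"), float(se[0]), float(se[1]))
            else:
                ses = (float(se[0]), float(se[1]), float(se[2]))
            flags.append("standard_errors_asymptotic")
        else:
            flags.append("information_not_positive_definite")
    except np.linalg.LinAlgError:
        flags.append("information_singular")

    return FitResult(
        params=params,
        log_likelihood=ll,
        converged=conv,
        iterations=total_iters,
        start_points=start_params,
        best_start=best_start,
        standard_errors=ses,
        probability_floor=floor,
        information_condition=info_cond,
        flags=flags,
    )
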
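"""Flux model construction, RSS fitting, chi-square testing, grid-search CIs.

The flux model constrains the steady-state flux space with measured
exchange rates (glucose uptake, acetate/succinate secretion) and biomass
effluxes derived from precursor-demand coefficients times the growth rate;
the remaining freedom is parameterized by a null-space basis plus one
exchange flux per reversible reaction.  Fitting minimizes the (by default
SD-weighted) residual sum of squares between measured and simulated
fragment MIDs from multiple random feasible starts; goodness of fit is a
chi-square test of the minimal RSS; per-flux confidence intervals come from
a grid-search over the flux of interest, re-optimizing all other free
fluxes at each grid value and thresholding the RSS increase at the
chi-square(1) quantile (3.84 at 95%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares, linprog
from scipy.stats import chi2

from .atom_network import (
    FluxVector,
    InfeasibleConstraintsError,
    MetabolicNetwork,
    null_space_parameterization,
)
from .emu import EMU, InputLabeling, decompose, simulate_mids, DegenerateFluxError
from .measurements import FragmentDef, MeasuredMID, map_fragment_to_emus, predict_fragment_mid

__all__ = [
    "PrecursorDemand",
    "FluxModel",
    "FitResult",
    "ConfidenceInterval",
    "build_constraints",
    "objective_rss",
    "fit_fluxes",
    "chi_square_threshold",
    "goodness_of_fit",
    "grid_search_ci",
    "compare_ci",
]

PENALTY_SCALE = 1e3  # soft enforcement of flux bounds in the residual vector
DEFAULT_EXCHANGE_BOUND = 20.0  # mmol g-DCW^-1 h^-1


@dataclass(frozen=True)
class PrecursorDemand:
    """Biomass precursor requirements: mmol of precursor per g-DCW.

    The biomass efflux of each precursor is ``coefficient * mu``.  The
    coefficients are organism- and model-specific data, shipped as an
    editable file; the defaults bundled with the synthetic networks are
    synthetic placeholders, not literature values.
    """

    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.coefficients.values()):
            raise ValueError("precursor-demand coefficients must be >= 0")

    def effluxes(self, mu: float) -> dict[str, float]:
        return {met: c * mu for met, c in self.coefficients.items()}


@dataclass
class FluxModel:
    """Constrained flux space plus everything needed to simulate MIDs."""

    network: MetabolicNetwork
    constraints: dict[str, float]
    fragments: dict[str, FragmentDef]
    labeling: InputLabeling
    v0: np.ndarray = field(repr=False, default=None)
    N: np.ndarray = field(repr=False, default=None)
    reaction_ids: list[str] = field(default_factory=list)
    exchange_bound: float = DEFAULT_EXCHANGE_BOUND
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.v0 is None:
            self.v0, self.N, self.reaction_ids = null_space_parameterization(
                self.network, self.constraints)
        self._rpos = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.exchange_ids = self.network.reversible_ids
        self._emunet_cache: dict[frozenset, object] = {}

    # -- parameterization ---------------------------------------------------

    @property
    def n_net_free(self) -> int:
        return self.N.shape[1]

    @property
    def n_free(self) -> int:
        return self.n_net_free + len(self.exchange_ids)

    def theta_to_fluxes(self, theta: np.ndarray) -> FluxVector:
        v = self.v0 + self.N @ theta[: self.n_net_free]
        exch = {rid: float(e) for rid, e in
                zip(self.exchange_ids, theta[self.n_net_free:])}
        return FluxVector(
            {rid: float(v[j]) for j, rid in enumerate(self.reaction_ids)}, exch)

    def flux_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower for r in self.network.reactions])
        ub = np.array([r.upper for r in self.network.reactions])
        return lb, ub

    def theta_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        k, ne = self.n_net_free, len(self.exchange_ids)
        lo = np.concatenate([np.full(k, -np.inf), np.zeros(ne)])
        hi = np.concatenate([np.full(k, np.inf),
                             np.full(ne, self.exchange_bound)])
        return lo, hi

    def chebyshev_center(self) -> tuple[np.ndarray, float]:
        """Most-interior net-flux parameter point and its bound slack."""
        lb, ub = self.flux_bounds()
        k = self.n_net_free
        if k == 0:
            v = self.v0
            slack = float(min(np.min(v - lb), np.min(ub - v)))
            return np.zeros(0), slack
        A = np.vstack([np.hstack([-self.N, np.ones((len(lb), 1))]),
                       np.hstack([self.N, np.ones((len(ub), 1))])])
        b = np.concatenate([self.v0 - lb, ub - self.v0])
        res = linprog(np.concatenate([np.zeros(k), [-1.0]]), A_ub=A, b_ub=b,
                      bounds=[(None, None)] * k + [(None, None)],
                      method="highs")
        if not res.success:
            raise InfeasibleConstraintsError("no feasible flux point exists")
        return res.x[:k], float(res.x[k])

    def with_fixed(self, flux_id: str, value: float) -> "FluxModel":
        """Copy of the model with one additional fixed net flux."""
        constraints = dict(self.constraints)
        constraints[flux_id] = value
        model = replace(self, constraints=constraints, v0=None, N=None,
                        reaction_ids=[])
        model._emunet_cache = self._emunet_cache  # EMU nets depend on fragments only
        return model

    # -- simulation ---------------------------------------------------------

    def _emunet(self, fragment_ids: frozenset):
        key = fragment_ids
        if key not in self._emunet_cache:
            targets: list[EMU] = []
            for fid in sorted(fragment_ids):
                targets.extend(
                    map_fragment_to_emus(self.fragments[fid], self.network))
            self._emunet_cache[key] = decompose(self.network, targets)
        return self._emunet_cache[key]

    def simulate_fragment_mids(
        self, fluxes: FluxVector, fragment_ids,
    ) -> dict[str, np.ndarray]:
        emunet = self._emunet(frozenset(fragment_ids))
        emu_mids = simulate_mids(emunet, fluxes, self.labeling)
        return {fid: predict_fragment_mid(self.fragments[fid], emu_mids)
                for fid in fragment_ids}


@dataclass
class FitResult:
    fluxes: FluxVector
    theta: np.ndarray
    rss: float
    n_data: int
    n_free: int
    threshold: float
    passed: bool
    start_rss: list[float]
    seed: int | None
    se_net: dict[str, float] = field(default_factory=dict)

    @property
    def degrees_of_freedom(self) -> int:
        return self.n_data - self.n_free


@dataclass
class ConfidenceInterval:
    flux_id: str
    lower: float
    upper: float
    level: float = 0.95
    lower_censored: bool = False
    upper_censored: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower CI bound exceeds upper")


def build_constraints(
    net: MetabolicNetwork,
    rates=None,
    demand: PrecursorDemand | None = None,
    *,
    analyte_map: dict[str, str] | None = None,
    fixed: dict[str, float] | None = None,
    fragments: dict[str, FragmentDef] | None = None,
    labeling: InputLabeling | None = None,
    weighted: bool = True,
    exchange_bound: float = DEFAULT_EXCHANGE_BOUND,
) -> FluxModel:
    """Assemble the constrained flux model.

    Measured specific rates are pinned onto the exchange reactions named by
    ``analyte_map`` (analyte -> reaction id); biomass effluxes are pinned to
    ``demand.coefficient[met] * mu`` on the unique drain reaction consuming
    each precursor into sink species.  Extra fixed fluxes go in ``fixed``.
    Raises a mapping error for unmatched analytes/precursors and an
    infeasibility error when the constraints contradict the carbon balance
    or the flux bounds.
    """
    constraints: dict[str, float] = dict(fixed or {})
    rxn_ids = set(net.reaction_ids)
    if rates is not None:
        # analytes absent from the map are left unconstrained (e.g. a trace
        # by-product the network does not model)
        for analyte, rid in (analyte_map or {}).items():
            if analyte not in rates.rates:
                raise KeyError(f"no measured rate for mapped analyte {analyte!r}")
            if rid not in rxn_ids:
                raise KeyError(f"analyte {analyte!r} maps to unknown reaction {rid!r}")
            constraints[rid] = float(rates.rates[analyte])
    if demand is not None:
        mu = rates.mu if rates is not None else None
        if mu is None:
            raise ValueError("precursor demands need a growth rate")
        for met, efflux in demand.effluxes(mu).items():
            drains = [r.id for r in net.reactions
                      if [m for m, _ in r.substrates] == [met]
                      and all(net.metabolite(m).role == "sink"
                              for m, _ in r.products)]
            if len(drains) != 1:
                raise KeyError(
                    f"precursor {met!r}: expected exactly one biomass drain "
                    f"reaction, found {drains}")
            constraints[drains[0]] = efflux
    model = FluxModel(net, constraints,
                      fragments=fragments or {},
                      labeling=labeling,
                      weighted=weighted, exchange_bound=exchange_bound)
    _, slack = model.chebyshev_center()  # raises if equalities + bounds clash
    if slack < -1e-6:
        raise InfeasibleConstraintsError(
            f"constraints violate flux bounds (slack {slack:.3g})")
    return model


def _residuals(model: FluxModel, theta: np.ndarray,
               measurements: list[MeasuredMID]) -> np.ndarray:
    fluxes = model.theta_to_fluxes(theta)
    frag_ids = [m.fragment_id for m in measurements]
    n_channels = sum(len(m.fractions) for m in measurements)
    lb, ub = model.flux_bounds()
    v = np.array([fluxes.net[r] for r in model.reaction_ids])
    pen = PENALTY_SCALE * (np.clip(lb - v, 0, None) + np.clip(v - ub, 0, None))
    try:
        sims = model.simulate_fragment_mids(fluxes, frag_ids)
    except DegenerateFluxError:
        return np.concatenate([np.full(n_channels, 1e3), pen])
    res = []
    for m in measurements:
        sim = sims[m.fragment_id]
        if len(sim) != len(m.fractions):
            raise ValueError(
                f"{m.fragment_id}: fragment predicts {len(sim)} channels, "
                f"measurement has {len(m.fractions)}")
        r = sim - m.fractions
        if model.weighted:
            r = r / m.sd
        res.append(r)
    return np.concatenate(res + [pen])


def objective_rss(model: FluxModel, fluxes: FluxVector | np.ndarray,
                  measurements: list[MeasuredMID]) -> float:
    """Sum over fragments and mass channels of ((sim - meas)/sd)^2
    (unweighted if the model says so).  Excludes bound penalties."""
    if isinstance(fluxes, FluxVector):
        theta_net, *_ = np.linalg.lstsq(
            model.N, np.array([fluxes.net[r] for r in model.reaction_ids]) - model.v0,
            rcond=None)
        exch = np.array([fluxes.exchange.get(r, 0.0) for r in model.exchange_ids])
        theta = np.concatenate([theta_net, exch])
    else:
        theta = np.asarray(fluxes, float)
    n_channels = sum(len(m.fractions) for m in measurements)
    r = _residuals(model, theta, measurements)[:n_channels]
    return float(r @ r)


class _FixedPointResult:
    """Stand-in for a least_squares result when nothing is free."""

    def __init__(self, fun):
        self.x = np.zeros(0)
        self.fun = fun
        self.jac = np.zeros((len(fun), 0))


def _local_fit(model, measurements, theta0):
    if model.n_free == 0:
        return _FixedPointResult(_residuals(model, np.zeros(0), measurements))
    lo, hi = model.theta_bounds()
    theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
    return least_squares(lambda th: _residuals(model, th, measurements),
                         theta0, bounds=(lo, hi), method="trf",
                         xtol=1e-10, ftol=1e-10, gtol=1e-10)


def fit_fluxes(
    model: FluxModel,
    measurements: list[MeasuredMID],
    n_starts: int = 20,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> FitResult:
    """Best-of-multistart local least squares over the free fluxes.

    Starts are drawn around the Chebyshev center of the feasible polytope;
    the run is deterministic given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    center, slack = model.chebyshev_center()
    k, ne = model.n_net_free, len(model.exchange_ids)
    scale = max(slack, 0.1)
    n_channels = sum(len(m.fractions) for m in measurements)

    best = None
    start_rss: list[float] = []
    failures = []
    for i in range(n_starts):
        theta0 = np.concatenate([
            center + (scale * rng.standard_normal(k) if i else np.zeros(k)),
            rng.uniform(0.0, min(2.0, model.exchange_bound), ne),
        ])
        try:
            res = _local_fit(model, measurements, theta0)
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            failures.append(str(exc))
            continue
        r = res.fun[:n_channels]
        rss = float(r @ r)
        start_rss.append(rss)
        if best is None or rss < best_rss:
            best, best_rss = res, rss
    if best is None:
        raise RuntimeError(
            f"all {n_starts} starts failed to converge: {failures[:3]}")

    n_free = model.n_free
    threshold = chi_square_threshold(n_channels, n_free, alpha)
    se_net = _net_flux_se(model, best, n_channels)
    return FitResult(
        fluxes=model.theta_to_fluxes(best.x), theta=best.x, rss=best_rss,
        n_data=n_channels, n_free=n_free, threshold=threshold,
        passed=best_rss <= threshold, start_rss=start_rss, seed=seed,
        se_net=se_net)


def _net_flux_se(model, ls_result, n_channels) -> dict[str, float]:
    """Linearized standard errors of the net fluxes (heuristic; used to seed
    the CI grid, never as the reported interval)."""
    J = ls_result.jac[:n_channels, : model.n_net_free]
    try:
        cov = np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:
        return {}
    var_v = np.einsum("ij,jk,ik->i", model.N, cov, model.N)
    return {rid: float(np.sqrt(max(var_v[j], 0.0)))
            for j, rid in enumerate(model.reaction_ids)}


def chi_square_threshold(n_data: int, n_free: int, alpha: float = 0.05) -> float:
    """(1 - alpha) quantile of chi-square with df = n_data - n_free."""
    df = n_data - n_free
    if df <= 0:
        raise ValueError(f"nonpositive degrees of freedom ({df})")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(chi2.ppf(1.0 - alpha, df))


def goodness_of_fit(fit: FitResult) -> dict:
    """Chi-square goodness-of-fit report for a completed fit."""
    return {
        "rss": fit.rss,
        "threshold": fit.threshold,
        "n_data": fit.n_data,
        "n_free": fit.n_free,
        "degrees_of_freedom": fit.degrees_of_freedom,
        "passed": bool(fit.rss <= fit.threshold),
    }


def _profile_rss(model: FluxModel, measurements, flux_id: str, value: float,
                 warm_starts: list[FluxVector],
                 n_channels: int) -> tuple[float, FluxVector | None]:
    """Minimal RSS with one net flux pinned to ``value``.

    Re-optimizes from every warm start (the global best fit plus, during a
    scan, the neighboring grid point's solution) and keeps the best; returns
    ``(rss, re-optimized fluxes)`` or ``(inf, None)`` when the pin is
    infeasible."""
    try:
        sub = model.with_fixed(flux_id, value)
        _, slack = sub.chebyshev_center()
    except InfeasibleConstraintsError:
        return np.inf, None
    if slack < -1e-6:
        return np.inf, None
    best_rss, best_fluxes = np.inf, None
    for warm in warm_starts:
        v_target = np.array([warm.net[r] for r in sub.reaction_ids])
        theta_net, *_ = np.linalg.lstsq(sub.N, v_target - sub.v0, rcond=None) \
            if sub.n_net_free else (np.zeros(0),)
        exch = np.array([warm.exchange.get(r, 0.0) for r in sub.exchange_ids])
        res = _local_fit(sub, measurements, np.concatenate([theta_net, exch]))
        r = res.fun[:n_channels]
        rss = float(r @ r)
        if rss < best_rss:
            best_rss, best_fluxes = rss, sub.theta_to_fluxes(res.x)
    return best_rss, best_fluxes


def grid_search_ci(
    model: FluxModel,
    measurements: list[MeasuredMID],
    fit: FitResult,
    flux_id: str,
    level: float = 0.95,
    *,
    n_grid: int = 21,
    max_doublings: int = 12,
) -> ConfidenceInterval:
    """Profile-likelihood CI of one net flux by grid search.

    Scans the flux over a grid around the point estimate (initially
    ``n_grid`` points over +/- 3 heuristic SEs, expanded adaptively),
    re-optimizing all other free fluxes at each grid value; the CI is the
    set of values whose re-optimized RSS stays within the chi-square(df=1)
    quantile (3.84 at 95%) of the minimum.  Endpoints are refined by
    bisection; an endpoint that runs into a flux bound is reported censored
    at that bound.
    """
    if flux_id not in model._rpos:
        raise KeyError(f"unknown flux {flux_id!r}")
    delta = float(chi2.ppf(level, 1))
    target = fit.rss + delta
    vhat = fit.fluxes.net[flux_id]
    n_channels = fit.n_data
    se = fit.se_net.get(flux_id, 0.0)
    if not np.isfinite(se) or se <= 0:
        se = max(0.05 * abs(vhat), 0.01)
    step0 = 6.0 * se / (n_grid - 1)
    rxn = model.network.reaction(flux_id)

    def scan(direction: int) -> tuple[float, bool]:
        inside = vhat
        step = step0
        moved = 0
        neighbor: list[FluxVector] = []  # continuation along the profile

        def prof(value: float) -> float:
            rss, fluxes = _profile_rss(model, measurements, flux_id, value,
                                       [fit.fluxes] + neighbor, n_channels)
            if fluxes is not None:
                neighbor[:] = [fluxes]
            return rss

        while True:
            value = inside + direction * step
            bound = rxn.upper if direction > 0 else rxn.lower
            if (direction > 0 and value >= bound) or (direction < 0 and value <= bound):
                value = bound
            rss = prof(value)
            if rss > target:
                # refine the crossing between `inside` and `value`
                lo, hi = (inside, value) if direction > 0 else (value, inside)
                xtol = 1e-3 * max(abs(vhat), 0.01)  # 1e-3 of flux magnitude
                root = brentq(lambda x: min(prof(x), 1e9) - target, lo, hi,
                              xtol=xtol)
                return float(root), False
            inside = value
            if value == bound:
                return float(bound), True
            moved += 1
            if moved >= n_grid // 2:
                step *= 2.0  # adaptive expansion past the initial grid
            if moved >= n_grid // 2 + max_doublings:
                return float(inside), True

    upper, up_cens = scan(+1)
    lower, lo_cens = scan(-1)
    return ConfidenceInterval(flux_id, min(lower, vhat), max(upper, vhat),
                              level, lo_cens, up_cens)


def compare_ci(ci_a: ConfidenceInterval, ci_b: ConfidenceInterval) -> bool:
    """Flux difference is called significant iff the two closed CIs are
    disjoint (touching endpoints overlap, hence not significant)."""
    if ci_a.flux_id != ci_b.flux_id or ci_a.level != ci_b.level:
        raise ValueError("can only compare CIs of the same flux and level")
    return bool(ci_a.upper < ci_b.lower or ci_b.upper < ci_a.lower)
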
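"""Double-observer mark-recapture detection submodel.

Two observer teams (front and rear seats) act as capture occasions, so the
probability of detecting a cluster on the transect line can be estimated
instead of assumed to be 1. Each team's detection probability for cluster i
follows a logistic model

    logit(p_{i,pos}) = b0_pos + b1 * d_i [+ b2 * x_i],

with position-specific intercepts, a common distance slope, and at most one
extra covariate. The likelihood conditions on detection by at least one
team: with p* = 1 - (1-pF)(1-pR), the capture histories (front only, rear
only, both) are multinomial with probabilities

    P(10) = pF (1-pR) / p*,   P(01) = (1-pF) pR / p*,   P(11) = pF pR / p*,

which always sum to one. This is the independent-observer ("io")
configuration of the MRDS framework.

Distances enter the linear predictor in kilometers internally for optimizer
conditioning; ``coef_distance_per_m`` reports the slope per meter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .model_averaging import aicc, akaike_weights
from .survey_data import SurveyDataset

__all__ = [
    "MRModelSpec",
    "MRFit",
    "MRModelSetResult",
    "MREstimationError",
    "CovariateMissingError",
    "MR_EXTRA_COVARIATES",
    "BLIND_SPOT_M",
    "mr_loglik",
    "fit_mr",
    "p0_star",
    "mr_model_set",
    "mr_gof",
]

#: rear-seat blind spot: sightings within this distance of the line get the dummy
BLIND_SPOT_M = 75.0

#: the nine candidate single-extra-covariate specifications
MR_EXTRA_COVARIATES = (
    "none",
    "distance2",
    "cluster_size",
    "activity",
    "ice_rough",
    "visibility_bad",
    "cloud",
    "blind_spot",
    "distance_position",
)

_COVARIATE_EXTRAS = {"cluster_size", "activity", "ice_rough", "visibility_bad", "cloud"}
_EXTRA_FIELD = {
    "activity": "activity",
    "ice_rough": "ice_rough",
    "visibility_bad": "visibility_bad",
    "cloud": "cloud_quartile",
}


class MREstimationError(RuntimeError):
    """Optimization failed or the information matrix is singular."""


class CovariateMissingError(ValueError):
    """A covariate model was requested on data without recorded covariates."""


@dataclass(frozen=True)
class MRModelSpec:
    """One candidate model: intercepts + distance plus at most one extra term."""

    extra_covariate: str = "none"

    def __post_init__(self) -> None:
        if self.extra_covariate not in MR_EXTRA_COVARIATES:
            raise ValueError(f"unknown extra covariate {self.extra_covariate!r}")

    @property
    def k(self) -> int:
        """Number of estimated coefficients (b0F, b0R, b1 [+ b2])."""
        return 3 if self.extra_covariate == "none" else 4

    @property
    def coef_names(self) -> tuple[str, ...]:
        base = ("intercept_front", "intercept_rear", "distance_km")
        return base if self.extra_covariate == "none" else base + (self.extra_covariate,)


def _design(dataset: SurveyDataset, spec: MRModelSpec) -> tuple[np.ndarray, ...]:
    """Per-cluster distance (km), extra-term values by position, capture history."""
    if dataset.n_observations == 0:
        raise MREstimationError("empty dataset")
    d_km = dataset.distances() / 1000.0
    sf = np.array([o.seen_front for o in dataset.observations])
    sr = np.array([o.seen_rear for o in dataset.observations])
    extra = spec.extra_covariate
    n = len(d_km)
    if extra == "none":
        xf = xr = np.zeros(n)
    elif extra == "distance2":
        xf = xr = d_km**2
    elif extra == "blind_spot":
        xf = np.zeros(n)
        xr = (dataset.distances() <= BLIND_SPOT_M).astype(float)
    elif extra == "distance_position":
        xf = np.zeros(n)
        xr = d_km
    elif extra == "cluster_size":
        xf = xr = dataset.cluster_sizes()
    elif extra in _EXTRA_FIELD:
        vals = [getattr(o, _EXTRA_FIELD[extra]) for o in dataset.observations]
        if any(v is None for v in vals):
            raise CovariateMissingError(
                f"covariate {extra!r} is not recorded for every observation; "
                "covariate models cannot be fit to fixture data without covariates"
            )
        xf = xr = np.asarray(vals, dtype=float)
    else:  # pragma: no cover - guarded by MRModelSpec
        raise ValueError(extra)
    if extra in _COVARIATE_EXTRAS and np.ptp(np.asarray(xf, dtype=float)) == 0:
        raise CovariateMissingError(
            f"covariate {extra!r} is constant across observations; effect not estimable"
        )
    return d_km, xf, xr, sf, sr


def _probs(coef: np.ndarray, d_km, xf, xr) -> tuple[np.ndarray, np.ndarray]:
    b0f, b0r, b1 = coef[0], coef[1], coef[2]
    b2 = coef[3] if len(coef) > 3 else 0.0
    eta_f = b0f + b1 * d_km + b2 * xf
    eta_r = b0r + b1 * d_km + b2 * xr
    if not (np.all(np.isfinite(eta_f)) and np.all(np.isfinite(eta_r))):
        raise MREstimationError("non-finite linear predictor")
    return special.expit(eta_f), special.expit(eta_r)


def mr_loglik(coefficients: Sequence[float], dataset: SurveyDataset, spec: MRModelSpec) -> float:
    """Conditional log likelihood of the observed capture histories."""
    coef = np.asarray(coefficients, dtype=float)
    if len(coef) != spec.k:
        raise ValueError(f"expected {spec.k} coefficients for spec {spec.extra_covariate!r}")
    d_km, xf, xr, sf, sr = _design(dataset, spec)
    pf, pr = _probs(coef, d_km, xf, xr)
    # log P(history)/p*, clipped away from exact 0/1 for numerical safety
    eps = 1e-300
    p_star = 1.0 - (1.0 - pf) * (1.0 - pr)
    p_hist = np.where(
        sf & sr, pf * pr, np.where(sf == 1, pf * (1.0 - pr), (1.0 - pf) * pr)
    )
    return float(np.sum(np.log(np.maximum(p_hist, eps)) - np.log(np.maximum(p_star, eps))))


def p0_star(
    p_f0: float,
    p_r0: float,
    var_f: float | None = None,
    var_r: float | None = None,
    cov_fr: float = 0.0,
) -> tuple[float, float | None]:
    """Probability at least one observer detects a cluster on the line.

    p0* = 1 - (1 - pF0)(1 - pR0); the SE (returned when variances are
    supplied) is the delta-method propagation with gradient
    (1 - pR0, 1 - pF0).
    """
    for p in (p_f0, p_r0):
        if not (0.0 < p <= 1.0):
            raise ValueError("detection probabilities must lie in (0, 1]")
    value = 1.0 - (1.0 - p_f0) * (1.0 - p_r0)
    if var_f is None or var_r is None:
        return value, None
    gf, gr = 1.0 - p_r0, 1.0 - p_f0
    var = gf**2 * var_f + gr**2 * var_r + 2.0 * gf * gr * cov_fr
    return value, float(np.sqrt(max(var, 0.0)))


@dataclass
class MRFit:
    """A fitted double-observer model with line-intercept summaries."""

    spec: MRModelSpec
    coefficients: np.ndarray
    vcov: np.ndarray
    loglik: float
    k: int
    n: int
    aicc: float
    p0_front: float
    se_p0_front: float
    p0_rear: float
    se_p0_rear: float
    p0_star: float
    se_p0_star: float
    identifiable: bool = True
    message: str = ""
    delta_aicc: float = np.nan
    weight: float = np.nan
    uninformative: bool = False

    @property
    def label(self) -> str:
        return self.spec.extra_covariate

    @property
    def coef_distance_per_m(self) -> float:
        """Distance slope expressed per meter (fitted internally per km)."""
        return float(self.coefficients[2]) / 1000.0


def _p0_summaries(coef: np.ndarray, dataset: SurveyDataset, spec: MRModelSpec,
                  weights: np.ndarray | None = None) -> np.ndarray:
    """(mean pF0, mean pR0, mean p0*) over detected clusters at distance 0.

    The extra term is evaluated at each cluster's own covariate value for
    covariate models and at its reference value 0 for the distance-based and
    blind-spot terms (distance and its square vanish on the line; the
    blind-spot reduction is reported separately from the line intercept).
    """
    n = dataset.n_observations
    b2 = coef[3] if len(coef) > 3 else 0.0
    extra = spec.extra_covariate
    if extra in _COVARIATE_EXTRAS:
        _, xf0, xr0, _, _ = _design(dataset, spec)
    else:
        xf0 = xr0 = np.zeros(n)
    pf0 = special.expit(coef[0] + b2 * xf0)
    pr0 = special.expit(coef[1] + b2 * xr0)
    ps0 = 1.0 - (1.0 - pf0) * (1.0 - pr0)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, float) / np.sum(weights)
    return np.array([weights @ pf0, weights @ pr0, weights @ ps0])


def fit_mr(
    dataset: SurveyDataset,
    spec: MRModelSpec = MRModelSpec(),
    n_starts: int = 5,
    seed: int = 0,
    p0_weighting: str = "simple",
) -> MRFit:
    """Maximum conditional likelihood fit of one double-observer model.

    Multistart quasi-Newton optimization from the null model plus jittered
    starts; the covariance matrix is the inverse observed information. AICc
    uses n = number of detected clusters. ``p0_weighting`` controls how
    per-cluster line intercepts are summarized for covariate models:
    ``"simple"`` (unweighted mean, default) or ``"ht"``
    (inverse-p* weighted, the Horvitz-Thompson weighting).
    """
    d_km, xf, xr, sf, sr = _design(dataset, spec)
    n = dataset.n_observations
    if n < spec.k + 1:
        raise MREstimationError(f"need at least {spec.k + 1} observations, have {n}")
    front_only = int(np.sum((sf == 1) & (sr == 0)))
    rear_only = int(np.sum((sf == 0) & (sr == 1)))
    identifiable = front_only > 0 and rear_only > 0
    if p0_weighting not in ("simple", "ht"):
        raise ValueError("p0_weighting must be 'simple' or 'ht'")

    def nll(c: np.ndarray) -> float:
        try:
            return -mr_loglik(c, dataset, spec)
        except MREstimationError:
            return np.inf

    rng = np.random.default_rng(seed)
    x0 = np.zeros(spec.k)
    starts = [x0] + [x0 + rng.normal(scale=0.5, size=spec.k) for _ in range(n_starts - 1)]
    best = None
    for start in starts:
        res = optimize.minimize(nll, start, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise MREstimationError("optimization failed from every start")
    coef = best.x
    # boundary drift (|coef| huge) signals a degenerate capture-history design
    if np.any(np.abs(coef) > 15.0):
        identifiable = False

    hess = approx_hess(coef, nll)
    try:
        vcov = np.linalg.inv(hess)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if identifiable:
            raise MREstimationError(
                "singular information matrix; consider a simpler specification"
            ) from None
        vcov = np.full((spec.k, spec.k), np.nan)
    vcov = 0.5 * (vcov + vcov.T)

    ll = -best.fun
    weights = None
    if p0_weighting == "ht":
        pf, pr = _probs(coef, d_km, xf, xr)
        weights = 1.0 / (1.0 - (1.0 - pf) * (1.0 - pr))
    summ = _p0_summaries(coef, dataset, spec, weights)
    if np.all(np.isfinite(vcov)):
        grad = approx_fprime(
            coef, lambda c: _p0_summaries(c, dataset, spec, weights), centered=True
        )
        ses = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", grad, vcov, grad), 0.0))
    else:
        ses = np.full(3, np.nan)

    msg = "" if identifiable else (
        "boundary or degenerate capture-history design; estimates not identifiable"
    )
    return MRFit(
        spec=spec,
        coefficients=coef,
        vcov=vcov,
        loglik=ll,
        k=spec.k,
        n=n,
        aicc=aicc(ll, spec.k, n),
        p0_front=float(summ[0]),
        se_p0_front=float(ses[0]),
        p0_rear=float(summ[1]),
        se_p0_rear=float(ses[1]),
        p0_star=float(summ[2]),
        se_p0_star=float(ses[2]),
        identifiable=identifiable,
        message=msg,
    )


@dataclass
class MRModelSetResult:
    """Ranked candidate-set fits plus per-spec failures."""

    fits: list[MRFit]
    failures: dict[str, str] = field(default_factory=dict)

    def averaging_set(self, delta_max: float = 4.0) -> list[MRFit]:
        """Fits with delta AICc below ``delta_max`` and no uninformative extra."""
        return [f for f in self.fits if f.delta_aicc < delta_max and not f.uninformative]


def mr_model_set(
    dataset: SurveyDataset,
    extras: Sequence[str] = MR_EXTRA_COVARIATES,
    seed: int = 0,
    uninformative_delta: float = 2.0,
    uninformative_z: float = 1.28,
) -> MRModelSetResult:
    """Fit the candidate set and rank by AICc with Akaike weights.

    A one-extra-parameter model whose AICc lies within ``uninformative_delta``
    of the nested base model while the extra coefficient's |z| is below
    ``uninformative_z`` is flagged as carrying an uninformative parameter and
    is excluded from model averaging. Single-spec failures (e.g. covariate
    models on data without covariates) are recorded, not fatal.
    """
    fits: list[MRFit] = []
    failures: dict[str, str] = {}
    base: MRFit | None = None
    for extra in extras:
        try:
            fit = fit_mr(dataset, MRModelSpec(extra), seed=seed)
        except (MREstimationError, CovariateMissingError, ValueError) as exc:
            failures[extra] = str(exc)
            continue
        if extra == "none":
            base = fit
        fits.append(fit)
    if not fits:
        raise MREstimationError(f"no candidate model could be fit: {failures}")
    if base is not None:
        for fit in fits:
            if fit.k != base.k + 1 or not np.all(np.isfinite(fit.vcov)):
                continue
            se = float(np.sqrt(fit.vcov[3, 3]))
            z = abs(fit.coefficients[3]) / se if se > 0 else np.inf
            if abs(fit.aicc - base.aicc) < uninformative_delta and z < uninformative_z:
                fit.uninformative = True
    fits.sort(key=lambda f: (f.aicc, f.k))
    weights = akaike_weights([f.aicc for f in fits])
    best_aicc = fits[0].aicc
    for fit, w in zip(fits, weights):
        fit.delta_aicc = fit.aicc - best_aicc
        fit.weight = float(w)
    return MRModelSetResult(fits=fits, failures=failures)


def mr_gof(
    fit: MRFit, dataset: SurveyDataset, bin_width_m: float = 200.0, min_expected: float = 2.0
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit of the detection frequencies.

    For each observer position, observed and expected seen/missed counts
    (conditional on detection by at least one team, so the expected seen
    probability for the front team is pF/p*) are compared per distance
    bin. Adjacent bins whose smaller expected cell falls below
    ``min_expected`` are pooled. Each pooled bin carries a fixed total, so
    it contributes one free cell; df = pooled bins (both observers) - k.
    """
    d_km, xf, xr, sf, sr = _design(dataset, fit.spec)
    pf, pr = _probs(fit.coefficients, d_km, xf, xr)
    p_star = 1.0 - (1.0 - pf) * (1.0 - pr)

    d_m = dataset.distances()
    edges = np.arange(0.0, d_m.max() + bin_width_m, bin_width_m)
    if edges[-1] < d_m.max() + 1e-9:
        edges = np.append(edges, edges[-1] + bin_width_m)
    bin_idx = np.clip(np.searchsorted(edges, d_m, side="right") - 1, 0, len(edges) - 2)

    chi2 = 0.0
    n_free_cells = 0
    for seen, p_seen in ((sf, pf / p_star), (sr, pr / p_star)):
        pooled: list[tuple[float, float, float]] = []  # (obs seen, exp seen, total)
        acc_o = acc_e = acc_n = 0.0
        for b in range(len(edges) - 1):
            in_b = bin_idx == b
            acc_o += float(np.sum(seen[in_b]))
            acc_e += float(np.sum(p_seen[in_b]))
            acc_n += float(np.sum(in_b))
            if min(acc_e, acc_n - acc_e) >= min_expected:
                pooled.append((acc_o, acc_e, acc_n))
                acc_o = acc_e = acc_n = 0.0
        if acc_n > 0:  # trailing remainder pools into the last cell
            if pooled:
                o, e, n = pooled[-1]
                pooled[-1] = (o + acc_o, e + acc_e, n + acc_n)
            else:
                pooled.append((acc_o, acc_e, acc_n))
        for o, e, n in pooled:
            e_miss = n - e
            if e > 0:
                chi2 += (o - e) ** 2 / e
            if e_miss > 0:
                chi2 += ((n - o) - e_miss) ** 2 / e_miss
        n_free_cells += len(pooled)
    df = n_free_cells - fit.k
    if df < 1:
        raise MREstimationError(
            f"only {n_free_cells} pooled bins for {fit.k} parameters; GOF not defined"
        )
    p_value = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p_value
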
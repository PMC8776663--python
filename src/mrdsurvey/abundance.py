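"""Stratified Horvitz-Thompson abundance with a full variance decomposition.

Cluster abundance in the surveyed strips is the Horvitz-Thompson sum
C_S = sum_k c_k / p_a, where c_k counts detected clusters in stratum k and
p_a = p0* x p_d is the average (mark-recapture x distance-sampling)
detection probability. Scaling by the inverse coverage A_k / a_k of each
stratum (a_k = 2 w L_k of strip area) gives total cluster abundance, and
multiplying by mean cluster size g gives bears.

Variance has two additive components on the cluster scale: a detection
component from the delta method on p_a, and an encounter-rate component
from the among-transect variance of counts, estimated with the systematic
"S2" estimator that treats adjacent transects (in design order) as paired
samples and weights by transect length. Interval estimates assume the
abundance estimator is lognormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .survey_data import SurveyDataset, TransectRecord

__all__ = [
    "AbundanceEstimate",
    "combined_pa",
    "mean_group",
    "s2_rate_variance",
    "encounter_var_s2",
    "ht_abundance",
    "lognormal_ci",
    "extrapolate",
    "cv_components",
    "effort_for_cv",
]


def combined_pa(
    p0_star: float, var_p0: float, pd: float, var_pd: float
) -> tuple[float, float]:
    """Average detection probability p_a = p0* x p_d with delta-method variance.

    var(p_a) = (p0*)^2 var(p_d) + (p_d)^2 var(p0*).
    """
    for p in (p0_star, pd):
        if not (0.0 < p <= 1.0):
            raise ValueError("detection probabilities must lie in (0, 1]")
    if var_p0 < 0 or var_pd < 0:
        raise ValueError("variances must be >= 0")
    pa = p0_star * pd
    var_pa = p0_star**2 * var_pd + pd**2 * var_p0
    return pa, var_pa


def mean_group(dataset: SurveyDataset) -> tuple[float, float]:
    """Mean cluster size with SE = sample SD / sqrt(n)."""
    sizes = dataset.cluster_sizes()
    if len(sizes) == 0:
        raise ValueError("no observations; mean cluster size undefined")
    se = 0.0 if len(sizes) == 1 else float(np.std(sizes, ddof=1) / np.sqrt(len(sizes)))
    return float(np.mean(sizes)), se


def s2_rate_variance(lengths_km: Sequence[float], counts: Sequence[int]) -> float:
    """Systematic ("S2") estimator of var(n/L) for one stratum.

    Transects must be supplied in design order. Non-overlapping adjacent
    pairs form the groups (a trailing triple when the count is odd); within
    group h the length-weighted estimator is

        var_h(n/L) = K_h / (L_h^2 (K_h - 1)) * sum_j l_j^2 (n_j/l_j - n_h/L_h)^2

    and groups combine as var(n/L) = sum_h (L_h / L)^2 var_h.
    """
    ell = np.asarray(lengths_km, dtype=float)
    cnt = np.asarray(counts, dtype=float)
    if len(ell) != len(cnt):
        raise ValueError("lengths and counts must align")
    k = len(ell)
    if k < 2:
        raise ValueError("at least 2 transects required for the S2 estimator")
    groups: list[np.ndarray] = []
    idx = np.arange(k)
    n_pairs = k // 2
    for h in range(n_pairs):
        groups.append(idx[2 * h : 2 * h + 2])
    if k % 2 == 1:  # fold the odd transect into the last group
        groups[-1] = np.concatenate([groups[-1], idx[-1:]])
    total_l = float(ell.sum())
    var = 0.0
    for g in groups:
        lj, nj = ell[g], cnt[g]
        kh, lh = len(g), float(lj.sum())
        rate_h = nj.sum() / lh
        var_h = kh / (lh**2 * (kh - 1)) * float(np.sum(lj**2 * (nj / lj - rate_h) ** 2))
        var += (lh / total_l) ** 2 * var_h
    return var


def encounter_var_s2(
    transects: Sequence[TransectRecord], counts_by_transect: Mapping[str, int]
) -> dict[str, float]:
    """Per-stratum variance of the stratum total count, S2 estimator.

    ``counts_by_transect`` maps transect id -> detected clusters (missing
    ids count zero). The rate variance var(n/L) is scaled to the count by
    L^2. Raises when a stratum has a single transect, naming the stratum.
    """
    by_stratum: dict[str, list[TransectRecord]] = {}
    for t in transects:
        by_stratum.setdefault(t.stratum_id, []).append(t)
    out: dict[str, float] = {}
    for sid, trs in by_stratum.items():
        trs = sorted(trs, key=lambda t: t.design_order)
        if len(trs) < 2:
            raise ValueError(f"stratum {sid!r} has a single transect; S2 variance undefined")
        lengths = [t.length_km for t in trs]
        counts = [counts_by_transect.get(t.id, 0) for t in trs]
        total_l = float(sum(lengths))
        out[sid] = total_l**2 * s2_rate_variance(lengths, counts)
    return out


@dataclass
class AbundanceEstimate:
    """Stratified abundance with its variance decomposition (cluster scale)."""

    clusters_surveyed: float
    clusters_total: float
    n_total: float
    mean_group_size: float
    se_mean_group: float
    pa: float
    se_pa: float
    var_detection: float
    var_encounter: float
    var_total: float
    var_n_total: float
    cv: float
    ci_low: float
    ci_high: float
    density_per_1000km2: dict[str, tuple[float, float]] = field(default_factory=dict)
    clusters_by_stratum: dict[str, int] = field(default_factory=dict)

    @property
    def se_n_total(self) -> float:
        return float(np.sqrt(self.var_n_total))


def ht_abundance(
    dataset: SurveyDataset,
    pa: float,
    var_pa: float,
    g_mean: float,
    var_g: float,
    level: float = 0.95,
) -> AbundanceEstimate:
    """Horvitz-Thompson abundance for a truncated survey dataset.

    A single p_a and mean cluster size are shared across strata; only the
    encounter rate (and its variance) differs by stratum. ``w`` is taken
    from each stratum's ``truncation_m``, so the dataset must already be
    truncated consistently.
    """
    if not (0.0 < pa <= 1.0):
        raise ValueError("pa must lie in (0, 1]")
    counts_by_transect: dict[str, int] = {}
    counts_by_stratum: dict[str, int] = {s.id: 0 for s in dataset.strata}
    for o in dataset.observations:
        counts_by_transect[o.transect_id] = counts_by_transect.get(o.transect_id, 0) + 1
        counts_by_stratum[o.stratum_id] += 1
    if sum(counts_by_stratum.values()) == 0:
        raise ValueError("no detections in any stratum; abundance not estimable")

    effort_km: dict[str, float] = {s.id: 0.0 for s in dataset.strata}
    for t in dataset.transects:
        effort_km[t.stratum_id] += t.length_km
    enc_var_counts = encounter_var_s2(dataset.transects, counts_by_transect)

    c_s = 0.0
    c_total = 0.0
    var_det = 0.0
    var_enc = 0.0
    densities: dict[str, tuple[float, float]] = {}
    for s in dataset.strata:
        c_k = counts_by_stratum[s.id]
        a_k = 2.0 * (s.truncation_m / 1000.0) * effort_km[s.id]
        if a_k <= 0:
            raise ValueError(f"stratum {s.id!r} has no surveyed effort")
        scale = s.area_km2 / a_k
        c_s += c_k / pa
        c_total_k = scale * c_k / pa
        c_total += c_total_k
        var_det_k = scale**2 * (c_k / pa**2) ** 2 * var_pa
        var_enc_k = (scale / pa) ** 2 * enc_var_counts[s.id]
        var_det += var_det_k
        var_enc += var_enc_k
        # per-stratum bears and density with the same decomposition
        n_k = c_total_k * g_mean
        var_n_k = c_total_k**2 * var_g + g_mean**2 * (var_det_k + var_enc_k)
        densities[s.id] = (
            1000.0 * n_k / s.area_km2,
            1000.0 * float(np.sqrt(var_n_k)) / s.area_km2,
        )

    var_c_total = var_det + var_enc
    n_total = c_total * g_mean
    var_n = c_total**2 * var_g + g_mean**2 * var_c_total
    cv = float(np.sqrt(var_n)) / n_total if n_total > 0 else np.inf
    lo, hi = lognormal_ci(n_total, cv, level)
    return AbundanceEstimate(
        clusters_surveyed=c_s,
        clusters_total=c_total,
        n_total=n_total,
        mean_group_size=g_mean,
        se_mean_group=float(np.sqrt(var_g)),
        pa=pa,
        se_pa=float(np.sqrt(var_pa)),
        var_detection=var_det,
        var_encounter=var_enc,
        var_total=var_c_total,
        var_n_total=var_n,
        cv=cv,
        ci_low=lo,
        ci_high=hi,
        density_per_1000km2=densities,
        clusters_by_stratum=counts_by_stratum,
    )


def lognormal_ci(estimate: float, cv: float, level: float = 0.95) -> tuple[float, float]:
    """Lognormal interval (estimate/C, estimate*C), C = exp(z sqrt(ln(1+cv^2)))."""
    if estimate < 0 or cv < 0:
        raise ValueError("estimate and cv must be >= 0")
    if cv == 0 or estimate == 0:
        return estimate, estimate
    z = stats.norm.ppf(0.5 + level / 2.0)
    c = float(np.exp(z * np.sqrt(np.log1p(cv**2))))
    return estimate / c, estimate * c


def extrapolate(
    density_per_1000km2: float, se_density: float, area_km2: float, level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Project a density (bears per 1000 km^2) onto an unsurveyed area.

    Returns (bears, SE, lognormal CI); the CV carries over from the density.
    """
    if density_per_1000km2 < 0 or se_density < 0 or area_km2 <= 0:
        raise ValueError("density and SE must be >= 0 and area > 0")
    n = density_per_1000km2 * area_km2 / 1000.0
    se = se_density * area_km2 / 1000.0
    cv = se / n if n > 0 else 0.0
    return n, se, lognormal_ci(n, cv, level)


def cv_components(
    estimate: AbundanceEstimate,
    p0_star: float,
    se_p0_star: float,
    pd: float,
    se_pd: float,
) -> dict[str, float]:
    """Coefficients of variation of each estimated component of abundance.

    Reports CVs for p0*, p_d, p_a, the encounter rate, cluster abundance,
    mean group size and total abundance, plus the label of the largest
    single component under ``"largest"``.
    """
    cvs = {
        "p0_star": se_p0_star / p0_star,
        "pd": se_pd / pd,
        "pa": estimate.se_pa / estimate.pa,
        "encounter": float(np.sqrt(estimate.var_encounter)) / estimate.clusters_total,
        "clusters_total": float(np.sqrt(estimate.var_total)) / estimate.clusters_total,
        "group_size": estimate.se_mean_group / estimate.mean_group_size,
        "n_total": estimate.cv,
    }
    largest = max(("p0_star", "pd", "encounter", "group_size"), key=lambda k: cvs[k])
    out = {k: float(v) for k, v in cvs.items()}
    out["largest"] = largest  # type: ignore[assignment]
    return out


def effort_for_cv(cv_now: float, cv_target: float) -> float:
    """Effort multiplier to reach a target CV: precision improves as 1/sqrt(n).

    (cv_now / cv_target)^2; values below 1 mean the target is already met.
    """
    for cv in (cv_now, cv_target):
        if not (0.0 < cv <= 1.0):
            raise ValueError("CVs must lie in (0, 1]")
    return (cv_now / cv_target) ** 2
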
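"""Bayesian mixed-effects growth-curve fitting and model comparison.

Each lesion ``i`` in a cohort (homogeneous in lesion class and treatment
context) contributes log-volumes observed under multiplicative log-normal
noise around one of three growth laws:

* exponential: ``V = exp(beta + b_i) * exp((beta_r + b_ri) * t)``
* logistic:    ``V = (beta_K + b_Ki) / (1 + B * exp(-(beta_r + b_ri) * t))``
* linear:      ``V = (alpha + a_i) * t + (beta + b_i)``

Greek letters are fixed effects, ``b``/``a`` subscripted terms are
per-patient random effects, assumed independent Normal(0, sd) with
half-normal hyperpriors on their sds.  The logistic shape ``B`` carries a
fixed effect only (it is not identifiable per patient from short series).
Growth-rate priors are Normal(0.16, 0.14) for primary lesions and
Normal(0.58, 2.72) for metastases; capacity and ``B`` have diffuse
log-normal LN(0, 10) priors.

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme: the
per-patient random-effect blocks are conditionally independent given the
fixed effects, so they are proposed and accepted in parallel; fixed
effects, variance components and the residual sd get their own blocks.
Proposal scales adapt toward ~30% acceptance during warmup only, so the
post-warmup chain is a valid Markov chain.  Convergence is monitored with
split R-hat and effective sample size (arviz).

Model comparison uses AIC = 2k - 2 * log-likelihood evaluated at the
maximum-posterior sampled draw, with k counting fixed effects plus variance
components, so the three laws are ranked on one scale.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .growth import LesionClass, ModelKind, TreatmentContext, VolumeSeries
from .synthetic import NormalDist

__all__ = [
    "MixedEffectsSpec",
    "McmcOptions",
    "PosteriorSummary",
    "fit_mixed_model",
    "sample_prior",
    "select_model",
    "summarize_cohort",
    "rank_sum_comparisons",
    "RATE_PRIOR_PRIMARY",
    "RATE_PRIOR_METASTASIS",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

RATE_PRIOR_PRIMARY = NormalDist(0.16, 0.14)
RATE_PRIOR_METASTASIS = NormalDist(0.58, 2.72)

# Bounds stabilizing the logistic shape parameter B (fixed effect only).
_LOG_B_LO, _LOG_B_HI = math.log(1e-3), math.log(1e6)


@dataclass(frozen=True)
class MixedEffectsSpec:
    """Specification of one mixed-effects growth model.

    ``random_effect_scales`` are the half-normal hyperprior scales of the
    two per-patient random-effect sds, in the effect's own units (1/month
    for rates, cm^3 for capacity/intercept levels, cm^3/month for slopes).
    """

    model_kind: ModelKind
    rate_prior: NormalDist = RATE_PRIOR_PRIMARY
    capacity_log_prior_sd: float = 10.0
    shape_b_log_prior_sd: float = 10.0
    random_effect_scales: Tuple[float, float] = (1.0, 20.0)
    residual_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind(self.model_kind))
        if any(s <= 0 for s in self.random_effect_scales):
            raise ValueError("random_effect_scales must be positive")

    @classmethod
    def for_cohort(
        cls, model_kind: ModelKind, lesion_class: LesionClass
    ) -> "MixedEffectsSpec":
        """Default spec for a cohort of the given lesion class.

        Selects the growth-rate prior: N(0.16, 0.14) for primary lesions,
        N(0.58, 2.72) for metastases.
        """
        model_kind = ModelKind(model_kind)
        rate_prior = (
            RATE_PRIOR_PRIMARY
            if LesionClass(lesion_class) is LesionClass.PRIMARY
            else RATE_PRIOR_METASTASIS
        )
        if model_kind is ModelKind.LOGISTIC:
            scales = (1.0, 20.0)  # (rate effect, capacity effect cm^3)
        elif model_kind is ModelKind.EXPONENTIAL:
            scales = (1.0, 1.0)  # (log-intercept effect, rate effect)
        else:
            scales = (5.0, 20.0)  # (slope effect, intercept effect)
        return cls(model_kind=model_kind, rate_prior=rate_prior, random_effect_scales=scales)


@dataclass(frozen=True)
class McmcOptions:
    chains: int = 4
    iterations: int = 4000  # per chain, first half is warmup
    seed: int = 0

    @property
    def warmup(self) -> int:
        return self.iterations // 2


# --------------------------------------------------------------------------
# data container


class _CohortData:
    def __init__(self, cohort: Sequence[VolumeSeries]):
        if len(cohort) == 0:
            raise ValueError("cohort is empty")
        classes = {s.lesion_class for s in cohort}
        contexts = {s.context for s in cohort}
        if len(classes) > 1 or len(contexts) > 1:
            raise ValueError(
                "cohort must be homogeneous in lesion_class and context; "
                f"got {classes} / {contexts}"
            )
        for s in cohort:
            s.require_fittable()
        self.lesion_class = next(iter(classes))
        self.context = next(iter(contexts))
        self.patient_ids = [s.patient_id for s in cohort]
        self.n = len(cohort)
        self.t = np.concatenate([s.times for s in cohort])
        self.logv = np.log(np.concatenate([s.volumes for s in cohort]))
        self.pidx = np.concatenate(
            [np.full(s.n_scans, i, dtype=np.intp) for i, s in enumerate(cohort)]
        )
        self.n_per = np.bincount(self.pidx, minlength=self.n).astype(float)
        self.n_obs = int(self.t.size)
        h = hashlib.md5()
        h.update("|".join(self.patient_ids).encode())
        h.update(self.t.tobytes())
        h.update(self.logv.tobytes())
        self.key = h.hexdigest()


# --------------------------------------------------------------------------
# model-specific pieces

_FIXED_NAMES = {
    ModelKind.LOGISTIC: ("rate_fixed", "log_capacity_fixed", "log_shape_b"),
    ModelKind.EXPONENTIAL: ("log_intercept_fixed", "rate_fixed"),
    ModelKind.LINEAR: ("slope_fixed", "intercept_fixed"),
}

_RANEFF_NAMES = {
    ModelKind.LOGISTIC: ("rate", "capacity"),
    ModelKind.EXPONENTIAL: ("intercept_log", "rate"),
    ModelKind.LINEAR: ("slope", "intercept"),
}


def _ssr_per_patient(kind, fixed, raneff, data: _CohortData):
    """Sum of squared log-residuals per patient, with validity flags."""
    pidx = data.pidx
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if kind is ModelKind.LOGISTIC:
            rate_i = fixed[0] + raneff[:, 0]
            cap_i = math.exp(fixed[1]) + raneff[:, 1]
            b = math.exp(fixed[2])
            valid = cap_i > 0
            expo = np.exp(-rate_i[pidx] * data.t)
            logpred = np.log(np.maximum(cap_i[pidx], 1e-300)) - np.log1p(b * expo)
        elif kind is ModelKind.EXPONENTIAL:
            logpred = (fixed[0] + raneff[pidx, 0]) + (fixed[1] + raneff[pidx, 1]) * data.t
            valid = np.ones(data.n, dtype=bool)
        else:
            pred = (fixed[0] + raneff[pidx, 0]) * data.t + (fixed[1] + raneff[pidx, 1])
            bad = np.bincount(pidx, weights=(pred <= 0).astype(float), minlength=data.n)
            valid = bad == 0
            logpred = np.log(np.maximum(pred, 1e-300))
        resid = data.logv - logpred
        resid = np.where(np.isfinite(resid), resid, 1e6)
        ssr = np.bincount(pidx, weights=resid * resid, minlength=data.n)
    ssr = np.where(valid, ssr, np.inf)
    return ssr, valid


def _loglik_per_patient(ssr, n_per, sigma):
    return -n_per * (math.log(sigma) + _LOG_SQRT_2PI) - ssr / (2.0 * sigma**2)


def _norm_logpdf(x, mean, sd):
    return -_LOG_SQRT_2PI - math.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _fixed_log_prior(kind, fixed, spec: MixedEffectsSpec) -> float:
    if kind is ModelKind.LOGISTIC:
        if not (_LOG_B_LO <= fixed[2] <= _LOG_B_HI):
            return -np.inf
        return (
            _norm_logpdf(fixed[0], spec.rate_prior.mean, spec.rate_prior.sd)
            + _norm_logpdf(fixed[1], 0.0, spec.capacity_log_prior_sd)
            + _norm_logpdf(fixed[2], 0.0, spec.shape_b_log_prior_sd)
        )
    if kind is ModelKind.EXPONENTIAL:
        return _norm_logpdf(fixed[0], 0.0, 10.0) + _norm_logpdf(
            fixed[1], spec.rate_prior.mean, spec.rate_prior.sd
        )
    return _norm_logpdf(fixed[0], 0.0, 50.0) + _norm_logpdf(fixed[1], 0.0, 50.0)


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0) - _LOG_SQRT_2PI - math.log(scale) - 0.5 * (x / scale) ** 2


def _init_fixed(kind, data: _CohortData) -> np.ndarray:
    v0, vmax, slope = [], [], []
    for i in range(data.n):
        m = data.pidx == i
        t_i, lv_i = data.t[m], data.logv[m]
        v0.append(lv_i[0])
        vmax.append(lv_i.max())
        slope.append((lv_i[-1] - lv_i[0]) / max(t_i[-1], 1e-6))
    lv0, lvmax = float(np.mean(v0)), float(np.mean(vmax))
    sl = float(np.clip(np.mean(slope), -2.0, 2.0))
    if kind is ModelKind.LOGISTIC:
        log_k = lvmax + 0.3
        b = np.clip(math.exp(log_k - lv0) - 1.0, 0.3, 30.0)
        return np.array([max(sl, 0.05) if sl > -0.02 else sl, log_k, math.log(b)])
    if kind is ModelKind.EXPONENTIAL:
        return np.array([lv0, sl])
    vbar0 = float(np.mean(np.exp(np.asarray(v0))))
    return np.array([sl * vbar0, vbar0])


# --------------------------------------------------------------------------
# the sampler


def _run_chain(
    kind: ModelKind,
    spec: MixedEffectsSpec,
    data: Optional[_CohortData],
    n_patients: int,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
):
    """One adaptive Metropolis-within-Gibbs chain.

    With ``data=None`` the likelihood is identically zero and the chain
    samples the prior.
    """
    prior_only = data is None
    nf = len(_FIXED_NAMES[kind])
    n = n_patients

    if prior_only:
        fixed = np.zeros(nf)
        if kind is ModelKind.LOGISTIC:
            fixed[0] = spec.rate_prior.mean
        n_per = np.zeros(n)
    else:
        fixed = _init_fixed(kind, data)
        n_per = data.n_per
    fixed = fixed + 0.01 * rng.standard_normal(nf)
    raneff = np.zeros((n, 2))
    sds = 0.1 * np.asarray(spec.random_effect_scales, dtype=float)
    sigma = 0.2

    def ssr_of(fx, re):
        if prior_only:
            return np.zeros(n), np.ones(n, dtype=bool)
        return _ssr_per_patient(kind, fx, re, data)

    ssr, _ = ssr_of(fixed, raneff)

    # proposal scales
    s_ran = np.tile(0.1 * np.asarray(spec.random_effect_scales), (n, 1))
    s_fix = np.full(nf, 0.05)
    if kind is ModelKind.LOGISTIC and prior_only:
        s_fix = np.array([spec.rate_prior.sd, spec.capacity_log_prior_sd, 2.0])
    s_sd = np.full(2, 0.3)
    s_sig = 0.3
    # translation-move map: raneff column j <-> fixed index, log-stored flag
    if kind is ModelKind.LOGISTIC:
        trans_map = [(0, False), (1, True)]
    else:
        trans_map = [(0, False), (1, False)]
    s_trans = 0.3 * np.asarray(spec.random_effect_scales, dtype=float)
    acc_ran = np.zeros((n, 2))
    acc_fix = np.zeros(nf)
    acc_sd = np.zeros(2)
    acc_sig = 0.0
    acc_trans = np.zeros(2)
    window = 50
    # adaptive joint fixed-effect proposal from the warmup history
    hist_fix = np.empty((warmup, nf))
    chol_fix = None
    s_joint = 1.0
    acc_joint = 0.0
    t_char = 0.0 if prior_only else float(np.mean(data.t[data.t > 0])) if np.any(data.t > 0) else 0.0
    s_shape = 0.2
    acc_shape = 0.0

    keep = iterations - warmup
    out_fixed = np.empty((keep, nf))
    out_ran = np.empty((keep, n, 2))
    out_sds = np.empty((keep, 2))
    out_sigma = np.empty(keep)
    out_loglik = np.empty(keep)
    best_logpost = -np.inf
    best_loglik = -np.inf

    def loglik_total(ssr_vec, sig):
        if prior_only:
            return 0.0
        ll = _loglik_per_patient(ssr_vec, n_per, sig)
        return float(np.sum(ll))

    for it in range(iterations):
        # --- per-patient random effects, one column at a time -------------
        for j in (0, 1):
            prop = raneff.copy()
            prop[:, j] = raneff[:, j] + s_ran[:, j] * rng.standard_normal(n)
            ssr_p, _ = ssr_of(fixed, prop)
            d_lik = (
                np.zeros(n)
                if prior_only
                else (ssr - ssr_p) / (2.0 * sigma**2)
            )
            d_pri = (prop[:, j] ** 2 - raneff[:, j] ** 2) / (-2.0 * sds[j] ** 2)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(n)) < d_lik + d_pri
            accept &= np.isfinite(ssr_p) | np.isinf(ssr)
            raneff[accept, j] = prop[accept, j]
            ssr = np.where(accept, ssr_p, ssr)
            acc_ran[:, j] += accept

        # --- fixed effects (coordinate-wise random-walk) -------------------
        for jf in range(nf):
            prop_f = fixed.copy()
            prop_f[jf] += s_fix[jf] * rng.standard_normal()
            lp_prop = _fixed_log_prior(kind, prop_f, spec)
            if not np.isfinite(lp_prop):
                continue
            lp_cur = _fixed_log_prior(kind, fixed, spec)
            ssr_p, _ = ssr_of(prop_f, raneff)
            delta = (
                loglik_total(ssr_p, sigma)
                - loglik_total(ssr, sigma)
                + lp_prop
                - lp_cur
            )
            if math.log(rng.random()) < delta:
                fixed, ssr = prop_f, ssr_p
                acc_fix[jf] += 1

        # --- joint fixed-effect move with empirical proposal covariance ----
        if chol_fix is not None:
            prop_f = fixed + s_joint * (chol_fix @ rng.standard_normal(nf))
            lp_prop = _fixed_log_prior(kind, prop_f, spec)
            if np.isfinite(lp_prop):
                ssr_p, _ = ssr_of(prop_f, raneff)
                delta = (
                    loglik_total(ssr_p, sigma)
                    - loglik_total(ssr, sigma)
                    + lp_prop
                    - _fixed_log_prior(kind, fixed, spec)
                )
                if math.log(rng.random()) < delta:
                    fixed, ssr = prop_f, ssr_p
                    acc_joint += 1

        # --- shape/rate directional move (logistic): shift log B and
        # compensate the rate so B*exp(-r t) is unchanged at the central
        # observation time; targets their strong posterior correlation.
        if kind is ModelKind.LOGISTIC and t_char > 0:
            dlt = s_shape * rng.standard_normal()
            prop_f = fixed.copy()
            prop_f[2] += dlt
            prop_f[0] += dlt / t_char
            lp_prop = _fixed_log_prior(kind, prop_f, spec)
            if np.isfinite(lp_prop):
                ssr_p, _ = ssr_of(prop_f, raneff)
                delta = (
                    loglik_total(ssr_p, sigma)
                    - loglik_total(ssr, sigma)
                    + lp_prop
                    - _fixed_log_prior(kind, fixed, spec)
                )
                if math.log(rng.random()) < delta:
                    fixed, ssr = prop_f, ssr_p
                    acc_shape += 1

        # --- translation moves: shift a fixed effect and counter-shift its
        # random effects, leaving every patient-level parameter (hence the
        # likelihood) unchanged; breaks the fixed-vs-random degeneracy.
        for j, (jf, is_log) in enumerate(trans_map):
            if is_log:
                v = math.exp(fixed[jf])
                delta_v = s_trans[j] * rng.standard_normal()
                if v + delta_v <= 0:
                    continue
                new_stored = math.log(v + delta_v)
                # symmetric proposal in natural space: compare densities of
                # the natural variable (log-normal prior => -log v term)
                d_prior_f = (
                    _norm_logpdf(new_stored, 0.0, spec.capacity_log_prior_sd)
                    - new_stored
                    - _norm_logpdf(fixed[jf], 0.0, spec.capacity_log_prior_sd)
                    + fixed[jf]
                )
            else:
                delta_v = s_trans[j] * rng.standard_normal()
                new_stored = fixed[jf] + delta_v
                prop_f = fixed.copy()
                prop_f[jf] = new_stored
                d_prior_f = _fixed_log_prior(kind, prop_f, spec) - _fixed_log_prior(
                    kind, fixed, spec
                )
            b = raneff[:, j]
            d_prior_b = float(
                np.sum((b - delta_v) ** 2 - b**2) / (-2.0 * sds[j] ** 2)
            )
            if np.isfinite(d_prior_f) and math.log(rng.random()) < d_prior_f + d_prior_b:
                fixed[jf] = new_stored
                raneff[:, j] = b - delta_v
                acc_trans[j] += 1

        # --- random-effect sds (log-scale random walk) ---------------------
        for j in (0, 1):
            prop_sd = sds[j] * math.exp(s_sd[j] * rng.standard_normal())
            delta = (
                _half_normal_logpdf(prop_sd, spec.random_effect_scales[j])
                - _half_normal_logpdf(sds[j], spec.random_effect_scales[j])
                + n * math.log(sds[j] / prop_sd)
                + np.sum(raneff[:, j] ** 2) * (1 / sds[j] ** 2 - 1 / prop_sd**2) / 2
                + math.log(prop_sd / sds[j])  # Jacobian of log-scale proposal
            )
            if math.log(rng.random()) < delta:
                sds[j] = prop_sd
                acc_sd[j] += 1

        # --- residual sd ----------------------------------------------------
        prop_sig = sigma * math.exp(s_sig * rng.standard_normal())
        delta = (
            loglik_total(ssr, prop_sig)
            - loglik_total(ssr, sigma)
            + _half_normal_logpdf(prop_sig, spec.residual_sd_scale)
            - _half_normal_logpdf(sigma, spec.residual_sd_scale)
            + math.log(prop_sig / sigma)
        )
        if math.log(rng.random()) < delta:
            sigma = prop_sig
            acc_sig += 1

        # --- adaptation (warmup only) ---------------------------------------
        if it < warmup:
            hist_fix[it] = fixed
        if it < warmup and (it + 1) % window == 0:
            if it + 1 >= 300:
                sub = hist_fix[(it + 1) // 2 : it + 1]
                cov = np.cov(sub.T) + 1e-10 * np.eye(nf)
                try:
                    chol_fix = np.linalg.cholesky((2.38**2 / nf) * cov)
                except np.linalg.LinAlgError:
                    chol_fix = None
            if chol_fix is not None:
                s_joint = float(np.clip(s_joint * math.exp(acc_joint / window - 0.3), 1e-3, 10.0))
            acc_joint = 0.0
            s_shape = float(np.clip(s_shape * math.exp(acc_shape / window - 0.3), 1e-4, 10.0))
            acc_shape = 0.0
            s_ran *= np.exp((acc_ran / window - 0.3))
            np.clip(s_ran, 1e-6, 1e3, out=s_ran)
            s_fix *= np.exp((acc_fix / window - 0.35))
            np.clip(s_fix, 1e-6, 1e3, out=s_fix)
            s_sd *= np.exp((acc_sd / window - 0.3))
            np.clip(s_sd, 1e-3, 5.0, out=s_sd)
            s_sig = float(np.clip(s_sig * math.exp(acc_sig / window - 0.3), 1e-3, 5.0))
            s_trans *= np.exp((acc_trans / window - 0.3))
            np.clip(s_trans, 1e-8, 1e4, out=s_trans)
            acc_ran[:] = 0
            acc_fix[:] = 0
            acc_sd[:] = 0
            acc_sig = 0.0
            acc_trans[:] = 0

        ll = loglik_total(ssr, sigma)
        lpost = (
            ll
            + _fixed_log_prior(kind, fixed, spec)
            + float(
                np.sum(
                    -np.log(sds)[None, :]
                    - _LOG_SQRT_2PI
                    - raneff**2 / (2 * sds[None, :] ** 2)
                )
            )
            + _half_normal_logpdf(sds[0], spec.random_effect_scales[0])
            + _half_normal_logpdf(sds[1], spec.random_effect_scales[1])
            + _half_normal_logpdf(sigma, spec.residual_sd_scale)
        )
        if lpost > best_logpost:
            best_logpost = lpost
            best_loglik = ll
        if it >= warmup:
            k = it - warmup
            out_fixed[k] = fixed
            out_ran[k] = raneff
            out_sds[k] = sds
            out_sigma[k] = sigma
            out_loglik[k] = ll

    return {
        "fixed": out_fixed,
        "raneff": out_ran,
        "sds": out_sds,
        "sigma": out_sigma,
        "loglik": out_loglik,
        "best_logpost": best_logpost,
        "best_loglik": best_loglik,
    }


# --------------------------------------------------------------------------
# results


def _quartiles(draws: np.ndarray, axis=None):
    q1, med, q3 = np.percentile(draws, [25, 50, 75], axis=axis)
    return q1, med, q3


@dataclass
class PosteriorSummary:
    """Posterior of one mixed-effects growth-model fit.

    ``fixed`` is a table of fixed-effect summaries with diagnostics;
    ``per_patient`` holds per-lesion posterior median and quartiles of the
    patient-level parameters; ``draws`` keeps the raw (chain, draw) arrays
    for downstream sampling.
    """

    model_kind: ModelKind
    lesion_class: LesionClass
    context: TreatmentContext
    patient_ids: List[str]
    fixed: pd.DataFrame
    per_patient: pd.DataFrame
    draws: Dict[str, np.ndarray]
    aic: float
    max_loglik: float
    n_params: int
    n_obs: int
    converged: bool
    cohort_key: str

    def rhat_max(self) -> float:
        return float(self.fixed["rhat"].max())

    def to_parameter_table(self) -> pd.DataFrame:
        """Per-lesion parameter export (logistic fits only).

        Columns mirror the per-patient supplementary layout and double as
        the simulator's empirical-distribution import format.
        """
        if self.model_kind is not ModelKind.LOGISTIC:
            raise ValueError("parameter table export is defined for logistic fits")
        pp = self.per_patient
        b_med = float(np.median(np.exp(self.draws["log_shape_b"])))
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "lesion_class": self.lesion_class.value,
                "context": self.context.value,
                "rate_median": pp["rate_median"],
                "rate_q1": pp["rate_q1"],
                "rate_q3": pp["rate_q3"],
                "capacity_median": pp["capacity_median"],
                "capacity_q1": pp["capacity_q1"],
                "capacity_q3": pp["capacity_q3"],
                "B": b_med,
            }
        )


def _diagnostics(draws_2d: np.ndarray) -> Tuple[float, float]:
    """Split R-hat and bulk ESS for a (chain, draw) array via arviz.

    A single chain is split into two half-chains so the statistic is the
    usual split R-hat.
    """
    import arviz as az

    if draws_2d.shape[0] == 1:
        half = draws_2d.shape[1] // 2
        draws_2d = np.stack([draws_2d[0, :half], draws_2d[0, half : 2 * half]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(draws_2d))
        ess = float(az.ess(draws_2d))
    return rhat, ess


def fit_mixed_model(
    cohort: Sequence[VolumeSeries],
    spec: MixedEffectsSpec,
    mcmc: McmcOptions | Tuple[int, int, int] = McmcOptions(),
) -> PosteriorSummary:
    """Fit one mixed-effects growth law to a cohort by MCMC.

    The cohort must be homogeneous in lesion class and treatment context and
    every series must have >= 3 scans.  Deterministic given
    ``(seed, chains, iterations)``.  A fit whose fixed effects have split
    R-hat > 1.05 is returned flagged (``converged=False``) with a warning.
    """
    if not isinstance(mcmc, McmcOptions):
        mcmc = McmcOptions(*mcmc)
    data = _CohortData(cohort)
    kind = spec.model_kind
    chains = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, c]))
        chains.append(
            _run_chain(kind, spec, data, data.n, mcmc.iterations, mcmc.warmup, rng)
        )
    return _summarize(kind, spec, data, chains)


def sample_prior(
    spec: MixedEffectsSpec,
    n_draws: int = 4000,
    seed: int = 0,
    thin: int = 15,
) -> Dict[str, np.ndarray]:
    """Draws from the prior via the same sampler run with zero-length data.

    Returns flattened draw arrays keyed by fixed-effect name (thinned to
    reduce random-walk autocorrelation).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    warm = 1000
    iters = warm + n_draws * thin
    res = _run_chain(spec.model_kind, spec, None, 1, iters, warm, rng)
    names = _FIXED_NAMES[spec.model_kind]
    out = {}
    for j, name in enumerate(names):
        out[name] = res["fixed"][::thin, j][:n_draws]
    out["sigma"] = res["sigma"][::thin][:n_draws]
    return out


def _summarize(kind, spec, data: _CohortData, chains) -> PosteriorSummary:
    names = _FIXED_NAMES[kind]
    nf = len(names)
    fixed_d = np.stack([c["fixed"] for c in chains])  # (chain, draw, nf)
    ran_d = np.stack([c["raneff"] for c in chains])  # (chain, draw, n, 2)
    sds_d = np.stack([c["sds"] for c in chains])
    sig_d = np.stack([c["sigma"] for c in chains])
    ll_d = np.stack([c["loglik"] for c in chains])

    draws: Dict[str, np.ndarray] = {"sigma": sig_d, "loglik": ll_d}
    rows = []
    for j, name in enumerate(names):
        d = fixed_d[:, :, j]
        natural = d
        out_name = name
        if name == "log_capacity_fixed":
            natural = np.exp(d)
            out_name = "capacity_fixed"
        draws[name] = d
        if out_name != name:
            draws[out_name] = natural
        rhat, ess = _diagnostics(d)
        q1, med, q3 = _quartiles(natural.reshape(-1))
        rows.append(
            {"param": out_name, "median": med, "q1": q1, "q3": q3, "rhat": rhat, "ess": ess}
        )
    for j, nm in enumerate(("re_sd_1", "re_sd_2")):
        d = sds_d[:, :, j]
        draws[nm] = d
        rhat, ess = _diagnostics(d)
        q1, med, q3 = _quartiles(d.reshape(-1))
        rows.append({"param": nm, "median": med, "q1": q1, "q3": q3, "rhat": rhat, "ess": ess})
    rhat, ess = _diagnostics(sig_d)
    q1, med, q3 = _quartiles(sig_d.reshape(-1))
    rows.append({"param": "sigma", "median": med, "q1": q1, "q3": q3, "rhat": rhat, "ess": ess})
    fixed_table = pd.DataFrame(rows)

    # per-patient natural parameters
    re_names = _RANEFF_NAMES[kind]
    pp = {"patient_id": data.patient_ids}
    for j, re_name in enumerate(re_names):
        if kind is ModelKind.LOGISTIC:
            base = fixed_d[:, :, 0] if j == 0 else np.exp(fixed_d[:, :, 1])
        elif kind is ModelKind.EXPONENTIAL:
            base = fixed_d[:, :, j]
        else:
            base = fixed_d[:, :, j]
        per = base[:, :, None] + ran_d[:, :, :, j]  # (chain, draw, n)
        draws[f"per_patient_{re_name}"] = per
        q1, med, q3 = np.percentile(per.reshape(-1, data.n), [25, 50, 75], axis=0)
        pp[f"{re_name}_q1"] = q1
        pp[f"{re_name}_median"] = med
        pp[f"{re_name}_q3"] = q3
    per_patient = pd.DataFrame(pp)

    max_loglik = max(c["best_loglik"] for c in chains)
    k = nf + 3  # fixed effects + two random-effect sds + residual sd
    aic = 2 * k - 2 * max_loglik

    fixed_names_mask = fixed_table["param"].isin(
        {"rate_fixed", "capacity_fixed", "log_shape_b", "log_intercept_fixed",
         "slope_fixed", "intercept_fixed"}
    )
    converged = bool((fixed_table.loc[fixed_names_mask, "rhat"] <= 1.05).all())
    if not converged:
        warnings.warn(
            f"{kind.value} fit did not converge "
            f"(max fixed-effect R-hat {fixed_table['rhat'].max():.3f})",
            RuntimeWarning,
        )
    return PosteriorSummary(
        model_kind=kind,
        lesion_class=data.lesion_class,
        context=data.context,
        patient_ids=data.patient_ids,
        fixed=fixed_table,
        per_patient=per_patient,
        draws=draws,
        aic=float(aic),
        max_loglik=float(max_loglik),
        n_params=k,
        n_obs=data.n_obs,
        converged=converged,
        cohort_key=data.key,
    )


def select_model(
    fits: Mapping[str, PosteriorSummary] | Sequence[PosteriorSummary],
) -> pd.DataFrame:
    """Rank candidate growth-law fits of one cohort by AIC (ascending).

    All fits must be of the identical cohort.  Returns a table with columns
    model, k, loglik, aic, delta_aic.
    """
    if isinstance(fits, Mapping):
        items = [(name, f) for name, f in fits.items()]
    else:
        items = [(f.model_kind.value, f) for f in fits]
    if len(items) < 2:
        raise ValueError("need at least two candidate fits")
    keys = {f.cohort_key for _, f in items}
    if len(keys) > 1:
        raise ValueError("candidate fits are not of the identical cohort")
    rows = [
        {"model": name, "k": f.n_params, "loglik": f.max_loglik, "aic": f.aic}
        for name, f in items
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def rank_sum_comparisons(table: pd.DataFrame, value: str = "rate_median") -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney comparisons of per-patient estimates.

    ``table`` is a per-lesion parameter table with ``context`` and
    ``lesion_class`` columns; comparisons are across contexts within each
    lesion class.  Groups with fewer than 2 lesions are omitted with a
    warning.
    """
    from scipy.stats import mannwhitneyu

    rows = []
    for cls, sub in table.groupby("lesion_class"):
        groups = {ctx: g[value].to_numpy() for ctx, g in sub.groupby("context")}
        names = sorted(groups)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if len(groups[a]) < 2 or len(groups[b]) < 2:
                    warnings.warn(
                        f"comparison {a} vs {b} ({cls}) omitted: fewer than "
                        "2 lesions in a group"
                    )
                    continue
                res = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
                rows.append(
                    {
                        "lesion_class": cls,
                        "group_a": a,
                        "group_b": b,
                        "n_a": len(groups[a]),
                        "n_b": len(groups[b]),
                        "statistic": float(res.statistic),
                        "p_value": float(res.pvalue),
                    }
                )
    return pd.DataFrame(rows)


def summarize_cohort(
    fits: Union[PosteriorSummary, Sequence[PosteriorSummary]],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort summary table and cross-context rank-sum comparisons.

    For each fit (one homogeneous cohort), reports the median and quartiles
    across lesions of the per-patient posterior-median growth rate and
    capacity.  When several fits are given, growth rates are compared
    across treatment contexts within each lesion class by two-sided
    Mann-Whitney tests on the per-patient medians.
    """
    if isinstance(fits, PosteriorSummary):
        fits = [fits]
    summary_rows = []
    tables = []
    for f in fits:
        pp = f.per_patient.copy()
        rate_col = "rate_median" if "rate_median" in pp else "slope_median"
        row = {
            "context": f.context.value,
            "lesion_class": f.lesion_class.value,
            "model": f.model_kind.value,
            "n_lesions": len(pp),
        }
        q1, med, q3 = _quartiles(pp[rate_col].to_numpy())
        row.update(rate_median=med, rate_q1=q1, rate_q3=q3)
        if "capacity_median" in pp:
            q1, med, q3 = _quartiles(pp["capacity_median"].to_numpy())
            row.update(capacity_median=med, capacity_q1=q1, capacity_q3=q3)
        summary_rows.append(row)
        t = pp.rename(columns={rate_col: "rate_median"})[["patient_id", "rate_median"]]
        t["context"] = f.context.value
        t["lesion_class"] = f.lesion_class.value
        tables.append(t)
    summary = pd.DataFrame(summary_rows)
    comparisons = (
        rank_sum_comparisons(pd.concat(tables, ignore_index=True))
        if len(tables) > 1
        else pd.DataFrame()
    )
    return summary, comparisons
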
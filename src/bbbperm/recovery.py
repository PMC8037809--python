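"""Parameter-recovery experiments: the package's self-validation harness.

Each experiment generates data with a known truth through the synthetic
generators, runs the corresponding estimator, and summarises how well the
truth is recovered.  The defaults reproduce the measurement designs the
pipeline assumes: four eluent levels with triplicate measurements for the
chromatographic fits, and 30-compound training tables at the published
residual noise for the QSAR fits.  All experiments are deterministic given
their base seed (per-repetition seeds are ``base_seed + i``).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .exceptions import NonPhysicalFitError
from .foley import fit_foley
from .qsar import PREDICTORS, backward_eliminate, cross_validate_lto, fit_mlr
from .retention import build_series, fit_logk_series
from .simulate import (
    FoleySimSpec,
    QSARSimSpec,
    RetentionSimSpec,
    simulate_micellar,
    simulate_qsar_table,
    simulate_retention,
)

__all__ = [
    "logkw_recovery",
    "foley_recovery",
    "mlr_coefficient_bias",
    "elimination_rate",
    "rmsecv_recovery",
]


def logkw_recovery(
    n_seeds: int = 1000,
    noise_sd: float = 0.05,
    base_seed: int = 0,
    systems: tuple[str, ...] = ("IAM", "CHOL"),
) -> dict:
    """Mean recovered pure-water intercept vs truth for isocratic series.

    Simulates one series per seed and system at the four-level triplicate
    design, runs the standard pipeline (k-scale replicate averaging, OLS on
    log10 k) and returns the mean recovered intercept and its deviation from
    the generating logkw.
    """
    truth = {"IAM": (1.3, -3.0), "CHOL": (1.7, -3.5)}
    recovered, true_vals = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for system in systems:
            logkw_true, slope_true = truth[system]
            for i in range(n_seeds):
                spec = RetentionSimSpec(
                    logkw_true=logkw_true, slope_true=slope_true, noise_sd=noise_sd,
                    system=system, seed=base_seed + i,
                )
                (series,) = build_series(simulate_retention(spec))
                recovered.append(fit_logk_series(series).intercept)
                true_vals.append(logkw_true)
    recovered = np.asarray(recovered)
    bias = float(np.mean(recovered - np.asarray(true_vals)))
    return {"mean_bias": bias, "n_fits": len(recovered)}


def foley_recovery(
    n_seeds: int = 1000,
    noise_cv: float = 0.02,
    base_seed: int = 0,
    spec: FoleySimSpec | None = None,
) -> dict:
    """Median recovered K_MA over seeds vs the generating value.

    Uses the four-level triplicate micellar design with multiplicative noise
    on k.  The headline number is the relative error of the median estimate
    (the per-fit dispersion with only four levels is much larger than the
    bias; see the methods note).
    """
    spec = spec or FoleySimSpec(noise_cv=noise_cv)
    estimates = []
    n_nonphysical = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            sim = replace(spec, noise_cv=noise_cv, seed=base_seed + i)
            (series,) = build_series(simulate_micellar(sim), cmc=sim.cmc)
            try:
                estimates.append(fit_foley(series, phase_ratio=sim.phase_ratio).k_ma)
            except NonPhysicalFitError:
                # a noisy intercept can cross zero when b is small relative to
                # its standard error; rare at 2% noise, counted not imputed
                n_nonphysical += 1
    estimates = np.asarray(estimates)
    median = float(np.median(estimates))
    return {
        "median_k_ma": median,
        "true_k_ma": spec.k_ma_true,
        "median_rel_error_pct": 100.0 * abs(median - spec.k_ma_true) / spec.k_ma_true,
        "n_fits": len(estimates),
        "n_nonphysical": n_nonphysical,
    }


def mlr_coefficient_bias(
    n_sims: int = 1000, noise_sd: float = 0.436, base_seed: int = 0
) -> dict:
    """Monte-Carlo bias of the OLS coefficient estimates at the published noise.

    Returns per-term mean bias, the Monte-Carlo standard error of that mean,
    and their ratio (|bias|/SE <= 2 is the unbiasedness check).
    """
    terms = ("intercept", *PREDICTORS)
    draws = {t: [] for t in terms}
    for i in range(n_sims):
        table = simulate_qsar_table(QSARSimSpec(noise_sd=noise_sd, seed=base_seed + i))
        m = fit_mlr(table)
        draws["intercept"].append(m.intercept)
        draws["dlogp"].append(m.coef_dlogp)
        draws["lipophilicity"].append(m.coef_lipophilicity)
        draws["e"].append(m.coef_e)
    beta_true = dict(zip(terms, QSARSimSpec().beta_true))
    out = {}
    for t in terms:
        arr = np.asarray(draws[t])
        se = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        bias = float(arr.mean() - beta_true[t])
        out[t] = {"bias": bias, "mc_se": se, "abs_bias_over_se": abs(bias) / se}
    out["max_abs_bias_over_se"] = max(v["abs_bias_over_se"] for v in out.values()
                                      if isinstance(v, dict))
    out["n_sims"] = n_sims
    return out


def elimination_rate(
    n_seeds: int = 500,
    alpha: float = 0.01,
    noise_sd: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Fraction of seeds on which a planted zero-coefficient descriptor is removed.

    The dlogp coefficient is set to zero in the generator; the two signal
    descriptors keep their published coefficients.  A true-null descriptor
    survives elimination with probability ~alpha (its p-value is uniform
    under the null), so the removal rate directly measures 1 - alpha; the
    experiment also checks that no signal descriptor is ever removed.
    """
    removed = 0
    signal_lost = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            spec = QSARSimSpec(
                noise_sd=noise_sd, beta_true=(-0.114, 0.0, 0.278, 0.218),
                seed=base_seed + i,
            )
            m = backward_eliminate(simulate_qsar_table(spec), alpha=alpha)
            if m.coef_dlogp == 0.0:
                removed += 1
            if m.coef_lipophilicity == 0.0 or m.coef_e == 0.0:
                signal_lost += 1
    return {
        "removal_rate_pct": 100.0 * removed / n_seeds,
        "signal_loss_rate_pct": 100.0 * signal_lost / n_seeds,
        "alpha": alpha,
        "n_seeds": n_seeds,
    }


def rmsecv_recovery(
    n_repeats: int = 200, noise_sd: float = 0.436, seed: int = 0
) -> dict:
    """Mean leave-ten-out RMSECV vs the generating noise scale."""
    table = simulate_qsar_table(QSARSimSpec(noise_sd=noise_sd, seed=seed))
    rmsecv, r2cv, press = cross_validate_lto(table, seed=seed, n_repeats=n_repeats)
    return {
        "mean_rmsecv": rmsecv,
        "generating_sd": noise_sd,
        "rel_error_pct": 100.0 * abs(rmsecv - noise_sd) / noise_sd,
        "r_squared_cv": r2cv,
        "press": press,
        "n_repeats": n_repeats,
    }
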
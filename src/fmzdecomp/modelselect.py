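"""Model comparison, sanity checks and selection of a preferred model.

Candidate configurations are compared on goodness of fit (SSR, MSE,
least-squares AIC, pairwise extra-sum-of-squares F-tests between nested
pairs) and on sanity/generalizability checks: the percentage of
fraction parameters fitted to zero (overfit indicator), the stability
of fractions under leave-one-subject-per-arm cross-validation, and the
left-right asymmetry of the resulting component maps (overall binding
is known to be hemispherically symmetric, so plausible components
should be too).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import ElementMap, Geometry
from .occmodel import FitOptions, FitResult, ModelConfig, fit_model
from .preprocess import OccupancyDataset
from .synth import StudyDesign

logger = logging.getLogger(__name__)

ZERO_TOL = 1e-6


def goodness_of_fit(fit: FitResult) -> tuple[float, float, float]:
    """(SSR, MSE, AIC) with the least-squares AIC form
    ``n ln(SSR/n) + 2p``.  A perfect fit (SSR = 0) yields AIC = -inf."""
    if fit.n_obs <= fit.n_par:
        raise ValueError(
            f"saturated model: n_obs ({fit.n_obs}) must exceed n_par ({fit.n_par})"
        )
    mse = fit.ssr / fit.n_obs
    if fit.ssr <= 0:
        warnings.warn("perfect fit (SSR = 0); AIC reported as -inf", stacklevel=2)
        aic = float("-inf")
    else:
        aic = fit.n_obs * float(np.log(mse)) + 2 * fit.n_par
    return fit.ssr, mse, aic


def f_test(simple: FitResult, complex_: FitResult) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares F-test between nested fits.

    F = [(SSR_s - SSR_c) / (p_c - p_s)] / [SSR_c / (n - p_c)], compared
    against F(p_c - p_s, n - p_c).  A negative numerator (the complex
    model fits worse) is reported as-is with p = 1 and a warning.
    """
    if simple.n_obs != complex_.n_obs:
        raise ValueError("fits are not on the same dataset (n_obs differs)")
    df1 = complex_.n_par - simple.n_par
    if df1 <= 0:
        raise ValueError("not a nested pair: the simple fit must have fewer parameters")
    df2 = complex_.n_obs - complex_.n_par
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for the complex fit")
    fstat = ((simple.ssr - complex_.ssr) / df1) / (complex_.ssr / df2)
    if fstat < 0:
        warnings.warn(
            f"complex model {complex_.config.name} fits worse than {simple.config.name}",
            stacklevel=2,
        )
        p = 1.0
    else:
        p = float(stats.f.sf(fstat, df1, df2))
    return float(fstat), df1, df2, p


def zero_fraction(fit: FitResult, tol: float = ZERO_TOL) -> float:
    """Percent of fitted fractional-contribution parameters at zero."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    return 100.0 * float((fit.fractions <= tol).mean())


def cv_folds(design: StudyDesign) -> list[tuple[str, str]]:
    """All leave-one-subject-per-arm exclusion pairs (arm A x arm B)."""
    arms = design.drugs
    if len(arms) != 2:
        raise ValueError("cross-validation requires exactly two drug arms")
    sa, sb = (design.subjects_in_arm(d) for d in arms)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each arm needs >= 2 subjects for leave-one-per-arm CV")
    return [(a, b) for a in sa for b in sb]


@dataclass
class CVFold:
    excluded: tuple[str, str]
    fit: FitResult
    median_abs_diff: float


def cross_validate(
    config: ModelConfig,
    dataset: OccupancyDataset,
    design: StudyDesign | None = None,
    full_fit: FitResult | None = None,
    options: FitOptions | None = None,
) -> tuple[list[CVFold], float]:
    """Leave-one-subject-per-arm cross-validation of a configuration.

    Every (arm A subject, arm B subject) pair is excluded in turn and
    the full model (global K_i and all cluster fractions) is refitted on
    the remainder.  Stability index: the median of |f_cv - f_full| over
    all folds, clusters and components.
    """
    design = design or dataset.design
    folds = cv_folds(design)
    if full_fit is None:
        full_fit = fit_model(config, dataset, options)
    # start each refit from the full-model optimum (initialization only)
    fold_opts = FitOptions(**{**(options.__dict__ if options else FitOptions().__dict__)})
    fold_opts.theta0 = full_fit.theta
    fold_opts.n_starts = 1

    records: list[CVFold] = []
    diffs: list[np.ndarray] = []
    for pair in folds:
        sub = dataset.drop_subjects(set(pair))
        fit = fit_model(config, sub, fold_opts)
        d = np.abs(fit.fractions - full_fit.fractions)
        records.append(CVFold(pair, fit, float(np.median(d))))
        diffs.append(d.ravel())
    overall = float(np.median(np.concatenate(diffs)))
    return records, overall


def asymmetry(
    component_map: ElementMap, geometry: Geometry | None = None
) -> tuple[dict[int, float], float]:
    """Left-right regional asymmetry of a map, in percent of the mean.

    For every mirrored region pair, 100 |L - R| / ((L + R)/2) of the
    regional mean values; the overall index is the median across region
    pairs.  A pair with L = R = 0 contributes 0.
    """
    geo = geometry or component_map.geometry
    per_region: dict[int, float] = {}
    for rid in geo.region_ids:
        sel_l = (geo.regions == rid) & (geo.hemispheres < 0) & component_map.mask
        sel_r = (geo.regions == rid) & (geo.hemispheres > 0) & component_map.mask
        if not sel_l.any() or not sel_r.any():
            raise ValueError(f"region {int(rid)} is unpaired across hemispheres")
        lv = float(component_map.data[sel_l].mean())
        rv = float(component_map.data[sel_r].mean())
        mean = 0.5 * (lv + rv)
        per_region[int(rid)] = 0.0 if mean == 0 else 100.0 * abs(lv - rv) / abs(mean)
    return per_region, float(np.median(list(per_region.values())))


def fit_asymmetry(fit: FitResult, clusters, geometry: Geometry) -> float:
    """Median regional asymmetry pooled over all component maps of a fit
    (nearest-neighbour projection of cluster fractions to elements)."""
    from .maps import interpolate_to_elements

    cmaps = interpolate_to_elements(fit, clusters, mode="nearest")
    pcts: list[float] = []
    for k in range(fit.config.n_components):
        per_region, _ = asymmetry(cmaps.fraction_map(k + 1), geometry)
        pcts.extend(per_region.values())
    return float(np.median(pcts))


# ---------------------------------------------------------------------------
# Selection


@dataclass
class ConfigReport:
    config: ModelConfig
    fit: FitResult
    ssr: float
    mse: float
    aic: float
    zero_percent: float
    cv_median_abs_diff: float
    asymmetry_percent: float


@dataclass
class SelectionReport:
    configs: list[ConfigReport]
    f_table: pd.DataFrame  # simple, complex, F, df1, df2, p
    selected: str
    alpha: float
    warnings: list[str] = field(default_factory=list)

    def metrics_table(self) -> pd.DataFrame:
        rows = [
            {
                "config": r.config.name,
                "n_par": r.fit.n_par,
                "ssr": r.ssr,
                "mse": r.mse,
                "aic": r.aic,
                "zero_percent": r.zero_percent,
                "cv_median_abs_diff": r.cv_median_abs_diff,
                "asymmetry_percent": r.asymmetry_percent,
            }
            for r in self.configs
        ]
        return pd.DataFrame(rows).set_index("config")


def select_model(reports: list[ConfigReport], alpha: float = 0.05) -> tuple[str, pd.DataFrame, list[str]]:
    """Deterministic composite selection rule.

    F-test gate: a configuration survives only if it significantly
    improves on every nested simpler candidate (p < alpha); the simplest
    candidates pass vacuously.  Among survivors the configuration with
    the best mean rank across AIC, CV stability, zero-parameter
    percentage and asymmetry wins; ties break toward fewer components,
    then fewer parameters.  A complex configuration that wins its
    F-tests can still lose the rank stage on the sanity checks — the
    guard against overfitted variants.
    """
    if not reports:
        raise ValueError("no fitted configurations to select from")
    notes: list[str] = []
    f_rows = []
    by_name = {r.config.name: r for r in reports}
    names = list(by_name)
    beats: dict[tuple[str, str], bool] = {}
    for rs in reports:
        for rc in reports:
            if rc.fit.n_par > rs.fit.n_par:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fstat, df1, df2, p = f_test(rs.fit, rc.fit)
                f_rows.append(
                    {"simple": rs.config.name, "complex": rc.config.name,
                     "F": fstat, "df1": df1, "df2": df2, "p": p}
                )
                beats[(rc.config.name, rs.config.name)] = p < alpha
    f_table = pd.DataFrame(f_rows, columns=["simple", "complex", "F", "df1", "df2", "p"])

    survivors = []
    for name in names:
        r = by_name[name]
        wins_all_simpler = all(
            beats[(name, other)]
            for other in names
            if by_name[other].fit.n_par < r.fit.n_par
        )
        if wins_all_simpler:
            survivors.append(r)

    if not survivors:
        simplest = min(reports, key=lambda r: (r.fit.n_par, r.config.name))
        notes.append(
            "no configuration passed the F-test gate; falling back to the "
            f"simplest candidate {simplest.config.name}"
        )
        logger.warning(notes[-1])
        return simplest.config.name, f_table, notes

    if len(survivors) == 1:
        return survivors[0].config.name, f_table, notes

    metric_cols = [
        [r.aic for r in survivors],
        [r.cv_median_abs_diff for r in survivors],
        [r.zero_percent for r in survivors],
        [r.asymmetry_percent for r in survivors],
    ]
    ranks = np.mean([stats.rankdata(col) for col in metric_cols], axis=0)
    order = sorted(
        range(len(survivors)),
        key=lambda i: (
            ranks[i],
            survivors[i].config.n_components,
            survivors[i].fit.n_par,
            survivors[i].config.name,
        ),
    )
    return survivors[order[0]].config.name, f_table, notes


def evaluate_configs(
    configs: list[ModelConfig],
    dataset: OccupancyDataset,
    geometry: Geometry,
    alpha: float = 0.05,
    with_cv: bool = True,
    with_asymmetry: bool = True,
    options: FitOptions | None = None,
) -> SelectionReport:
    """Fit, score and select among candidate configurations."""
    reports: list[ConfigReport] = []
    for cfg in configs:
        fit = fit_model(cfg, dataset, options)
        ssr, mse, aic = goodness_of_fit(fit)
        zp = zero_fraction(fit)
        cv_med = float("nan")
        if with_cv:
            _, cv_med = cross_validate(cfg, dataset, full_fit=fit, options=options)
        asym = float("nan")
        if with_asymmetry:
            asym = fit_asymmetry(fit, dataset.clusters, geometry)
        reports.append(ConfigReport(cfg, fit, ssr, mse, aic, zp, cv_med, asym))
        logger.info(
            "config %s: SSR %.4g AIC %.4g zero%% %.2f CV %.4g asym%% %.3g",
            cfg.name, ssr, aic, zp, cv_med, asym,
        )
    selected, f_table, notes = select_model(reports, alpha=alpha)
    return SelectionReport(reports, f_table, selected, alpha, notes)
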
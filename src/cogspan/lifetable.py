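"""Multistate life tables: life expectancy with and without impairment.

State-specific life expectancy from start state r at age a is

    e_rs(a) = integral over u in [a, omega] of P_rs(a, u) du,

with omega = 110 the assumed maximum human age, evaluated by composite
midpoint (default) or Simpson quadrature on an annual or monthly grid.
Marginal life expectancy weights the start states by their prevalence at a.
Uncertainty comes from a percentile bootstrap that resamples subjects with
replacement and refits the transition model per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import occupancy_grid
from .markov import (CH, CI, GompertzMultistateModel, TransitionParams,
                     _as_z, prepare_panel)

STATE_NAMES = ("CH", "CI")


@dataclass
class LifeExpectancyEstimate:
    """Expected years in each living state from each living start state.

    ``e[r, s]`` is the expected time in state s (0=CH, 1=CI) between
    ``start_age`` and ``omega`` for a subject in state r at ``start_age``.
    """

    start_age: float
    omega: float
    e: np.ndarray              # (2, 2) years
    method: str
    step: float
    ci: dict = field(default_factory=dict)

    @property
    def e_total(self):
        return self.e.sum(axis=1)

    @property
    def proportion_ch(self):
        return self.e[:, 0] / self.e_total

    def as_series(self):
        out = {}
        for r, rn in enumerate(STATE_NAMES):
            for s, sn in enumerate(STATE_NAMES):
                out[f"e_{rn}_{sn}"] = self.e[r, s]
            out[f"e_{rn}_total"] = self.e_total[r]
            out[f"proportion_CH_from_{rn}"] = self.proportion_ch[r]
        return pd.Series(out)


@dataclass
class MarginalLifeExpectancy:
    """Start-state prevalence-weighted life expectancies at one age."""

    start_age: float
    weights: tuple
    e_ch: float
    e_ci: float

    @property
    def total(self):
        return self.e_ch + self.e_ci


def _resolve(model, profile, z):
    """Accept either a fitted estimator (+ attribute profile) or raw
    TransitionParams (+ design vector z)."""
    if isinstance(model, TransitionParams):
        return model, _as_z(z, model.n_covariates)
    if isinstance(model, GompertzMultistateModel):
        model._check_fitted()
        return model.params_, model.encode_profile(profile)
    raise TypeError("model must be a fitted GompertzMultistateModel or "
                    "TransitionParams")


def state_specific_le(model, profile=None, age=65.0, method="midpoint",
                      step=1.0, omega=110.0, z=None):
    """Life-table life expectancy by start and occupied state.

    The occupancy probabilities P(a, u) are evaluated on a half-step grid
    (piecewise-constant intensities, midpoint evaluation) so that the same
    product chain supports both midpoint values (cell centres) and Simpson
    node values (cell edges); e_r_total = e_r,CH + e_r,CI holds exactly
    because the two states share one quadrature.
    """
    if age >= omega:
        raise ValueError(f"start age {age} must be below the horizon {omega}")
    if method not in ("midpoint", "simpson"):
        raise ValueError("method must be 'midpoint' or 'simpson'")
    params, zz = _resolve(model, profile, z)
    n_cells = int(np.ceil((omega - age) / step - 1e-9))
    h = (omega - age) / n_cells
    grid = occupancy_grid(params.to_vector(), params.n_covariates, zz,
                          float(age), float(omega), h / 2.0,
                          params.reference_age)
    if method == "midpoint":
        e = h * grid[1::2].sum(axis=0)
    else:
        nodes = grid[::2]                      # n_cells + 1 edge values
        npanel = n_cells if n_cells % 2 == 0 else n_cells - 1
        e = np.zeros((2, 2))
        for k in range(0, npanel, 2):
            e += (h / 3.0) * (nodes[k] + 4.0 * nodes[k + 1] + nodes[k + 2])
        if npanel < n_cells:                   # odd final panel: trapezoid
            e += (h / 2.0) * (nodes[-2] + nodes[-1])
    return LifeExpectancyEstimate(start_age=float(age), omega=float(omega),
                                  e=e, method=method, step=float(step))


def marginal_le(model, weights, profile=None, age=65.0, method="midpoint",
                step=1.0, omega=110.0, z=None):
    """Prevalence-weighted life expectancy: e_s(a) = sum_r pi_r e_rs(a)."""
    pi = np.asarray(weights, dtype=float)
    if pi.shape != (2,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be two nonnegative numbers summing to 1")
    est = state_specific_le(model, profile, age, method, step, omega, z)
    return MarginalLifeExpectancy(
        start_age=float(age), weights=tuple(pi),
        e_ch=float(pi @ est.e[:, 0]), e_ci=float(pi @ est.e[:, 1]))


def prevalence_weights(panel, age, id_col="subject_id", age_col="age",
                       state_col="state"):
    """Start-state weights (pi_CH, pi_CI) at an age, from a logistic model
    of the baseline living state on baseline age."""
    import statsmodels.api as sm
    clean, _ = prepare_panel(panel, id_col, age_col, state_col)
    base = clean.groupby(id_col, sort=False).head(1)
    base = base[base[state_col].isin((CH, CI))]
    y = (base[state_col] == CI).astype(float).to_numpy()
    X = sm.add_constant(base[age_col].to_numpy(dtype=float))
    if y.min() == y.max():  # degenerate: single observed baseline state
        p = float(y.mean())
    else:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        p = float(res.predict(np.array([[1.0, age]]))[0])
    return (1.0 - p, p)


# ---------------------------------------------------------------------------
# contrasts and grids
# ---------------------------------------------------------------------------

def compare_groups(est_a: LifeExpectancyEstimate, est_b: LifeExpectancyEstimate):
    """Absolute (years) and relative (%) LE differences, group a minus b.

    Percent differences are relative to group b:  100 * (a - b) / b.
    """
    for attr in ("start_age", "method", "step", "omega"):
        if getattr(est_a, attr) != getattr(est_b, attr):
            raise ValueError(f"estimates differ in {attr}; not comparable")
    rows = []
    sa, sb = est_a.as_series(), est_b.as_series()
    for name in sa.index:
        if name.startswith("proportion"):
            continue
        delta = sa[name] - sb[name]
        rows.append({"quantity": name, "group_a": sa[name],
                     "group_b": sb[name], "delta_years": delta,
                     "percent": 100.0 * delta / sb[name] if sb[name] else np.nan})
    return pd.DataFrame(rows).set_index("quantity")


def le_grid(models, profiles, ages=(65.0, 75.0, 85.0), method="midpoint",
            step=1.0, omega=110.0):
    """Long-format LE table over profiles x ages (Figure-style output).

    Parameters
    ----------
    models : fitted model or {stratum_label: fitted model}
        Sex-stratified fits are passed as a mapping; profiles are evaluated
        under every stratum model.
    profiles : sequence of dict
        Attribute profiles (e.g. ``{"apoe": "e4", "lifestyle": "g45"}``).

    Failed cells are logged via warnings and skipped, never aborting the
    rest of the grid.
    """
    if not isinstance(models, dict):
        models = {"all": models}
    rows = []
    for stratum, model in models.items():
        for prof in profiles:
            for age in ages:
                try:
                    est = state_specific_le(model, prof, age, method, step,
                                            omega)
                except Exception as exc:  # noqa: BLE001 - per-cell isolation
                    warnings.warn(f"LE cell failed (stratum={stratum}, "
                                  f"profile={prof}, age={age}): {exc}")
                    continue
                base = {"stratum": stratum, **prof, "age": age,
                        "method": method, "step": step}
                rows.append(base | {"state": "CH", "estimate": est.e[0, 0]})
                rows.append(base | {"state": "CI", "estimate": est.e[0, 1]})
                rows.append(base | {"state": "TOTAL",
                                    "estimate": est.e_total[0],
                                    "proportion_ch": est.proportion_ch[0]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap of life expectancies.

    ``replicates`` holds one row per successful replicate with a column per
    (profile, age, quantity); ``lo``/``hi`` are the 2.5/97.5 percentiles.
    """

    B: int
    seed: int
    point: pd.Series
    replicates: pd.DataFrame
    lo: pd.Series
    hi: pd.Series
    n_failed: int
    unreliable: bool


def _le_quantities(model, profiles, ages, method, step, omega):
    out = {}
    for label, prof in profiles.items():
        for age in ages:
            est = state_specific_le(model, prof, age, method, step, omega)
            out[f"{label}|{age:g}|e_CH"] = est.e[0, 0]
            out[f"{label}|{age:g}|e_CI"] = est.e[0, 1]
            out[f"{label}|{age:g}|total"] = est.e_total[0]
    return pd.Series(out)


def bootstrap_le(panel, model: GompertzMultistateModel, profiles=None,
                 ages=(65.0,), B=1000, seed=0, method="midpoint", step=1.0,
                 omega=110.0, id_col="subject_id"):
    """Subject-level percentile bootstrap of life expectancies.

    Subjects are resampled with replacement; the model is refitted on each
    replicate (warm-started at the full-data MLE) and the LE quantities are
    recomputed.  Non-converged or failing replicates are dropped and
    counted; more than 5 % failures flags the result unreliable.
    Deterministic for a given seed.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    profiles = profiles if profiles is not None else {"reference": {}}
    fitted = model if hasattr(model, "params_") else model.fit(panel)
    theta_hat = fitted._theta_.copy()
    point = _le_quantities(fitted, profiles, ages, method, step, omega)
    z_by_profile = {label: fitted.encode_profile(prof)
                    for label, prof in profiles.items()}
    p = len(fitted.design_columns_)
    a0 = fitted.reference_age

    # the likelihood is a sum over per-subject pair blocks, so resampling
    # subjects is exactly resampling their (contiguous) pair rows
    from .markov import _pair_arrays, build_design
    clean, _ = prepare_panel(panel, id_col, fitted.age_col, fitted.state_col)
    first = clean.groupby(id_col, sort=False).head(1)
    design = build_design(first, fitted.covariates, fitted.interactions)[
        list(fitted.design_columns_)] if p else pd.DataFrame(index=first.index)
    a1, a2, sf, st, Z = _pair_arrays(clean, design, id_col, fitted.age_col,
                                     fitted.state_col)
    sizes = clean.groupby(id_col, sort=False).size().to_numpy() - 1
    stops = np.cumsum(sizes)
    starts = stops - sizes
    n_subj = len(sizes)

    rng = np.random.default_rng(seed)
    rows, n_failed = [], 0
    template = clone_model(fitted)
    for _ in range(B):
        pick = rng.integers(0, n_subj, size=n_subj)
        rows_idx = np.concatenate(
            [np.arange(starts[i], stops[i]) for i in pick])
        try:
            theta, res, _, _, _ = template._fit_arrays(
                a1[rows_idx], a2[rows_idx], sf[rows_idx], st[rows_idx],
                np.ascontiguousarray(Z[rows_idx]), p, theta_hat.copy())
            if not (res.success or np.linalg.norm(res.jac) <= 10 * template.gtol):
                raise RuntimeError("replicate did not converge")
            params = TransitionParams.from_vector(
                theta, p, a0, fitted.design_columns_)
            out = {}
            for label in profiles:
                for age in ages:
                    est = state_specific_le(params, z=z_by_profile[label],
                                            age=age, method=method,
                                            step=step, omega=omega)
                    out[f"{label}|{age:g}|e_CH"] = est.e[0, 0]
                    out[f"{label}|{age:g}|e_CI"] = est.e[0, 1]
                    out[f"{label}|{age:g}|total"] = est.e_total[0]
            rows.append(pd.Series(out))
        except Exception:  # noqa: BLE001 - failed replicates are counted
            n_failed += 1
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise RuntimeError("all bootstrap replicates failed")
    lo = reps.quantile(0.025)
    hi = reps.quantile(0.975)
    unreliable = n_failed > 0.05 * B
    if unreliable:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed; "
                      "intervals flagged unreliable")
    return BootstrapResult(B=B, seed=seed, point=point, replicates=reps,
                           lo=lo, hi=hi, n_failed=n_failed,
                           unreliable=unreliable)


def clone_model(model: GompertzMultistateModel):
    """Fresh unfitted estimator with the same settings, configured to skip
    the Hessian (bootstrap replicates only need point estimates)."""
    settings = model.get_params(deep=False)
    settings["hessian"] = False
    return GompertzMultistateModel(**settings)
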
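"""Continuous-time three-state Markov model of cognitive ageing.

States are CH (cognitively healthy), CI (cognitively impaired) and DEAD,
with the four transitions CH->CI, CH->DEAD, CI->CH, CI->DEAD.  Each
transition intensity is Gompertz in age with proportional covariate effects:

    q_rs(a, z) = exp(alpha_rs + xi_rs * (a - a0) + beta_rs' z)

Living states are observed only at interview ages (interval censoring);
death ages are exact.  The model is fitted by maximum likelihood on the
panel of consecutive observation pairs, with transition probabilities
computed under piecewise-constant intensities (midpoint evaluation on a
configurable age grid, 1 year by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from ._kernels import (interval_pll, occupancy_grid, panel_loglik,
                       panel_loglik_grad, _rates)

CH, CI, DEAD = 1, 2, 3
_STATE_CODES = {"CH": CH, "CI": CI, "DEAD": DEAD, 1: CH, 2: CI, 3: DEAD}

#: allowed transitions, in the fixed parameter order
TRANSITIONS = ((CH, CI), (CH, DEAD), (CI, CH), (CI, DEAD))
TRANSITION_LABELS = ("CH->CI", "CH->Death", "CI->CH", "CI->Death")

#: categorical covariates with their level order; the first level is the
#: reference and encodes to all-zero dummies
CATEGORIES = {
    "apoe": ("e3e3", "e2", "e4"),
    "lifestyle": ("g01", "g23", "g45"),
    "hli_tertile": ("LOW", "MID", "HIGH"),
    "sex": ("woman", "man"),
    "residence": ("rural", "urban"),
    "schooling": ("never", "1-6", "6plus"),
    "living_arrangement": ("with_family", "alone"),
    "marital_status": ("not_married", "married"),
    "comorbidity": ("none", "one", "comorbidity"),
    "disabled": (False, True),
    "pension": (False, True),
    "insurance": (False, True),
    "hospital_access": (False, True),
}


class PanelDataError(ValueError):
    """Raised when panel observations violate the data contract."""


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _dummy_columns(var):
    """(column name, level) pairs for the non-reference levels of ``var``."""
    if var not in CATEGORIES:
        return [(var, None)]  # numeric / already-binary column
    levels = CATEGORIES[var]
    return [(f"{var}_{lev}".lower(), lev) for lev in levels[1:]]


def design_columns(covariates=(), interactions=()):
    """Ordered design column names for a covariate + interaction spec."""
    cols = []
    for var in covariates:
        cols.extend(name for name, _ in _dummy_columns(var))
    for va, vb in interactions:
        for na, _ in _dummy_columns(va):
            for nb, _ in _dummy_columns(vb):
                cols.append(f"{na}:{nb}")
    return cols


def build_design(profiles, covariates=(), interactions=()):
    """Encode subject attributes into a model design matrix.

    Parameters
    ----------
    profiles : DataFrame (or Series/dict for a single subject)
        One row per subject with the raw attribute columns named in
        ``covariates`` (e.g. ``apoe``, ``lifestyle``, ``sex``).
    covariates, interactions : sequences
        Main-effect variable names and pairs of variable names whose
        dummy products form interaction columns.

    The reference profile (first level of every categorical) encodes to the
    all-zero vector; interaction columns are products of parent dummies.
    """
    single = isinstance(profiles, (dict, pd.Series))
    df = pd.DataFrame([profiles]) if single else pd.DataFrame(profiles)
    for var in set(covariates) | {v for pair in interactions for v in pair}:
        if var not in df.columns:
            raise KeyError(
                f"unknown design variable {var!r}; available: {sorted(df.columns)}"
            )
        if var in CATEGORIES:
            bad = set(df[var].dropna()) - set(CATEGORIES[var])
            if bad:
                raise ValueError(
                    f"unknown level(s) {sorted(map(str, bad))} for {var!r}; "
                    f"expected {CATEGORIES[var]}"
                )
    out = pd.DataFrame(index=df.index)
    for var in covariates:
        for name, lev in _dummy_columns(var):
            out[name] = (
                df[var].astype(float)
                if lev is None
                else (df[var] == lev).astype(float)
            )
    for va, vb in interactions:
        for na, la in _dummy_columns(va):
            for nb, lb in _dummy_columns(vb):
                da = df[va].astype(float) if la is None else (df[va] == la).astype(float)
                db = df[vb].astype(float) if lb is None else (df[vb] == lb).astype(float)
                out[f"{na}:{nb}"] = da * db
    return out


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class TransitionParams:
    """Parameters of the four Gompertz transition intensities.

    alpha : log baseline intensity at the reference age, per transition
    xi    : Gompertz slope per year of age, per transition
    beta  : (4, p) covariate log hazard ratios, per transition
    """

    alpha: np.ndarray
    xi: np.ndarray
    beta: np.ndarray
    reference_age: float = 65.0
    covariate_names: tuple = ()

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.beta.size == 0:
            self.beta = np.zeros((4, 0))
        if self.alpha.shape != (4,) or self.xi.shape != (4,):
            raise ValueError("alpha and xi must each have one entry per transition")
        if self.beta.shape[0] != 4:
            raise ValueError("beta must have one row per transition")
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.xi))
                and np.all(np.isfinite(self.beta))):
            raise ValueError("transition parameters must be finite")

    @property
    def n_covariates(self):
        return self.beta.shape[1]

    def to_vector(self):
        return np.concatenate([self.alpha, self.xi, self.beta.ravel()])

    @classmethod
    def from_vector(cls, theta, n_covariates, reference_age=65.0, covariate_names=()):
        theta = np.asarray(theta, dtype=float)
        p = n_covariates
        return cls(
            alpha=theta[0:4],
            xi=theta[4:8],
            beta=theta[8:].reshape(4, p) if p else np.zeros((4, 0)),
            reference_age=reference_age,
            covariate_names=tuple(covariate_names),
        )


def _as_z(z, p):
    if z is None:
        return np.zeros(p)
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != p:
        raise ValueError(f"covariate vector has length {z.shape[0]}, expected {p}")
    return z


def intensity_matrix(age, z, params: TransitionParams):
    """3x3 generator Q(age, z): rows sum to zero, death row is zero."""
    if not np.isfinite(age):
        raise ValueError("age must be finite")
    z = _as_z(z, params.n_covariates)
    q = _rates(params.to_vector(), params.n_covariates, float(age), z,
               params.reference_age)
    Q = np.zeros((3, 3))
    Q[0, 1], Q[0, 2] = q[0], q[1]
    Q[1, 0], Q[1, 2] = q[2], q[3]
    Q[0, 0] = -(q[0] + q[1])
    Q[1, 1] = -(q[2] + q[3])
    return Q


def transition_probability(params: TransitionParams, z, a1, a2, step=1.0):
    """P(a1, a2): 3x3 stochastic matrix under piecewise-constant intensities
    on sub-intervals of width <= step (midpoint evaluation)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if a2 < a1:
        raise ValueError("a2 must be >= a1")
    z = _as_z(z, params.n_covariates)
    p11, p12, p21, p22 = interval_pll(
        params.to_vector(), params.n_covariates, z, float(a1), float(a2),
        float(step), params.reference_age)
    P = np.array([
        [p11, p12, 1.0 - p11 - p12],
        [p21, p22, 1.0 - p21 - p22],
        [0.0, 0.0, 1.0],
    ])
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# panel preparation
# ---------------------------------------------------------------------------

def prepare_panel(panel, id_col="subject_id", age_col="age", state_col="state"):
    """Validate the observation contract and drop non-analysable subjects.

    Returns ``(clean_panel, exclusions)`` where exclusions counts subjects
    dropped for having a single record or a death as first retained record.
    Ordering violations (non-increasing ages, death not last) raise
    :class:`PanelDataError` naming the subject.
    """
    df = pd.DataFrame(panel).copy()
    for col in (id_col, age_col, state_col):
        if col not in df.columns:
            raise PanelDataError(f"panel is missing required column {col!r}")
    df["_state"] = df[state_col].map(_STATE_CODES)
    if df["_state"].isna().any():
        bad = df.loc[df["_state"].isna(), state_col].unique()
        raise PanelDataError(f"unrecognised state value(s): {list(bad)}")
    df = df.sort_values([id_col, age_col], kind="stable")
    exclusions = {"single_record": 0, "dead_first": 0}
    keep = []
    for sid, g in df.groupby(id_col, sort=False):
        ages = g[age_col].to_numpy(dtype=float)
        states = g["_state"].to_numpy(dtype=int)
        if np.any(np.diff(ages) <= 0):
            raise PanelDataError(f"subject {sid!r}: ages not strictly increasing")
        ndead = int(np.sum(states == DEAD))
        if ndead > 1 or (ndead == 1 and states[-1] != DEAD):
            raise PanelDataError(f"subject {sid!r}: DEAD must be the unique last record")
        if states[0] == DEAD:
            exclusions["dead_first"] += 1
            continue
        if len(g) < 2:
            exclusions["single_record"] += 1
            continue
        keep.append(g.index)
    if keep:
        df = df.loc[np.concatenate([k.to_numpy() for k in keep])]
    else:
        df = df.iloc[0:0]
    df[state_col] = df.pop("_state")
    return df, exclusions


def _pair_arrays(panel, design, id_col, age_col, state_col):
    """Flatten a clean panel into consecutive-pair arrays for the kernel."""
    a1, a2, sf, st, rows = [], [], [], [], []
    for sid, g in panel.groupby(id_col, sort=False):
        ages = g[age_col].to_numpy(dtype=float)
        states = g[state_col].to_numpy(dtype=int)
        ridx = g.index[0]
        for k in range(len(g) - 1):
            a1.append(ages[k])
            a2.append(ages[k + 1])
            sf.append(states[k])
            st.append(states[k + 1])
            rows.append(ridx)
    Z = design.loc[rows].to_numpy(dtype=float) if design.shape[1] else \
        np.zeros((len(rows), 0))
    return (np.asarray(a1), np.asarray(a2),
            np.asarray(sf, dtype=np.int64), np.asarray(st, dtype=np.int64),
            np.ascontiguousarray(Z))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GompertzMultistateModel(BaseEstimator):
    """Three-state illness-death model with recovery, fitted to panel data.

    Parameters
    ----------
    covariates : sequence of str
        Attribute columns (see :data:`CATEGORIES`) entering every transition
        intensity as proportional effects.
    interactions : sequence of (str, str)
        Variable pairs whose dummy products are added as interaction columns.
    step : float
        Width (years) of the piecewise-constant intensity grid; 1.0 gives
        annual transition probabilities, 1/12 monthly.
    reference_age : float
        Age a0 at which alpha is the log intensity.
    gompertz : {"all", "mortality"}
        Whether the age slope xi is free for all four transitions or only
        for the two transitions into death.
    gtol : float
        Gradient-norm convergence tolerance of the quasi-Newton optimizer.

    Fitted attributes (trailing underscore): ``params_``, ``loglik_``,
    ``information_``, ``covariance_``, ``n_iter_``, ``converged_``,
    ``design_columns_``, ``exclusions_``, ``weakly_identified_``.
    """

    def __init__(self, covariates=(), interactions=(), step=1.0,
                 reference_age=65.0, gompertz="all", gtol=1e-5, max_iter=500,
                 hessian=True, id_col="subject_id", age_col="age",
                 state_col="state"):
        self.covariates = covariates
        self.interactions = interactions
        self.step = step
        self.reference_age = reference_age
        self.gompertz = gompertz
        self.gtol = gtol
        self.max_iter = max_iter
        self.hessian = hessian
        self.id_col = id_col
        self.age_col = age_col
        self.state_col = state_col

    # -- helpers ----------------------------------------------------------

    def _free_mask(self, p):
        mask = np.ones(8 + 4 * p, dtype=bool)
        if self.gompertz == "mortality":
            mask[4] = False  # xi for CH->CI
            mask[6] = False  # xi for CI->CH
        elif self.gompertz != "all":
            raise ValueError("gompertz must be 'all' or 'mortality'")
        return mask

    def _crude_init(self, a1, a2, sf, st, p):
        theta = np.zeros(8 + 4 * p)
        weak = []
        dt = a2 - a1
        time_in = {CH: dt[sf == CH].sum(), CI: dt[sf == CI].sum()}
        for t, (r, s) in enumerate(TRANSITIONS):
            events = int(np.sum((sf == r) & (st == s)))
            if events == 0:
                weak.append(TRANSITION_LABELS[t])
            rate = max(events, 0.5) / max(time_in[r], 1e-6)
            theta[t] = np.log(rate)
        return theta, weak

    def _negloglik_factory(self, a1, a2, sf, st, Z, p):
        """Mean negative log-likelihood per observation pair, with its
        analytic gradient.  Normalising keeps the gradient-norm tolerance
        meaningful across data sizes."""
        step = float(self.step)
        a0 = float(self.reference_age)
        scale = 1.0 / max(a1.shape[0], 1)

        def nll(theta):
            return -scale * panel_loglik(theta, p, a1, a2, sf, st, Z, step, a0)

        def nll_grad(theta):
            ll, g = panel_loglik_grad(theta, p, a1, a2, sf, st, Z, step, a0)
            return -scale * ll, -scale * g

        return nll, nll_grad

    def _fit_arrays(self, a1, a2, sf, st, Z, p, theta0):
        """Maximise the likelihood on prebuilt pair arrays (bootstrap fast
        path); returns (theta, scipy result, nll callables)."""
        mask = self._free_mask(p)
        fixed = theta0.copy()
        nll, nll_grad = self._negloglik_factory(a1, a2, sf, st, Z, p)

        def fg_free(x):
            theta = fixed.copy()
            theta[mask] = x
            f, g = nll_grad(theta)
            return f, g[mask]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                fg_free, theta0[mask], method="BFGS", jac=True,
                options={"gtol": self.gtol, "maxiter": self.max_iter})
        theta = fixed.copy()
        theta[mask] = res.x
        return theta, res, nll, nll_grad, mask

    # -- sklearn API ------------------------------------------------------

    def fit(self, panel, y=None, init=None):
        """Maximise the panel likelihood.

        Parameters
        ----------
        panel : DataFrame
            Long-format observations with id/age/state columns plus the raw
            attribute columns named in ``covariates`` (constant per subject;
            baseline values are used).
        init : array or TransitionParams, optional
            Starting values; defaults to log crude rates with zero slopes
            and zero covariate effects.  Passing the previous solution gives
            a warm start (used heavily by the bootstrap).
        """
        clean, exclusions = prepare_panel(panel, self.id_col, self.age_col,
                                          self.state_col)
        if clean.empty:
            raise PanelDataError("no analysable subjects in panel")
        cols = design_columns(self.covariates, self.interactions)
        first = clean.groupby(self.id_col, sort=False).head(1)
        design = build_design(first, self.covariates, self.interactions) \
            if cols else pd.DataFrame(index=first.index)
        a1, a2, sf, st, Z = _pair_arrays(clean, design, self.id_col,
                                         self.age_col, self.state_col)
        p = len(cols)
        theta0, weak = self._crude_init(a1, a2, sf, st, p)
        if init is not None:
            theta0 = init.to_vector() if isinstance(init, TransitionParams) \
                else np.asarray(init, dtype=float).copy()
        theta, res, nll, nll_grad, mask = self._fit_arrays(
            a1, a2, sf, st, Z, p, theta0)
        if not res.success and np.linalg.norm(res.jac) > 10 * self.gtol:
            warnings.warn(
                f"optimizer did not converge ({res.message}); "
                "returning best parameters found", RuntimeWarning)
        self.converged_ = bool(res.success or np.linalg.norm(res.jac) <= 10 * self.gtol)
        self.n_iter_ = int(res.nit)
        self.gradient_norm_ = float(np.linalg.norm(res.jac))
        n_pairs = a1.shape[0]
        self.loglik_ = -float(res.fun) * n_pairs
        self.design_columns_ = tuple(cols)
        self.exclusions_ = exclusions
        self.weakly_identified_ = weak
        self.params_ = TransitionParams.from_vector(
            theta, p, self.reference_age, cols)
        self._theta_ = theta
        self._mask_ = mask
        self._nll_ = nll
        if self.hessian:
            # nll is the per-pair mean; rescale to the observed information
            info = n_pairs * self._observed_information(theta, nll_grad, mask)
            self.information_ = info
            self.covariance_ = self._safe_inverse(info)
        else:
            self.information_ = None
            self.covariance_ = None
        self.n_subjects_ = int(clean[self.id_col].nunique())
        return self

    @staticmethod
    def _observed_information(theta, nll_grad, mask):
        """Hessian of the negative log-likelihood by central differences of
        the analytic gradient, embedded in the full parameter dimension
        (zeros at pinned entries)."""
        idx = np.flatnonzero(mask)
        k = len(idx)
        h = 1e-5 * (1.0 + np.abs(theta[idx]))
        H = np.zeros((k, k))
        for a in range(k):
            ta, tb = theta.copy(), theta.copy()
            ta[idx[a]] += h[a]
            tb[idx[a]] -= h[a]
            _, ga = nll_grad(ta)
            _, gb = nll_grad(tb)
            H[a, :] = (ga[idx] - gb[idx]) / (2 * h[a])
        full = np.zeros((len(theta), len(theta)))
        full[np.ix_(idx, idx)] = 0.5 * (H + H.T)
        return full

    @staticmethod
    def _safe_inverse(info):
        idx = np.flatnonzero(np.diag(info) != 0)
        cov = np.full_like(info, np.nan)
        if idx.size == 0:
            return cov
        sub = info[np.ix_(idx, idx)]
        try:
            inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            warnings.warn("observed information is singular; standard errors "
                          "reported as missing", RuntimeWarning)
            return cov
        cov[np.ix_(idx, idx)] = inv
        return cov

    # -- post-fit quantities ----------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def encode_profile(self, profile):
        """Design vector z for a subject attribute mapping (None -> reference)."""
        self._check_fitted()
        if profile is None:
            return np.zeros(len(self.design_columns_))
        if isinstance(profile, np.ndarray):
            return _as_z(profile, len(self.design_columns_))
        row = {v: CATEGORIES[v][0] for v in self.covariates if v in CATEGORIES}
        row.update(profile)
        enc = build_design(row, self.covariates, self.interactions)
        return enc[list(self.design_columns_)].to_numpy(dtype=float).ravel()

    def intensity_matrix(self, age, profile=None):
        self._check_fitted()
        return intensity_matrix(age, self.encode_profile(profile), self.params_)

    def transition_probability(self, a1, a2, profile=None, step=None):
        self._check_fitted()
        return transition_probability(
            self.params_, self.encode_profile(profile), a1, a2,
            self.step if step is None else step)

    def score(self, panel, y=None):
        """Mean log-likelihood per subject (sklearn scoring convention)."""
        self._check_fitted()
        clean, _ = prepare_panel(panel, self.id_col, self.age_col, self.state_col)
        cols = self.design_columns_
        first = clean.groupby(self.id_col, sort=False).head(1)
        design = build_design(first, self.covariates, self.interactions)[list(cols)] \
            if cols else pd.DataFrame(index=first.index)
        a1, a2, sf, st, Z = _pair_arrays(clean, design, self.id_col,
                                         self.age_col, self.state_col)
        ll = panel_loglik(self._theta_, len(cols), a1, a2, sf, st, Z,
                          float(self.step), float(self.reference_age))
        return float(ll) / max(clean[self.id_col].nunique(), 1)

    def hazard_ratios(self, contrast, alpha=0.05):
        """HR with Wald CI per transition for a covariate column or a linear
        combination of columns.

        Parameters
        ----------
        contrast : str or dict
            A design column name (unit contrast) or ``{column: weight}``
            for within-stratum effects in interaction models, e.g.
            ``{"apoe_e4": 1, "apoe_e4:lifestyle_g45": 1}``.
        """
        self._check_fitted()
        cols = list(self.design_columns_)
        if isinstance(contrast, str):
            contrast = {contrast: 1.0}
        missing = [c for c in contrast if c not in cols]
        if missing:
            raise KeyError(f"unknown contrast column(s) {missing}; "
                           f"available: {cols}")
        if self.covariance_ is None:
            raise RuntimeError("model was fitted with hessian=False; refit "
                               "with hessian=True to get standard errors")
        c = np.zeros(len(cols))
        for name, w in contrast.items():
            c[cols.index(name)] = w
        from scipy.stats import norm
        zcrit = norm.ppf(1 - alpha / 2)
        p = len(cols)
        rows = []
        for t, label in enumerate(TRANSITION_LABELS):
            idx = 8 + t * p + np.arange(p)
            est = float(c @ self._theta_[idx])
            cov = self.covariance_[np.ix_(idx, idx)]
            var = float(c @ cov @ c)
            se = np.sqrt(var) if var >= 0 else np.nan
            rows.append({
                "transition": label,
                "log_hr": est,
                "se": se,
                "hr": np.exp(est),
                "lo": np.exp(est - zcrit * se),
                "hi": np.exp(est + zcrit * se),
            })
        return pd.DataFrame(rows).set_index("transition")

    def hazard_ratio_table(self, alpha=0.05):
        """Tidy HR table for every design column (Table-2-style layout)."""
        self._check_fitted()
        frames = []
        for col in self.design_columns_:
            tab = self.hazard_ratios(col, alpha=alpha).reset_index()
            tab.insert(0, "variable", col)
            frames.append(tab)
        if not frames:
            return pd.DataFrame(
                columns=["variable", "transition", "log_hr", "se", "hr", "lo", "hi"])
        return pd.concat(frames, ignore_index=True)

    # -- serialization -----------------------------------------------------

    def to_dict(self):
        self._check_fitted()
        return {
            "format": "cogspan-fitted-model/1",
            "settings": self.get_params(deep=False) | {
                "covariates": list(self.covariates),
                "interactions": [list(x) for x in self.interactions],
            },
            "design_columns": list(self.design_columns_),
            "theta": self._theta_.tolist(),
            "information": None if self.information_ is None
            else self.information_.tolist(),
            "loglik": self.loglik_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "n_subjects": self.n_subjects_,
            "exclusions": self.exclusions_,
            "weakly_identified": self.weakly_identified_,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload):
        settings = dict(payload["settings"])
        settings["covariates"] = tuple(settings["covariates"])
        settings["interactions"] = tuple(tuple(x) for x in settings["interactions"])
        model = cls(**settings)
        cols = tuple(payload["design_columns"])
        theta = np.asarray(payload["theta"], dtype=float)
        model.design_columns_ = cols
        model._theta_ = theta
        model._mask_ = model._free_mask(len(cols))
        model.params_ = TransitionParams.from_vector(
            theta, len(cols), model.reference_age, cols)
        if payload["information"] is None:
            model.information_ = None
            model.covariance_ = None
        else:
            model.information_ = np.asarray(payload["information"], dtype=float)
            model.covariance_ = cls._safe_inverse(model.information_)
        model.loglik_ = payload["loglik"]
        model.converged_ = payload["converged"]
        model.n_iter_ = payload["n_iter"]
        model.n_subjects_ = payload["n_subjects"]
        model.exclusions_ = payload["exclusions"]
        model.weakly_identified_ = payload["weakly_identified"]
        return model

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def log_likelihood(panel, params: TransitionParams, covariates=(),
                   interactions=(), step=1.0, id_col="subject_id",
                   age_col="age", state_col="state"):
    """Panel log-likelihood at fixed parameters (empty panel -> 0)."""
    df = pd.DataFrame(panel)
    if df.empty:
        return 0.0
    clean, _ = prepare_panel(df, id_col, age_col, state_col)
    if clean.empty:
        return 0.0
    cols = design_columns(covariates, interactions)
    first = clean.groupby(id_col, sort=False).head(1)
    design = build_design(first, covariates, interactions)[cols] if cols \
        else pd.DataFrame(index=first.index)
    a1, a2, sf, st, Z = _pair_arrays(clean, design, id_col, age_col, state_col)
    return float(panel_loglik(params.to_vector(), len(cols), a1, a2, sf, st,
                              Z, float(step), float(params.reference_age)))


def fit(panel, covariates=(), interactions=(), init=None, **kwargs):
    """Fit a :class:`GompertzMultistateModel`; returns the fitted estimator."""
    return GompertzMultistateModel(
        covariates=covariates, interactions=interactions, **kwargs
    ).fit(panel, init=init)
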
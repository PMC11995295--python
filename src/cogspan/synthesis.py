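"""Synthetic ageing-cohort generator with known ground truth.

Emulates the observation process of a longitudinal survey of older adults:
baseline ages 65-99 with an old-heavy mix, interview waves every 2-4 years
over ~15 years, living states seen only at interviews (interval censoring),
death ages exact, right censoring at the last attended interview.  Latent
trajectories follow the three-state model of :mod:`cogspan.markov` exactly:
per-transition Gompertz event times are drawn by inversion of the cumulative
hazard (closed form for either sign of the slope), the minimum winning the
competing risk.

Default attribute frequencies and truth hazard ratios mirror a published
nationwide Chinese cohort of 6448 adults aged 65+: APOE groups 68.0 / 14.2 /
17.8 % (e3e3, e2 carrier, e4 carrier), lifestyle groups 17.5 / 63.6 / 18.9 %
(0-1, 2-3, 4-5 healthy factors), 49.1 % women, ~63 % dying during follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .markov import (CH, CI, DEAD, TransitionParams, design_columns,
                     build_design)

#: truth covariate effects: log HRs per transition (rows: CH->CI, CH->D,
#: CI->CH, CI->D) for columns (apoe_e2, apoe_e4, lifestyle_g23,
#: lifestyle_g45, sex_man)
DEFAULT_TRUTH_HR = np.array([
    [1.05, 1.27, 0.90, 0.73, 0.75],
    [0.88, 1.06, 0.76, 0.57, 1.65],
    [0.88, 1.24, 1.32, 1.73, 1.17],
    [0.97, 1.01, 0.68, 0.37, 1.16],
])

DEFAULT_COVARIATES = ("apoe", "lifestyle", "sex")


def default_truth_params():
    """Truth transition parameters for the default synthetic cohort.

    Baseline intensities at 65 and Gompertz slopes give a mortality profile
    with roughly 60 % of an old-heavy cohort dying over 15 years; recovery
    from impairment is common at young-old ages and wanes with age
    (negative slope, exercising the mixed-sign sampling path).
    """
    return TransitionParams(
        alpha=np.log([0.012, 0.018, 0.25, 0.045]),
        xi=np.array([0.08, 0.085, -0.02, 0.08]),
        beta=np.log(DEFAULT_TRUTH_HR),
        reference_age=65.0,
        covariate_names=tuple(design_columns(DEFAULT_COVARIATES)),
    )


@dataclass
class TruthConfig:
    """Ground-truth configuration of a synthetic cohort."""

    n: int = 1000
    seed: int = 0
    params: TransitionParams = field(default_factory=default_truth_params)
    covariates: tuple = DEFAULT_COVARIATES
    #: (lower, upper, probability) baseline age bands
    age_bands: tuple = ((65.0, 75.0, 0.268), (75.0, 85.0, 0.305),
                       (85.0, 100.0, 0.427))
    frequencies: dict = field(default_factory=lambda: {
        "apoe": {"e3e3": 0.680, "e2": 0.142, "e4": 0.178},
        "lifestyle": {"g01": 0.175, "g23": 0.636, "g45": 0.189},
        "sex": {"woman": 0.491, "man": 0.509},
    })
    visit_gaps: dict = field(default_factory=lambda: {2.0: 0.25, 3.0: 0.50,
                                                      4.0: 0.25})
    follow_up_years: float = 15.0
    dropout: float = 0.10
    omega: float = 110.0
    #: logit of baseline impairment probability: b0 + b1 * (age - 65)
    baseline_ci_logit: tuple = (-2.9, 0.07)
    emit_mmse: bool = False

    def validate(self):
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if self.follow_up_years <= 0:
            raise ValueError("follow-up horizon must be positive")
        for var, freq in self.frequencies.items():
            if abs(sum(freq.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies for {var!r} do not sum to 1")
        if abs(sum(p for _, _, p in self.age_bands) - 1.0) > 1e-9:
            raise ValueError("age band probabilities do not sum to 1")
        if abs(sum(self.visit_gaps.values()) - 1.0) > 1e-9:
            raise ValueError("visit gap probabilities do not sum to 1")
        return self


# ---------------------------------------------------------------------------
# event-time sampling
# ---------------------------------------------------------------------------

def _invert_gompertz(E, lam, xi, age, a0):
    """Time to event from ``age`` for hazard lam*exp(xi*(u-a0)), where E is
    a unit-exponential draw.  Exact inversion of the cumulative hazard;
    returns inf where the bounded (xi<0) cumulative hazard is never reached."""
    E = np.asarray(E, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if abs(xi) < 1e-12:
        return E / lam
    base = np.exp(xi * (np.asarray(age, dtype=float) - a0))
    arg = base + xi * E / lam
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(arg > 0.0, np.log(np.maximum(arg, 1e-300)) / xi
                     - (np.asarray(age, dtype=float) - a0), np.inf)
    return t


def _thinning_gompertz(rng, lam, xi, age, a0, horizon):
    """Rejection (thinning) sampler for one Gompertz event time; the
    dominating rate is the hazard at whichever end of [age, horizon] is
    larger (the hazard is monotone in age)."""
    hmax = max(lam * np.exp(xi * (age - a0)), lam * np.exp(xi * (horizon - a0)))
    if hmax <= 0:
        return np.inf
    t = 0.0
    while True:
        t += rng.exponential(1.0 / hmax)
        if age + t >= horizon:
            return np.inf
        if rng.random() <= lam * np.exp(xi * (age + t - a0)) / hmax:
            return t


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Latent episode sequence: (entry_age, state) pairs, contiguous in age,
    ending in death (``dead=True``, ``end_age`` exact) or truncation at
    the maximum age omega."""

    episodes: list
    end_age: float
    dead: bool

    def state_at(self, age):
        """Latent state at an age (DEAD at/after an exact death age)."""
        if self.dead and age >= self.end_age:
            return DEAD
        state = self.episodes[0][1]
        for entry, s in self.episodes:
            if entry <= age:
                state = s
            else:
                break
        return state


def simulate_trajectory(age0, state0, z, params: TransitionParams, rng,
                        omega=110.0, method="inversion"):
    """Exact simulation of one latent trajectory under competing Gompertz
    intensities.  ``method`` selects inversion (default, exact for either
    slope sign) or thinning (rejection) sampling."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) \
        else rng
    z = np.zeros(params.n_covariates) if z is None else np.asarray(z, float)
    lp = params.beta @ z if params.n_covariates else np.zeros(4)
    lam = np.exp(params.alpha + lp)
    a0 = params.reference_age
    age, state = float(age0), int(state0)
    episodes = [(age, state)]
    while age < omega:
        idx = (0, 1) if state == CH else (2, 3)
        times = []
        for t in idx:
            if method == "inversion":
                times.append(float(_invert_gompertz(
                    rng.exponential(), lam[t], params.xi[t], age, a0)))
            elif method == "thinning":
                times.append(_thinning_gompertz(
                    rng, lam[t], params.xi[t], age, a0, omega))
            else:
                raise ValueError("method must be 'inversion' or 'thinning'")
        tmin = min(times)
        if age + tmin >= omega:
            return Trajectory(episodes, omega, False)
        age += tmin
        dest = ((CI, DEAD) if state == CH else (CH, DEAD))[times.index(tmin)]
        if dest == DEAD:
            return Trajectory(episodes, age, True)
        state = dest
        episodes.append((age, state))
    return Trajectory(episodes, omega, False)


def simulate_cohort_trajectories(ages0, states0, Z, params: TransitionParams,
                                 rng, omega=110.0):
    """Vectorised exact simulation of many trajectories (inversion sampling).

    Returns a list of :class:`Trajectory`, one per subject."""
    ages0 = np.asarray(ages0, dtype=float)
    states0 = np.asarray(states0, dtype=int)
    n = ages0.size
    Z = np.zeros((n, 0)) if Z is None else np.asarray(Z, dtype=float)
    lam = np.exp(params.alpha[None, :] + (Z @ params.beta.T if Z.shape[1]
                                          else np.zeros((n, 4))))
    a0 = params.reference_age
    cur_age = ages0.copy()
    cur_state = states0.copy()
    episodes = [[(float(a), int(s))] for a, s in zip(ages0, states0)]
    end_age = np.full(n, omega)
    dead = np.zeros(n, dtype=bool)
    active = cur_age < omega
    for _ in range(10000):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        t_event = np.full((idx.size, 2), np.inf)
        dest = np.empty((idx.size, 2), dtype=int)
        for k, (s, trans, to) in enumerate((
                (CH, (0, 1), (CI, DEAD)), (CI, (2, 3), (CH, DEAD)))):
            m = cur_state[idx] == s
            if not m.any():
                continue
            sub = idx[m]
            for col, (t, d) in enumerate(zip(trans, to)):
                E = rng.exponential(size=sub.size)
                t_event[m, col] = _invert_gompertz(
                    E, lam[sub, t], params.xi[t], cur_age[sub], a0)
                dest[m, col] = d
        winner = np.argmin(t_event, axis=1)
        tmin = t_event[np.arange(idx.size), winner]
        new_age = cur_age[idx] + tmin
        truncated = new_age >= omega
        cur_age[idx] = np.where(truncated, omega, new_age)
        active[idx[truncated]] = False
        for i in np.flatnonzero(~truncated):
            sid = idx[i]
            d = dest[i, winner[i]]
            if d == DEAD:
                dead[sid] = True
                end_age[sid] = cur_age[sid]
                active[sid] = False
            else:
                cur_state[sid] = d
                episodes[sid].append((float(cur_age[sid]), int(d)))
    else:  # pragma: no cover - guards runaway recovery loops
        raise RuntimeError("trajectory simulation did not terminate")
    return [Trajectory(episodes[i], float(end_age[i]), bool(dead[i]))
            for i in range(n)]


# ---------------------------------------------------------------------------
# cohort attributes and panel observation
# ---------------------------------------------------------------------------

def sample_cohort(config: TruthConfig, rng=None):
    """Draw subject attributes and baseline states for a synthetic cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    n = config.n
    lo = np.array([b[0] for b in config.age_bands])
    hi = np.array([b[1] for b in config.age_bands])
    pk = np.array([b[2] for b in config.age_bands])
    band = rng.choice(len(pk), size=n, p=pk)
    age0 = rng.uniform(lo[band], hi[band])
    cols = {"subject_id": [f"s{i:06d}" for i in range(n)], "age0": age0}
    for var, freq in config.frequencies.items():
        levels = list(freq)
        cols[var] = rng.choice(levels, size=n, p=np.array(list(freq.values())))
    df = pd.DataFrame(cols)
    b0, b1 = config.baseline_ci_logit
    p_ci = 1.0 / (1.0 + np.exp(-(b0 + b1 * (age0 - 65.0))))
    df["state0"] = np.where(rng.random(n) < p_ci, CI, CH)
    return df


def observe_panel(traj: Trajectory, visit_ages, rng=None, dropout=0.0,
                  omega=110.0):
    """Project a latent trajectory onto an interview schedule.

    Living states are recorded at attended visit ages; a death before the
    next attended visit is emitted once with its exact age; observation
    stops at dropout (per-wave probability after baseline), death, or the
    end of the schedule.  Deaths after the last attended visit are censored.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    rows = []
    for j, va in enumerate(visit_ages):
        if j > 0 and dropout > 0 and rng.random() < dropout:
            break
        if traj.dead and traj.end_age <= va:
            rows.append((float(traj.end_age), DEAD, True))
            break
        if va >= omega:
            break
        rows.append((float(va), int(traj.state_at(va)), False))
    return rows


def _visit_schedule(age0, config: TruthConfig, rng):
    gaps = np.array(list(config.visit_gaps))
    pg = np.array(list(config.visit_gaps.values()))
    ages = [age0]
    while ages[-1] - age0 < config.follow_up_years:
        nxt = ages[-1] + rng.choice(gaps, p=pg)
        if nxt - age0 > config.follow_up_years:
            break
        ages.append(nxt)
    return ages


_STATE_NAMES = {CH: "CH", CI: "CI", DEAD: "DEAD"}


def generate_dataset(config: TruthConfig):
    """Full synthetic panel plus its truth manifest.

    Deterministic for a given config (seed included): the same config yields
    byte-identical CSV/JSON output from :func:`write_dataset`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort = sample_cohort(config, rng)
    cols = design_columns(config.covariates)
    Z = build_design(cohort, config.covariates).to_numpy(dtype=float) \
        if cols else None
    trajs = simulate_cohort_trajectories(
        cohort["age0"].to_numpy(), cohort["state0"].to_numpy(), Z,
        config.params, rng, config.omega)
    records = []
    for i, traj in enumerate(trajs):
        schedule = _visit_schedule(cohort["age0"].iloc[i], config, rng)
        obs = observe_panel(traj, schedule, rng, config.dropout, config.omega)
        for w, (age, state, exact) in enumerate(obs):
            rec = {"subject_id": cohort["subject_id"].iloc[i], "wave": w,
                   "age": round(age, 6), "state": _STATE_NAMES[state],
                   "exact": exact}
            for var in config.frequencies:
                rec[var] = cohort[var].iloc[i]
            records.append(rec)
    panel = pd.DataFrame(records)
    if config.emit_mmse and not panel.empty:
        panel = _emit_mmse(panel, rng)
    manifest = {
        "generator": "cogspan.synthesis/1",
        "n": config.n,
        "seed": config.seed,
        "truth": {
            "alpha": config.params.alpha.tolist(),
            "xi": config.params.xi.tolist(),
            "beta": config.params.beta.tolist(),
            "reference_age": config.params.reference_age,
            "covariate_columns": list(design_columns(config.covariates)),
        },
        "covariates": list(config.covariates),
        "frequencies": config.frequencies,
        "follow_up_years": config.follow_up_years,
        "dropout": config.dropout,
        "omega": config.omega,
        "n_subjects_observed": int(panel["subject_id"].nunique()) if not panel.empty else 0,
        "n_single_record": int((panel.groupby("subject_id").size() == 1).sum()) if not panel.empty else 0,
        "n_deaths_observed": int((panel["state"] == "DEAD").sum()) if not panel.empty else 0,
    }
    return panel, manifest


def _emit_mmse(panel, rng):
    """Optional raw cognition columns: MMSE drawn from truncated normals on
    either side of the 18-point cut, plus a self-reported dementia flag, so
    that state classification can be exercised end to end."""
    panel = panel.copy()
    n = len(panel)
    mmse = np.full(n, np.nan)
    dementia = np.full(n, "no", dtype=object)
    living = panel["state"] != "DEAD"
    ch = (panel["state"] == "CH").to_numpy()
    ci = (panel["state"] == "CI").to_numpy()
    mmse[ch] = np.clip(np.round(rng.normal(25, 3, ch.sum())), 18, 30)
    mmse[ci] = np.clip(np.round(rng.normal(12, 4, ci.sum())), 0, 17)
    via_report = ci & (rng.random(n) < 0.10)
    dementia[via_report] = "yes"
    mmse[via_report] = np.clip(np.round(rng.normal(20, 5, via_report.sum())), 0, 30)
    panel["mmse"] = mmse
    panel.loc[~living, "mmse"] = np.nan
    panel["dementia"] = dementia
    panel.loc[~living, "dementia"] = ""
    return panel


def write_dataset(config: TruthConfig, panel_path, manifest_path):
    """Write the panel CSV and truth manifest JSON (byte-stable per seed)."""
    panel, manifest = generate_dataset(config)
    panel.to_csv(panel_path, index=False, float_format="%.6f")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return panel, manifest
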
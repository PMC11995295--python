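"""Derivation of analysis variables from questionnaire-like records.

Covers cognitive-state classification from the MMSE and self-reported
dementia, the five binary healthy-lifestyle factors and their 0-1 / 2-3 /
4-5 grouping, the regression-weighted Healthy Living Index with tertiles,
APOE grouping from the rs429358/rs7412 SNPs with a Hardy-Weinberg check,
covariate encodings (comorbidity category, ADL disability, categorical
dummies), and nearest-wave imputation of missing covariates.

Missing-data policy: a missing single lifestyle item counts as unhealthy
(flag False); subjects missing all five items, or cognition at every wave,
are excluded by :func:`phenotype_panel`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

MMSE_CUTOFF = 18          # scores strictly below are severe impairment
QUIT_YEARS = 10.0         # smoking/alcohol abstinence must exceed this
DIET_ITEMS_CUTOFF = 5     # daily food items for an ideal diet
COGNITIVE_SESSIONS = 2    # weekly sessions for active engagement

FOOD_ITEMS = frozenset({
    "fruits", "vegetables", "grains", "meat", "fish_seafood", "eggs",
    "dairy", "legumes", "sweets", "garlic", "nuts", "tea",
})
COGNITIVE_ACTIVITIES = ("reading", "cards", "social", "visiting")
DISEASES = frozenset({
    "hypertension", "diabetes", "heart_disease", "stroke",
    "respiratory_disease", "tuberculosis", "cataracts", "glaucoma",
    "cancer", "gastric_ulcer", "parkinsons", "bedsores", "arthritis",
})
ADL_ITEMS = ("bathing", "dressing", "toileting", "indoor_mobility",
             "continence", "eating")

LIFESTYLE_FLAGS = ("no_smoking", "no_alcohol", "ideal_diet",
                   "physically_active", "cognitive_engagement")


def _is_missing(x):
    return x is None or (isinstance(x, float) and np.isnan(x)) or \
        (isinstance(x, str) and x == "")


# ---------------------------------------------------------------------------
# cognition
# ---------------------------------------------------------------------------

def classify_cognition(mmse, dementia_selfreport="no"):
    """Cognitive state from MMSE and self-reported dementia.

    CI if MMSE < 18 or dementia reported; CH if MMSE >= 18 without a
    dementia report; None (missing) if the MMSE is missing and no dementia
    is reported.  MMSE outside [0, 30] raises ValueError.
    """
    dementia = None if _is_missing(dementia_selfreport) else \
        str(dementia_selfreport).lower()
    if dementia not in (None, "yes", "no"):
        raise ValueError(f"dementia_selfreport must be yes/no/missing, "
                         f"got {dementia_selfreport!r}")
    if dementia == "yes":
        return "CI"
    if _is_missing(mmse):
        return None
    mmse = float(mmse)
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE score {mmse} outside [0, 30]")
    return "CI" if mmse < MMSE_CUTOFF else "CH"


def classify_cognition_frame(df, mmse_col="mmse", dementia_col="dementia",
                             id_col="subject_id", wave_col="wave"):
    """Vector version over a panel; errors name the offending subject/wave."""
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(classify_cognition(row.get(mmse_col),
                                          row.get(dementia_col, "no")))
        except ValueError as exc:
            sid = row.get(id_col, idx)
            wave = row.get(wave_col, "?")
            raise ValueError(f"subject {sid!r}, wave {wave}: {exc}") from exc
    return pd.Series(out, index=df.index, dtype=object)


# ---------------------------------------------------------------------------
# lifestyle
# ---------------------------------------------------------------------------

def _abstinent(status, quit_years):
    """Never users are healthy; quitters only after more than 10 years."""
    if _is_missing(status):
        return False
    status = str(status).lower()
    if status == "never":
        return True
    if status == "current":
        return False
    if status == "quit":
        return (not _is_missing(quit_years)) and float(quit_years) > QUIT_YEARS
    raise ValueError(f"unknown use status {status!r}")


def _food_count(value):
    if _is_missing(value):
        return 0
    if isinstance(value, (int, np.integer, float)):
        return int(value)
    if isinstance(value, str):
        items = {v.strip() for v in value.split(";") if v.strip()}
    else:
        items = set(value)
    bad = items - FOOD_ITEMS
    if bad:
        raise ValueError(f"unknown food item(s) {sorted(bad)}; "
                         f"universe: {sorted(FOOD_ITEMS)}")
    return len(items)


def score_lifestyle_factors(record):
    """The five healthy-lifestyle booleans for one record (dict/Series).

    Expected fields: ``smoking`` / ``drinking`` (never|current|quit) with
    ``smoking_quit_years`` / ``drinking_quit_years``; ``food_items`` (item
    set, semicolon string, or a count); ``physically_active`` (bool); and
    ``cog_<activity>`` weekly session counts for reading, cards, social,
    visiting.  Missing fields count as unhealthy.
    """
    rec = dict(record)
    flags = {
        "no_smoking": _abstinent(rec.get("smoking"),
                                 rec.get("smoking_quit_years")),
        "no_alcohol": _abstinent(rec.get("drinking"),
                                 rec.get("drinking_quit_years")),
        "ideal_diet": _food_count(rec.get("food_items")) >= DIET_ITEMS_CUTOFF,
        "physically_active": bool(rec.get("physically_active"))
        if not _is_missing(rec.get("physically_active")) else False,
    }
    sessions = [rec.get(f"cog_{a}") for a in COGNITIVE_ACTIVITIES]
    flags["cognitive_engagement"] = any(
        (not _is_missing(s)) and float(s) >= COGNITIVE_SESSIONS
        for s in sessions)
    return flags


def score_lifestyle_frame(df):
    """DataFrame of the five lifestyle flags, one row per input row."""
    rows = [score_lifestyle_factors(row) for _, row in df.iterrows()]
    return pd.DataFrame(rows, index=df.index, columns=LIFESTYLE_FLAGS)


def group_lifestyle(flags):
    """(count, group) with groups g01 (<=1), g23 (2-3), g45 (>=4)."""
    if isinstance(flags, dict):
        flags = [flags[k] for k in LIFESTYLE_FLAGS]
    count = int(sum(bool(f) for f in flags))
    if len(list(flags)) != 5:
        raise ValueError("expected exactly five lifestyle flags")
    group = "g01" if count <= 1 else ("g23" if count <= 3 else "g45")
    return count, group


def estimate_hli_betas(flags_df, ci_indicator):
    """Weights for the Healthy Living Index: absolute logistic-regression
    coefficients of impairment on the five flags."""
    import statsmodels.api as sm
    X = sm.add_constant(flags_df[list(LIFESTYLE_FLAGS)].astype(float))
    y = np.asarray(ci_indicator, dtype=float)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return np.abs(res.params.to_numpy()[1:])


def weighted_hli(flags_df, betas):
    """HLI = sum_i beta_i * flag_i per row."""
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (5,):
        raise ValueError("betas must have five entries")
    if np.all(betas == 0):
        warnings.warn("all HLI betas are zero; index is degenerate")
    X = flags_df[list(LIFESTYLE_FLAGS)].astype(float).to_numpy()
    return pd.Series(X @ betas, index=flags_df.index, name="hli")


def assign_tertiles(hli, subject_ids=None):
    """LOW/MID/HIGH with group sizes differing by at most one; ties broken
    by stable subject-id order."""
    hli = pd.Series(hli)
    ids = pd.Series(subject_ids, index=hli.index) if subject_ids is not None \
        else pd.Series(hli.index, index=hli.index)
    order = hli.index[np.lexsort((ids.to_numpy(), hli.to_numpy()))]
    labels = pd.Series(index=hli.index, dtype=object)
    for name, chunk in zip(("LOW", "MID", "HIGH"), np.array_split(order, 3)):
        labels.loc[chunk] = name
    return labels


# ---------------------------------------------------------------------------
# APOE
# ---------------------------------------------------------------------------

_EPS_TABLE = {
    # (rs429358 genotype, rs7412 genotype) -> epsilon genotype; genotypes
    # are allele-sorted strings.  Haplotype coding: e2 = (T, T), e3 = (T, C),
    # e4 = (C, C); the C-T haplotype would be the vanishingly rare e1.
    ("TT", "CC"): ("e3", "e3"),
    ("TT", "CT"): ("e2", "e3"),
    ("TT", "TT"): ("e2", "e2"),
    ("CT", "CC"): ("e3", "e4"),
    ("CC", "CC"): ("e4", "e4"),
    # double heterozygote: unphased; resolved as e2/e4 by convention
    ("CT", "CT"): ("e2", "e4"),
}

APOE_GROUPS = {
    ("e2", "e2"): "e2", ("e2", "e3"): "e2",
    ("e3", "e3"): "e3e3",
    ("e3", "e4"): "e4", ("e4", "e4"): "e4",
    ("e2", "e4"): "excluded_e2e4",
}


def _norm_genotype(g, snp):
    alleles = sorted(str(g).upper().replace("/", ""))
    if len(alleles) != 2 or set(alleles) - {"C", "T"}:
        raise ValueError(f"invalid {snp} genotype {g!r}: alleles must be C/T")
    return "".join(alleles)


def group_apoe(rs429358, rs7412):
    """(epsilon genotype, analysis group) from the two APOE SNPs.

    Groups: 'e3e3' (reference), 'e2' (e2/e2, e2/e3), 'e4' (e3/e4, e4/e4),
    'excluded_e2e4' (the unphased CT/CT double heterozygote, resolved as
    e2/e4 and excluded from analysis).  Genotype combinations implying the
    rare e1 haplotype (rs429358 C with rs7412 T in cis) raise ValueError.
    """
    key = (_norm_genotype(rs429358, "rs429358"), _norm_genotype(rs7412, "rs7412"))
    if key not in _EPS_TABLE:
        raise ValueError(
            f"rs429358={key[0]}, rs7412={key[1]} implies the rare e1 "
            "haplotype, outside the e2/e3/e4 classification")
    eps = _EPS_TABLE[key]
    return "/".join(eps), APOE_GROUPS[eps]


def hwe_chi_square(genotype_counts):
    """1-df chi-square test of Hardy-Weinberg equilibrium.

    ``genotype_counts`` are (hom_ref, het, hom_alt) counts for one SNP.
    A monomorphic SNP returns (0, 1) with a warning.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise ValueError("genotype_counts must be three nonnegative numbers")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        warnings.warn("monomorphic SNP: HWE test degenerate, p = 1")
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def comorbidity_category(diseases):
    """'none' / 'one' / 'comorbidity' (two or more chronic diseases).

    ``diseases`` is a disease-name set (validated against the 13-condition
    list), a semicolon string, or an integer count.
    """
    if _is_missing(diseases):
        return None
    if isinstance(diseases, (int, np.integer)):
        k = int(diseases)
    else:
        items = {v.strip() for v in diseases.split(";") if v.strip()} \
            if isinstance(diseases, str) else set(diseases)
        bad = items - DISEASES
        if bad:
            raise ValueError(f"unknown disease(s) {sorted(bad)}")
        k = len(items)
    return "none" if k == 0 else ("one" if k == 1 else "comorbidity")


def adl_disability(adl_flags):
    """True if help is needed in any of the six daily-living activities."""
    flags = [adl_flags.get(f"adl_{item}") for item in ADL_ITEMS] \
        if isinstance(adl_flags, (dict, pd.Series)) else list(adl_flags)
    if len(flags) != 6:
        raise ValueError("expected six ADL items")
    return any(bool(f) for f in flags if not _is_missing(f))


def encode_covariates(df):
    """Derived covariate columns: comorbidity category, ADL disability, and
    validated categorical levels ready for the model's dummy coding."""
    from .markov import CATEGORIES
    out = df.copy()
    if "diseases" in out.columns:
        out["comorbidity"] = out["diseases"].map(comorbidity_category)
    adl_cols = [f"adl_{i}" for i in ADL_ITEMS]
    if set(adl_cols) <= set(out.columns):
        out["disabled"] = out[adl_cols].apply(
            lambda r: adl_disability(dict(zip(adl_cols, r))), axis=1)
    for var in ("residence", "schooling", "living_arrangement",
                "marital_status", "sex"):
        if var in out.columns:
            observed = set(out[var].dropna()) - {""}
            bad = observed - set(CATEGORIES[var])
            if bad:
                raise ValueError(f"unknown {var} label(s) {sorted(map(str, bad))}; "
                                 f"expected {CATEGORIES[var]}")
    return out


def impute_nearest_wave(panel, columns, id_col="subject_id", age_col="age"):
    """Fill missing covariates from the temporally nearest wave of the same
    subject; equidistant ties resolve to the earlier wave.  Covariates
    missing at every wave stay missing.  Idempotent; never touches states.
    """
    df = pd.DataFrame(panel).copy()
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in panel")
    for sid, g in df.groupby(id_col, sort=False):
        ages = g[age_col].to_numpy(dtype=float)
        for col in columns:
            vals = g[col]
            miss = vals.apply(_is_missing).to_numpy()
            if not miss.any() or miss.all():
                continue
            donors = np.flatnonzero(~miss)
            for i in np.flatnonzero(miss):
                dist = np.abs(ages[donors] - ages[i])
                best = donors[np.lexsort((ages[donors], dist))][0]
                df.loc[g.index[i], col] = vals.iloc[best]
    return df


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def phenotype_panel(raw, id_col="subject_id", age_col="age", wave_col="wave",
                    impute_columns=(), hli=False):
    """Raw panel -> analysis-ready panel plus a provenance manifest.

    Applies, in the fixed exclusion order: (1) baseline age outside
    [65, 100); (2) a single record; (3) the e2/e4 (or e1-bearing) APOE
    genotype; (4) cognition missing at every wave or all five lifestyle
    items missing.  Emits state, lifestyle flags/count/group, APOE group
    and encoded covariates.
    """
    df = encode_covariates(pd.DataFrame(raw).copy())
    df = df.sort_values([id_col, age_col], kind="stable")
    if impute_columns:
        df = impute_nearest_wave(df, impute_columns, id_col, age_col)
    manifest = {"thresholds": {
        "mmse_cutoff": MMSE_CUTOFF, "quit_years": QUIT_YEARS,
        "diet_items": DIET_ITEMS_CUTOFF,
        "cognitive_sessions_per_week": COGNITIVE_SESSIONS}}
    exclusions = {"age_range": 0, "single_record": 0, "apoe_e2e4": 0,
                  "missing_mmse_or_all_lifestyle": 0}

    if "state" not in df.columns:
        df["state"] = classify_cognition_frame(df, id_col=id_col,
                                               wave_col=wave_col)
        if "death_age" in df.columns:
            deaths = df.groupby(id_col, sort=False).tail(1)
            dead = deaths[~deaths["death_age"].apply(_is_missing)]
            extra = dead.copy()
            extra["age"] = extra["death_age"].astype(float)
            extra["state"] = "DEAD"
            df = pd.concat([df, extra]).sort_values([id_col, age_col],
                                                    kind="stable")

    if {"rs429358", "rs7412"} <= set(df.columns) and "apoe" not in df.columns:
        def _apoe(row):
            try:
                return group_apoe(row["rs429358"], row["rs7412"])[1]
            except ValueError:
                return "excluded_e2e4"
        df["apoe"] = df.apply(_apoe, axis=1)

    lifestyle_cols = {"smoking", "drinking", "food_items",
                      "physically_active"} | \
        {f"cog_{a}" for a in COGNITIVE_ACTIVITIES}
    has_lifestyle_raw = bool(lifestyle_cols & set(df.columns))
    if has_lifestyle_raw and "lifestyle" not in df.columns:
        base = df.groupby(id_col, sort=False).head(1)
        flags = score_lifestyle_frame(base)
        grouped = flags.apply(lambda r: group_lifestyle(dict(r)), axis=1)
        per_subject = pd.DataFrame({
            id_col: base[id_col].to_numpy(),
            "lifestyle_count": [c for c, _ in grouped],
            "lifestyle": [g for _, g in grouped],
        })
        for k in LIFESTYLE_FLAGS:
            per_subject[k] = flags[k].to_numpy()
        df = df.merge(per_subject, on=id_col, how="left")
        all_missing = base[
            [c for c in lifestyle_cols if c in base.columns]
        ].apply(lambda r: all(_is_missing(v) for v in r), axis=1)
        all_missing_ids = set(base.loc[all_missing.to_numpy(), id_col])
    else:
        all_missing_ids = set()

    keep_rows = []
    for sid, g in df.sort_values([id_col, age_col], kind="stable").groupby(
            id_col, sort=False):
        base_age = float(g[age_col].iloc[0])
        if not (65.0 <= base_age < 100.0):
            exclusions["age_range"] += 1
            continue
        if len(g) < 2:
            exclusions["single_record"] += 1
            continue
        if "apoe" in g.columns and g["apoe"].iloc[0] == "excluded_e2e4":
            exclusions["apoe_e2e4"] += 1
            continue
        states = g["state"]
        cognition_all_missing = states[states != "DEAD"].apply(
            _is_missing).all()
        if cognition_all_missing or sid in all_missing_ids:
            exclusions["missing_mmse_or_all_lifestyle"] += 1
            continue
        keep_rows.append(g.index)
    df = df.loc[np.concatenate([k.to_numpy() for k in keep_rows])] if keep_rows \
        else df.iloc[0:0]

    if hli and not df.empty and set(LIFESTYLE_FLAGS) <= set(df.columns):
        base = df.groupby(id_col, sort=False).head(1)
        y = (base["state"] == "CI").astype(float)
        betas = estimate_hli_betas(base[list(LIFESTYLE_FLAGS)], y)
        hli_vals = weighted_hli(base[list(LIFESTYLE_FLAGS)], betas)
        tert = assign_tertiles(hli_vals, base[id_col])
        mapping = pd.DataFrame({id_col: base[id_col].to_numpy(),
                                "hli": hli_vals.to_numpy(),
                                "hli_tertile": tert.to_numpy()})
        df = df.merge(mapping, on=id_col, how="left")
        manifest["hli_betas"] = betas.tolist()

    manifest["exclusions"] = exclusions
    manifest["n_subjects"] = int(df[id_col].nunique()) if not df.empty else 0
    return df.reset_index(drop=True), manifest
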
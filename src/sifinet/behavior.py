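"""Behavioral scoring and participant stratification.

Illusion rates are the fraction of 2 beeps / 1 flash trials on which a
participant reported two flashes.  Within each age group, participants
are rank-ordered by their overall illusion rate and split at the median
into a propensity-to-perceive-illusion (PPI) and a propensity-to-
perceive-no-illusion (PPNI) group.  Trial counts between two sets are
equalized by seeded uniform subsampling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["illusion_rates", "control_accuracies", "median_split",
           "stratify_trials", "behavioral_anova"]

ILLUSION_CONDITION = "2b1f"


def illusion_rates(table: pd.DataFrame, per_soa: bool = True) -> pd.DataFrame:
    """Per-subject illusion rates from a per-trial behavioral table.

    A 2 beeps / 1 flash trial answered "2" counts as a perceived
    illusion.  Rates for subject/SOA cells without trials are undefined
    and returned as NaN with a warning (never silently zero).

    Parameters
    ----------
    table : DataFrame
        Per-trial table with columns ``subject, age_group, condition,
        soa_ms, response``.
    per_soa : bool
        If True return one rate per subject and SOA; otherwise one
        overall rate per subject.

    Returns
    -------
    DataFrame with columns ``subject, age_group, [soa_ms,] n_trials,
    rate``.
    """
    ill = table[table["condition"] == ILLUSION_CONDITION]
    if ill.empty:
        raise ValueError("table contains no 2 beeps / 1 flash trials")
    keys = ["subject", "age_group"] + (["soa_ms"] if per_soa else [])
    grouped = ill.groupby(keys, observed=True)["response"]
    out = grouped.agg(n_trials="size", rate=lambda r: np.mean(r == 2)).reset_index()
    if per_soa:
        # flag subject x SOA cells absent from the table
        subjects = ill[["subject", "age_group"]].drop_duplicates()
        soas = ill["soa_ms"].unique()
        full = subjects.merge(pd.DataFrame({"soa_ms": soas}), how="cross")
        out = full.merge(out, on=keys, how="left")
        missing = out["rate"].isna()
        if missing.any():
            warnings.warn(f"{int(missing.sum())} subject x SOA cells have no "
                          "trials; rates set to NaN")
            out.loc[missing, "n_trials"] = 0
    return out


def control_accuracies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject accuracy in the audiovisual control conditions."""
    ctrl = table[table["condition"].isin(["1b1f", "2b2f"])]
    if ctrl.empty:
        raise ValueError("table contains no control trials")
    correct = ctrl["response"] == ctrl["n_flashes"]
    out = (ctrl.assign(correct=correct)
           .groupby(["subject", "age_group", "condition"], observed=True)["correct"]
           .agg(n_trials="size", accuracy="mean").reset_index())
    return out


def median_split(rates: pd.DataFrame) -> pd.DataFrame:
    """Median-split subjects into PPI / PPNI within each age group.

    Subjects strictly above their age group's median illusion rate are
    labelled PPI; subjects at or below the median are labelled PPNI
    (ties resolve toward "no illusion").  The assignment is invariant to
    subject ordering.

    Parameters
    ----------
    rates : DataFrame
        One row per subject with columns ``subject, age_group, rate``
        (e.g. ``illusion_rates(table, per_soa=False)``).

    Returns
    -------
    DataFrame with columns ``subject, age_group, rate, propensity``.
    """
    if rates["subject"].duplicated().any():
        raise ValueError("rates must contain one row per subject")
    out = []
    for group, sub in rates.groupby("age_group", observed=True):
        if len(sub) < 2:
            raise ValueError(f"age group {group!r}: need >= 2 subjects")
        r = sub["rate"].to_numpy(dtype=float)
        if np.allclose(r, r[0]):
            raise ValueError(f"age group {group!r}: all illusion rates "
                             "identical, median split undefined")
        med = np.median(r)
        lab = np.where(r > med, "PPI", "PPNI")
        out.append(sub.assign(propensity=lab))
    return pd.concat(out, ignore_index=True)


def stratify_trials(set_a, set_b, seed: int = 0):
    """Equalize two trial-index sets by uniform subsampling.

    Both returned arrays have size ``min(|a|, |b|)``; the larger set is
    subsampled uniformly without replacement using the given seed, the
    smaller is returned unchanged (sorted).
    """
    a = np.asarray(list(set_a))
    b = np.asarray(list(set_b))
    if a.size == 0 or b.size == 0:
        raise ValueError("both trial sets must be non-empty")
    rng = np.random.default_rng(seed)
    m = min(a.size, b.size)
    if a.size > m:
        a = rng.choice(a, size=m, replace=False)
    if b.size > m:
        b = rng.choice(b, size=m, replace=False)
    return np.sort(a), np.sort(b)


def behavioral_anova(rates: pd.DataFrame) -> pd.DataFrame:
    """Mixed two-way ANOVA (Age Group x SOA) on per-subject illusion rates.

    Routine companion statistic for the behavioral table; Age Group is
    between subjects, SOA within.  Uses an ordinary two-way ANOVA on the
    subject x SOA rate table with the subject term absorbed into the
    within-cell error, which is the standard mixed-model F for the
    between factor and a conservative F for SOA.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = rates.dropna(subset=["rate"]).copy()
    d["soa"] = d["soa_ms"].astype(str)
    model = ols("rate ~ C(age_group) * C(soa)", data=d).fit()
    return sm.stats.anova_lm(model, typ=2)
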
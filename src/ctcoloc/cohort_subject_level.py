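"""Transfer of the colocalization framework to longitudinal cohorts.

The same relative-change formula and dominance decomposition are applied
to observed two(+)-session CT data: per-subject change maps, per-subject
dominance decompositions, and a group-level test that compares the mean
full-model R² (and each mean total dominance) across subjects against
null analyses in which the whole predictor set is replaced by jointly
drawn variogram-matched surrogates (one surrogate set per null iteration,
shared across subjects, since the test concerns the group mean).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .ct_change_windows import CTChangeMap, relative_change
from .dominance_influence import (_check_design, _dominance_from_table,
                                  _standardize, _subset_r2_table)
from .parcel_core import AtlasSet, ParcelMap
from .spatial_nulls import NullEnsemble

__all__ = [
    "subject_change",
    "cohort_average_change",
    "subject_dominance",
    "group_mean_null_test",
]

logger = logging.getLogger(__name__)


def _session_index(cohort, label: str) -> int:
    try:
        return cohort.session_labels.index(label)
    except ValueError:
        raise ValueError(f"unknown session {label!r}; cohort has "
                         f"{cohort.session_labels}") from None


def subject_change(cohort, span: tuple[str, str]
                   ) -> dict[str, CTChangeMap]:
    """Per-subject relative CT change between two sessions.

    Subjects missing either session are excluded (count logged).  The
    window is labeled by each subject's session ages.
    """
    a, b = (_session_index(cohort, s) for s in span)
    out: dict[str, CTChangeMap] = {}
    excluded = 0
    for s, sid in enumerate(cohort.subject_ids):
        if np.isnan(cohort.ages[s, a]) or np.isnan(cohort.ages[s, b]):
            excluded += 1
            continue
        ct_i = ParcelMap(cohort.parcel_ids, cohort.ct[s, a],
                         f"{sid}_{span[0]}", cohort.hemisphere)
        ct_j = ParcelMap(cohort.parcel_ids, cohort.ct[s, b],
                         f"{sid}_{span[1]}", cohort.hemisphere)
        out[sid] = relative_change(
            ct_i, ct_j, (float(cohort.ages[s, a]), float(cohort.ages[s, b])))
    if not out:
        raise ValueError(f"no subject has both sessions {span}")
    logger.info("subject_change %s: %d subjects, %d excluded "
                "(missing session)", span, len(out), excluded)
    return out


def cohort_average_change(cohort, span: tuple[str, str]
                          ) -> tuple[CTChangeMap, CTChangeMap]:
    """(change of the cohort-average CT, average of subject change maps).

    The two differ slightly because the change is a ratio; both are
    returned so the difference can be reported.
    """
    changes = subject_change(cohort, span)
    a, b = (_session_index(cohort, s) for s in span)
    keep = [s for s, sid in enumerate(cohort.subject_ids) if sid in changes]
    mean_i = cohort.ct[keep, a].mean(axis=0)
    mean_j = cohort.ct[keep, b].mean(axis=0)
    ages = (float(np.nanmean(cohort.ages[keep, a])),
            float(np.nanmean(cohort.ages[keep, b])))
    of_mean = relative_change(
        ParcelMap(cohort.parcel_ids, mean_i, "cohort_mean_i",
                  cohort.hemisphere),
        ParcelMap(cohort.parcel_ids, mean_j, "cohort_mean_j",
                  cohort.hemisphere), ages)
    mean_vals = np.mean([c.values for c in changes.values()], axis=0)
    mean_of = CTChangeMap(ages, ParcelMap(cohort.parcel_ids, mean_vals,
                                          "mean_subject_change",
                                          cohort.hemisphere))
    return of_mean, mean_of


def _subject_tables(predictors: AtlasSet,
                    changes: dict[str, CTChangeMap]):
    """Standardized design + per-subject outcome correlations."""
    X = _standardize(predictors.matrix())
    _check_design(X)
    Y = np.column_stack([c.values for c in changes.values()])
    Ys = (Y - Y.mean(0)) / Y.std(0)
    return X, Ys


def subject_dominance(changes: dict[str, CTChangeMap],
                      predictors: AtlasSet) -> pd.DataFrame:
    """One exact dominance decomposition per subject change map.

    Returns one row per subject: full-model R² (plain and adjusted),
    per-predictor total dominance, Spearman sign, and follow-up duration
    in years.
    """
    for c in changes.values():
        if tuple(c.parcel_ids) != tuple(predictors.parcel_ids):
            raise ValueError("cohort and predictors use different parcels")
    X, Ys = _subject_tables(predictors, changes)
    n, p = X.shape
    C = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
    c = X.T @ Ys / n
    table = _subset_r2_table(C, c)
    dom = _dominance_from_table(table, p)            # (p, n_subj)
    r2 = table[-1]
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    ranks_X = scipy.stats.rankdata(X, axis=0)
    rows = []
    for j, (sid, ch) in enumerate(changes.items()):
        rho = _spearman_cols(ranks_X, ch.values)
        row = {"subject": sid, "window_start": ch.window[0],
               "window_end": ch.window[1],
               "duration": ch.window[1] - ch.window[0],
               "full_model_r2": float(r2[j]),
               "full_model_adj_r2": float(adj[j])}
        for i, nm in enumerate(predictors.names):
            row[f"dom_{nm}"] = float(dom[i, j])
            row[f"rho_{nm}"] = float(rho[i])
        rows.append(row)
    return pd.DataFrame(rows)


def _spearman_cols(ranks_X: np.ndarray, y: np.ndarray) -> np.ndarray:
    ry = scipy.stats.rankdata(y)
    rx = ranks_X - ranks_X.mean(0)
    ry = ry - ry.mean()
    return (rx.T @ ry) / np.sqrt((rx ** 2).sum(0) * (ry ** 2).sum())


def group_mean_null_test(changes: dict[str, CTChangeMap],
                         predictors: AtlasSet,
                         nulls: dict[str, NullEnsemble],
                         n_null: int = 1000) -> dict:
    """Permuted-atlas test of the cohort-mean R² and mean dominances.

    Observed statistics are the across-subject means of the full-model R²
    and of each predictor's total dominance.  Each of ``n_null`` null
    iterations replaces the predictor set by one jointly drawn surrogate
    set (reused across subjects within the iteration) and recomputes the
    means; p = (1 + #{null >= observed}) / (1 + N), positive-sided.
    """
    if n_null < 1:
        raise ValueError("need at least one null iteration")
    if len(changes) < 2:
        raise ValueError("group test needs at least two subjects")
    names = predictors.names
    missing = [nm for nm in names if nm not in nulls]
    if missing:
        raise ValueError(f"no null ensemble for predictors {missing}")
    navail = min(nulls[nm].n for nm in names)
    if n_null > navail:
        raise ValueError(f"requested {n_null} null iterations but smallest "
                         f"ensemble has {navail}")

    obs = subject_dominance(changes, predictors)
    obs_full = float(obs["full_model_r2"].mean())
    obs_dom = np.array([obs[f"dom_{nm}"].mean() for nm in names])

    X, Ys = _subject_tables(predictors, changes)
    n, p = X.shape
    ge_full = 0
    ge_dom = np.zeros(p, dtype=int)
    for t in range(n_null):
        Xt = _standardize(np.column_stack(
            [nulls[nm].surrogates[t] for nm in names]))
        Ct = np.corrcoef(Xt, rowvar=False) if p > 1 else np.ones((1, 1))
        ct = Xt.T @ Ys / n
        table = _subset_r2_table(Ct, ct)
        ge_full += int(table[-1].mean() >= obs_full)
        ge_dom += _dominance_from_table(table, p).mean(axis=1) >= obs_dom
    return {
        "mean_full_model_r2": obs_full,
        "p_full": (1 + ge_full) / (1 + n_null),
        "mean_dominance": pd.Series(obs_dom, index=names),
        "p_dominance": pd.Series((1 + ge_dom) / (1 + n_null), index=names),
        "n_null": n_null, "n_subjects": len(changes),
    }
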
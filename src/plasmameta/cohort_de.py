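"""Single-cohort two-group differential expression.

Moderated t-statistics with empirical-Bayes variance shrinkage toward a
scaled inverse-chi-squared prior (fitted by method of moments on log s^2),
Benjamini-Hochberg correction, two-tier DEG thresholds with an automatic
fallback for under-powered cohorts, and shared-DEG counting across cohorts.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import CohortDataset

#: Two-tier DEG thresholds: adjusted p for the stringent tier, raw p for
#: the relaxed fallback; both demand a two-fold change on log2 scale.
P_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0


class SmallSampleError(ValueError):
    """Raised when a cohort has fewer than 2 samples in an arm; the caller
    should fall back to fold-change-only DEG calling."""


def _trigamma_inverse(x: float) -> float:
    # Newton iteration for psi'(y) = x (monotone decreasing on (0, inf))
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-squared prior.

    Models gene-wise sample variances as ``s^2 ~ s0^2 * F(df, d0)`` and
    matches the first two moments of ``log s^2`` (which are available in
    closed form through digamma/trigamma).  Returns ``(d0, s0^2)``; ``d0``
    is ``inf`` when the observed spread of log-variances is no wider than
    pure chi-squared noise, i.e. complete shrinkage.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_t(cohort: CohortDataset, moderation: bool = True) -> pd.DataFrame:
    """Per-gene two-group statistics with variance moderation.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (treated
    mean minus control mean), ``t_stat``, ``p_raw`` and ``residual_df``
    (the moderated degrees of freedom ``df + d0``).  With
    ``moderation=False`` the statistic is the ordinary pooled two-sample t.

    Genes with zero variance in both arms get ``t_stat = NaN`` and
    ``p_raw = 1`` when no shrinkage target exists; the fold change is
    still reported.
    """
    Xc = cohort.arm_values("control").to_numpy(dtype=float)
    Xt = cohort.arm_values("treated").to_numpy(dtype=float)
    n_c, n_t = Xc.shape[1], Xt.shape[1]
    if n_c < 2 or n_t < 2:
        raise SmallSampleError(
            f"cohort {cohort.cohort_id!r} has {n_c} control / {n_t} treated samples; "
            "need >= 2 per arm for a t-test (use fc_only mode)"
        )
    df = n_c + n_t - 2
    mc, mt = Xc.mean(axis=1), Xt.mean(axis=1)
    vc = Xc.var(axis=1, ddof=1)
    vt = Xt.var(axis=1, ddof=1)
    s2 = ((n_c - 1) * vc + (n_t - 1) * vt) / df
    log2fc = mt - mc

    if moderation:
        d0, s02 = fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            t_df = np.inf
        else:
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
            t_df = df + d0
    else:
        s2_post = s2
        t_df = float(df)

    se = np.sqrt(s2_post * (1.0 / n_c + 1.0 / n_t))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.nan)
    if np.isinf(t_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), t_df)
    p = np.where(np.isnan(t), 1.0, p)  # degenerate zero-variance genes

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t,
            "p_raw": p,
            "residual_df": t_df,
        },
        index=pd.Index(cohort.matrix.feature_ids, name="gene"),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(stats_frame: pd.DataFrame, mode: str = "auto") -> pd.DataFrame:
    """Apply the two-tier DEG thresholds to a per-gene statistics table.

    ``stats_frame`` must carry ``log2fc`` and, unless fold-change-only
    calling is intended, ``p_raw``; ``p_adj`` is computed here if absent.

    Modes
    -----
    stringent : ``p_adj <= 0.05`` and ``|log2fc| >= 1``.
    relaxed   : ``p_raw <= 0.05`` and ``|log2fc| >= 1`` (fallback tier).
    fc_only   : ``|log2fc| >= 1`` (one sample per arm; no test possible).
    auto      : stringent, falling back to relaxed when stringent yields
                zero DEGs, and to fc_only when p-values are unavailable.
    """
    if mode not in ("auto", "stringent", "relaxed", "fc_only"):
        raise ValueError(f"unknown DEG mode {mode!r}")
    out = stats_frame.copy()
    has_p = "p_raw" in out.columns and out["p_raw"].notna().any()
    if has_p and "p_adj" not in out.columns:
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())

    if mode == "auto":
        mode = "stringent" if has_p else "fc_only"
        if mode == "stringent":
            hits = (out["p_adj"] <= P_THRESHOLD) & (out["log2fc"].abs() >= LFC_THRESHOLD)
            if not hits.any():
                mode = "relaxed"

    big = out["log2fc"].abs() >= LFC_THRESHOLD
    if mode == "stringent":
        sig = big & (out["p_adj"] <= P_THRESHOLD)
    elif mode == "relaxed":
        sig = big & (out["p_raw"] <= P_THRESHOLD)
    else:  # fc_only
        sig = big
    out["deg_call"] = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig, "down", "none")
    )
    out["threshold_mode"] = mode
    return out


def run_de(
    cohort: CohortDataset, mode: str = "auto", moderation: bool = True
) -> pd.DataFrame:
    """Full single-cohort DE: statistics, BH correction, DEG calls.

    Cohorts with one sample in an arm cannot be tested; they get a
    fold-change-only table (``p_raw``/``p_adj`` undefined).
    """
    try:
        table = moderated_t(cohort, moderation=moderation)
    except SmallSampleError:
        if mode not in ("auto", "fc_only"):
            raise
        Xc = cohort.arm_values("control").to_numpy(dtype=float)
        Xt = cohort.arm_values("treated").to_numpy(dtype=float)
        table = pd.DataFrame(
            {
                "log2fc": Xt.mean(axis=1) - Xc.mean(axis=1),
                "t_stat": np.nan,
                "p_raw": np.nan,
                "residual_df": np.nan,
            },
            index=pd.Index(cohort.matrix.feature_ids, name="gene"),
        )
        return call_degs(table, mode="fc_only")
    return call_degs(table, mode=mode)


def count_shared_degs(
    deg_tables: Mapping[str, pd.DataFrame], min_cohorts: int
) -> pd.DataFrame:
    """Genes called DEG in at least ``min_cohorts`` cohorts.

    Genes are matched case-insensitively across cohorts (platforms disagree
    on symbol casing); the first-seen casing is reported.  Mixed directions
    are allowed and preserved per cohort.
    """
    if len(deg_tables) < 2:
        raise ValueError("need DEG tables from at least 2 cohorts")
    if min_cohorts > len(deg_tables):
        raise ValueError(
            f"min_cohorts={min_cohorts} exceeds the number of cohorts ({len(deg_tables)})"
        )
    display: dict[str, str] = {}
    calls: dict[str, dict[str, str]] = {}
    for cid, table in deg_tables.items():
        for gene, call in table["deg_call"].items():
            if call == "none":
                continue
            key = str(gene).upper()
            display.setdefault(key, str(gene))
            calls.setdefault(key, {})[cid] = call
    rows = []
    for key, per_cohort in calls.items():
        n = len(per_cohort)
        if n < min_cohorts:
            continue
        n_up = sum(1 for c in per_cohort.values() if c == "up")
        rows.append(
            {
                "gene": display[key],
                "n_cohorts_deregulated": n,
                "n_up": n_up,
                "n_down": n - n_up,
                "directions": ";".join(
                    f"{cid}:{call}" for cid, call in sorted(per_cohort.items())
                ),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene", "n_cohorts_deregulated", "n_up", "n_down", "directions"]
    )
    return out.sort_values(
        ["n_cohorts_deregulated", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
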
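"""Per-gene cross-cohort random-effects meta-analysis.

For every gene measured in enough cohorts: Hedges' adjusted g per cohort,
DerSimonian-Laird random-effects pooling with Cochran's Q heterogeneity,
directional Fisher's sum-of-logs p-value combination with BH FDR, signature
selection under effect-size and FDR thresholds, geometric-mean signature
scoring of held-out cohorts, and forest-plot data export.

Conventions
-----------
* Effects are standardized mean differences, treated minus control, with
  the small-sample correction J = 1 - 3/(4*df - 1) applied (Hedges' g).
* The sampling variance of g uses the common large-sample form
  ``(n_t + n_c)/(n_t * n_c) + g^2 / (2 (n_t + n_c))``.
* Per-cohort one-sided p-values are built from the normal approximation
  ``z = g / sqrt(var_g)``; ``p_up = 1 - Phi(z)``, ``p_down = Phi(z)``.
* BH is applied separately within the up- and down-direction families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_de import bh_adjust
from .preprocess import CohortDataset, ExpressionMatrix

#: Floor applied to per-cohort one-sided p-values before taking logs.
P_FLOOR = 1e-300


class ZeroVarianceError(ValueError):
    """Pooled within-arm variance is zero; no standardized effect exists."""


@dataclass(frozen=True)
class GeneEffect:
    """One gene in one cohort: Hedges' g and its sampling variance."""

    gene: str
    cohort: str
    g: float
    var_g: float
    n_t: int
    n_c: int

    def __post_init__(self) -> None:
        if self.var_g <= 0:
            raise ValueError("var_g must be positive")
        if self.n_t < 2 or self.n_c < 2:
            raise ValueError("Hedges' g needs >= 2 samples per arm")


@dataclass
class SignatureGeneSet:
    """Ordered signature members with direction and selection thresholds."""

    table: pd.DataFrame  # columns: gene, direction, es_pooled, fisher_fdr, k
    thresholds: tuple[float, float, int]  # (es_min, fdr_max, min_cohorts)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def directions(self) -> dict[str, str]:
        return dict(zip(self.table["gene"], self.table["direction"]))

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# elementary statistics (scalar API; run_meta uses the same formulas
# vectorized across genes)
# ---------------------------------------------------------------------------

def hedges_g(
    treated: Sequence[float],
    control: Sequence[float],
    gene: str = "",
    cohort: str = "",
) -> GeneEffect:
    """Hedges' adjusted g (treated minus control) with its variance.

    ``d = (mean_t - mean_c) / s_p`` with the df-weighted pooled SD,
    ``J = 1 - 3/(4 df - 1)`` with ``df = n_t + n_c - 2``, ``g = J d``.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    n_t, n_c = len(t), len(c)
    if n_t < 2 or n_c < 2:
        raise ValueError("need at least 2 values per arm")
    df = n_t + n_c - 2
    sp2 = ((n_t - 1) * t.var(ddof=1) + (n_c - 1) * c.var(ddof=1)) / df
    if sp2 <= 0:
        raise ZeroVarianceError(
            f"gene {gene!r} in cohort {cohort!r} has zero pooled variance"
        )
    d = (t.mean() - c.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    var_g = (n_t + n_c) / (n_t * n_c) + g * g / (2.0 * (n_t + n_c))
    return GeneEffect(gene=gene, cohort=cohort, g=float(g), var_g=float(var_g),
                      n_t=n_t, n_c=n_c)


def _check_variances(g: np.ndarray, v: np.ndarray) -> None:
    if np.any(v <= 0):
        raise ValueError("all effect variances must be positive")


def dl_pool(effects: Sequence[GeneEffect]) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooled estimate for one gene.

    Fixed-effects weights ``w_i = 1/var_i`` give Cochran's Q; the moment
    estimator ``tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1))`` with
    ``S1 = sum w``, ``S2 = sum w^2``; random-effects weights
    ``1/(var_i + tau^2)`` give the pooled effect and its SE.  A single
    effect is passed through with ``tau^2 = 0`` and a warning.
    """
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var_g for e in effects], dtype=float)
    _check_variances(g, v)
    if len(g) == 0:
        raise ValueError("no effects to pool")
    if len(g) == 1:
        warnings.warn("single-cohort gene: pooled effect is the lone effect",
                      stacklevel=2)
        return float(g[0]), float(np.sqrt(v[0])), 0.0
    es, se, tau2, _ = _dl_core(g[None, :], v[None, :])
    return float(es[0]), float(se[0]), float(tau2[0])


def cochran_q(effects: Sequence[GeneEffect]) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic and its chi-squared(k-1) p-value."""
    if len(effects) < 2:
        raise ValueError("Cochran's Q needs at least 2 cohorts")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var_g for e in effects], dtype=float)
    _check_variances(g, v)
    _, _, _, q = _dl_core(g[None, :], v[None, :])
    p = float(stats.chi2.sf(q[0], len(g) - 1))
    return float(q[0]), p


def one_sided_pvalues(effect: GeneEffect) -> tuple[float, float]:
    """Directional per-cohort p-values from ``z = g / sqrt(var_g)``.

    ``p_up + p_down = 1`` exactly; a zero effect gives (0.5, 0.5).
    """
    z = effect.g / np.sqrt(effect.var_g)
    p_up = float(stats.norm.sf(z))
    return p_up, 1.0 - p_up


def fisher_combine(
    p_values: Sequence[float], floor: float = P_FLOOR
) -> tuple[float, float]:
    """Fisher's sum of logs: ``X = -2 sum ln p_i ~ chi^2(2k)`` under the null."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(f"zero p-value clamped to {floor}", stacklevel=2)
        p = np.maximum(p, floor)
    x = float(-2.0 * np.sum(np.log(p)))
    return x, float(stats.chi2.sf(x, 2 * p.size))


def _dl_core(
    g: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized DL pooling over genes (rows); NaN entries mark missing
    cohorts.  Returns (es_pooled, se_pooled, tau2, Q)."""
    mask = np.isfinite(g) & np.isfinite(v)
    w = np.where(mask, 1.0 / np.where(mask, v, 1.0), 0.0)
    k = mask.sum(axis=1)
    sw = w.sum(axis=1)
    gw = np.where(mask, g, 0.0)
    mean_fixed = (w * gw).sum(axis=1) / sw
    q = (w * (gw - mean_fixed[:, None]) ** 2 * mask).sum(axis=1)
    s2 = (w**2).sum(axis=1)
    denom = sw - s2 / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(
            (k > 1) & (denom > 0), np.maximum(0.0, (q - (k - 1)) / denom), 0.0
        )
    w_star = np.where(mask, 1.0 / (np.where(mask, v, 1.0) + tau2[:, None]), 0.0)
    sw_star = w_star.sum(axis=1)
    es = (w_star * gw).sum(axis=1) / sw_star
    se = 1.0 / np.sqrt(sw_star)
    return es, se, tau2, q


# ---------------------------------------------------------------------------
# full per-gene meta-analysis across cohorts
# ---------------------------------------------------------------------------

def compute_effects(cohort: CohortDataset) -> pd.DataFrame:
    """Hedges' g and variance for every gene of one cohort (vectorized).

    Genes with zero pooled variance are excluded with a warning count.
    Returns a DataFrame indexed by gene with columns g, var_g, n_t, n_c.
    """
    Xc = cohort.arm_values("control").to_numpy(dtype=float)
    Xt = cohort.arm_values("treated").to_numpy(dtype=float)
    n_c, n_t = Xc.shape[1], Xt.shape[1]
    if n_c < 2 or n_t < 2:
        raise ValueError(
            f"cohort {cohort.cohort_id!r} is not eligible for meta-analysis "
            f"({n_c} control / {n_t} treated; need >= 2 per arm)"
        )
    df = n_c + n_t - 2
    sp2 = ((n_c - 1) * Xc.var(axis=1, ddof=1) + (n_t - 1) * Xt.var(axis=1, ddof=1)) / df
    ok = sp2 > 0
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"cohort {cohort.cohort_id}: {n_bad} zero-variance genes excluded",
            stacklevel=2,
        )
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (Xt.mean(axis=1) - Xc.mean(axis=1)) / np.sqrt(sp2)
    g = J * d
    var_g = (n_t + n_c) / (n_t * n_c) + g**2 / (2.0 * (n_t + n_c))
    frame = pd.DataFrame(
        {"g": g, "var_g": var_g, "n_t": n_t, "n_c": n_c},
        index=pd.Index(cohort.matrix.feature_ids, name="gene"),
    )
    return frame.loc[ok]


def run_meta(
    cohorts: Sequence[CohortDataset],
    min_cohorts_measured: int = 2,
    p_floor: float = P_FLOOR,
) -> pd.DataFrame:
    """Per-gene meta-analysis across cohorts.

    For every gene measured in at least ``min_cohorts_measured`` cohorts:
    per-cohort Hedges' g, DL pooling, Cochran's Q, and directional Fisher
    combination of one-sided normal-approximation p-values, with BH FDR
    applied separately to the up and down families across all genes.

    Cohort matrices must already be gene-level (probes collapsed); genes
    are matched case-insensitively, reporting the first-seen casing.
    """
    if min_cohorts_measured < 1:
        raise ValueError("min_cohorts_measured must be >= 1")
    per_cohort = {c.cohort_id: compute_effects(c) for c in cohorts}

    display: dict[str, str] = {}
    for eff in per_cohort.values():
        for gene in eff.index:
            display.setdefault(str(gene).upper(), str(gene))
    keys = sorted(display)
    key_pos = {g: i for i, g in enumerate(keys)}

    K, G = len(cohorts), len(keys)
    g_mat = np.full((G, K), np.nan)
    v_mat = np.full((G, K), np.nan)
    for j, cohort in enumerate(cohorts):
        eff = per_cohort[cohort.cohort_id]
        rows = np.array([key_pos[str(gene).upper()] for gene in eff.index])
        g_mat[rows, j] = eff["g"].to_numpy()
        v_mat[rows, j] = eff["var_g"].to_numpy()

    measured = np.isfinite(g_mat)
    k = measured.sum(axis=1)
    keep = k >= min_cohorts_measured
    if not keep.any():
        warnings.warn("no gene is measured in enough cohorts; empty meta result",
                      stacklevel=2)
    g_mat, v_mat, k = g_mat[keep], v_mat[keep], k[keep]
    kept_keys = [keys[i] for i in np.flatnonzero(keep)]

    es, se, tau2, q = _dl_core(g_mat, v_mat)
    q_p = np.where(k > 1, stats.chi2.sf(q, np.maximum(k - 1, 1)), np.nan)
    q = np.where(k > 1, q, np.nan)

    with np.errstate(invalid="ignore"):
        z = g_mat / np.sqrt(v_mat)
    p_up = stats.norm.sf(z)
    p_down = 1.0 - p_up
    p_up = np.clip(p_up, p_floor, 1.0)
    p_down = np.clip(p_down, p_floor, 1.0)
    mask = np.isfinite(z)
    x_up = -2.0 * np.nansum(np.where(mask, np.log(p_up), 0.0), axis=1)
    x_down = -2.0 * np.nansum(np.where(mask, np.log(p_down), 0.0), axis=1)
    fp_up = stats.chi2.sf(x_up, 2 * k)
    fp_down = stats.chi2.sf(x_down, 2 * k)

    result = pd.DataFrame(
        {
            "gene": [display[key] for key in kept_keys],
            "k": k,
            "es_pooled": es,
            "se_pooled": se,
            "tau2": tau2,
            "q_stat": q,
            "q_pvalue": q_p,
            "fisher_stat_up": x_up,
            "fisher_p_up": fp_up,
            "fisher_fdr_up": bh_adjust(fp_up) if len(fp_up) else fp_up,
            "fisher_stat_down": x_down,
            "fisher_p_down": fp_down,
            "fisher_fdr_down": bh_adjust(fp_down) if len(fp_down) else fp_down,
        }
    )
    return result.reset_index(drop=True)


def select_signature(
    meta: pd.DataFrame,
    es_min: float = 1.0,
    fdr_max: float = 0.05,
    min_cohorts: int = 5,
) -> SignatureGeneSet:
    """Genes passing |pooled ES| >= es_min and directional Fisher FDR <=
    fdr_max while measured in at least ``min_cohorts`` cohorts.

    Up- and down-direction members are selected symmetrically and ordered
    by their directional FDR, then by |pooled ES| descending.  An empty
    signature is a valid result.
    """
    measured = meta["k"] >= min_cohorts
    up = measured & (meta["es_pooled"] >= es_min) & (meta["fisher_fdr_up"] <= fdr_max)
    down = measured & (meta["es_pooled"] <= -es_min) & (meta["fisher_fdr_down"] <= fdr_max)
    rows = []
    for sel, direction, fdr_col in ((up, "up", "fisher_fdr_up"),
                                    (down, "down", "fisher_fdr_down")):
        sub = meta.loc[sel]
        for _, row in sub.iterrows():
            rows.append(
                {
                    "gene": row["gene"],
                    "direction": direction,
                    "es_pooled": row["es_pooled"],
                    "fisher_fdr": row[fdr_col],
                    "k": int(row["k"]),
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "direction", "es_pooled", "fisher_fdr", "k"])
    if len(table):
        table = table.assign(_abs=table["es_pooled"].abs()).sort_values(
            ["fisher_fdr", "_abs", "gene"], ascending=[True, False, True],
            kind="mergesort",
        ).drop(columns="_abs").reset_index(drop=True)
    return SignatureGeneSet(table=table, thresholds=(es_min, fdr_max, min_cohorts))


def geometric_mean_score(
    matrix: ExpressionMatrix,
    signature: SignatureGeneSet | Sequence[str],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample geometric-mean score of a gene signature.

    On log2 data the score is the arithmetic mean of the signature genes'
    log2 values, i.e. the log2 of the geometric mean on linear scale.
    Genes are matched case-insensitively; the number found is recorded in
    ``frame.attrs["n_genes_found"]``.  If ``groups`` is given, a per-group
    summary lands in ``frame.attrs["group_means"]``.
    """
    genes = signature.genes if isinstance(signature, SignatureGeneSet) else list(signature)
    wanted = {g.upper() for g in genes}
    present = [f for f in matrix.feature_ids if str(f).upper() in wanted]
    if not present:
        raise ValueError("no signature gene is present in the matrix")
    scores = matrix.data.loc[present].mean(axis=0)
    frame = pd.DataFrame({"sample_id": scores.index, "score": scores.to_numpy()})
    if groups is not None:
        frame["group"] = [groups.get(s) for s in frame["sample_id"]]
        frame.attrs["group_means"] = frame.groupby("group")["score"].mean().to_dict()
    frame.attrs["n_genes_found"] = len(present)
    return frame.reset_index(drop=True)


def forest_data(
    gene: str,
    effects: Sequence[GeneEffect],
    pooled: Mapping[str, float],
) -> pd.DataFrame:
    """Forest-plot rows for one gene: per-cohort CI and weight plus summary.

    ``pooled`` must be the gene's meta-analysis row (mapping with keys
    ``gene``, ``es_pooled``, ``se_pooled``, ``tau2``) computed from exactly
    these effects.  Weights are the normalized random-effects weights
    ``1/(var_g + tau^2)`` and sum to 1; 95% CIs use +/- 1.96 SE.
    """
    if not effects:
        raise ValueError("no effects given")
    if any(e.gene != gene for e in effects):
        raise ValueError("effects list contains a different gene")
    if str(pooled["gene"]).upper() != gene.upper():
        raise ValueError(
            f"pooled result is for gene {pooled['gene']!r}, not {gene!r}"
        )
    tau2 = float(pooled["tau2"])
    w = np.array([1.0 / (e.var_g + tau2) for e in effects])
    w = w / w.sum()
    rows = [
        {
            "cohort": e.cohort,
            "g": e.g,
            "ci_low": e.g - 1.96 * np.sqrt(e.var_g),
            "ci_high": e.g + 1.96 * np.sqrt(e.var_g),
            "weight": float(wi),
            "is_summary": False,
        }
        for e, wi in zip(effects, w)
    ]
    es, se = float(pooled["es_pooled"]), float(pooled["se_pooled"])
    rows.append(
        {
            "cohort": "POOLED",
            "g": es,
            "ci_low": es - 1.96 * se,
            "ci_high": es + 1.96 * se,
            "weight": 1.0,
            "is_summary": True,
        }
    )
    return pd.DataFrame(rows)
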
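"""Synthetic multi-cohort expression data with known ground truth.

Emulates the statistical structure of small two-arm microarray studies of
plasma-treated cancer cells: log2-intensity matrices from K cohorts with
heterogeneous sample sizes, multi-probe-per-gene redundancy, a planted set
of up-regulated genes with standardized effect sizes, optional
between-cohort effect heterogeneity (tau^2), and null genes.

The generator is the test bed for the whole pipeline: every planted
quantity (which genes carry an effect, the realized standardized shift per
gene and cohort) is recorded, so downstream estimates can be checked
against truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import PathwayCatalog
from .preprocess import CohortDataset, ExpressionMatrix

#: Probe-level measurement noise SD on log2 scale.  Small relative to
#: biological noise so probe collapsing matters but does not dominate.
PROBE_NOISE_SD = 0.1


@dataclass
class SyntheticConfig:
    """Parameters of the multi-cohort generator.

    The defaults describe the study conditions exercised throughout the
    test suite: five cohorts of 4 control + 4 treated samples, 1000 genes
    of which 50 carry a planted standardized up-shift of ``delta = 2``
    within-arm SDs, no between-cohort heterogeneity, and 3 probes per gene.

    Parameters
    ----------
    n_cohorts : number of independent studies.
    per_cohort_n : (n_control, n_treated) per cohort; defaults to (4, 4)
        everywhere.  Real cohorts range from 1 to 16 samples per arm.
    n_genes : genes per cohort.
    n_signature : number of planted differentially expressed genes.
    delta : planted standardized mean shift (within-arm SD units).
    tau2 : between-cohort variance of the planted effect.
    probes_per_gene : platform redundancy; int or one int per gene.
    baseline_mean, baseline_sd : location/spread of per-gene baseline
        log2 intensity (typical microarray values near 7 +/- 1.5).
    var_prior_df, var_prior_scale : the per-gene noise variance is drawn
        as ``var_prior_df * var_prior_scale / chi2(var_prior_df)`` — a
        scaled inverse-chi-squared spread that makes variance moderation
        non-trivial.  ``var_prior_scale`` is the typical variance
        (0.25, i.e. SD 0.5 on log2 scale).
    mixed_directions : if True, half of the planted genes are shifted
        down instead of up (exercises the down-direction Fisher branch).
    cohort_probe_dropout : probability that a probe is missing from a
        given cohort's platform (exercises missing-gene handling).
    seed : RNG seed; same config + seed is bit-identical.
    """

    n_cohorts: int = 5
    per_cohort_n: Sequence[tuple[int, int]] | None = None
    n_genes: int = 1000
    n_signature: int = 50
    delta: float = 2.0
    tau2: float = 0.0
    probes_per_gene: int | Sequence[int] = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    var_prior_df: float = 10.0
    var_prior_scale: float = 0.25
    mixed_directions: bool = False
    cohort_probe_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_cohort_n is None:
            self.per_cohort_n = [(4, 4)] * self.n_cohorts
        self.validate()

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be a positive integer")
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if not 0 <= self.n_signature <= self.n_genes:
            raise ValueError("n_signature must satisfy 0 <= n_signature <= n_genes")
        if len(self.per_cohort_n) != self.n_cohorts:
            raise ValueError("per_cohort_n must list one (n_control, n_treated) pair per cohort")
        for pair in self.per_cohort_n:
            if len(pair) != 2 or pair[0] < 1 or pair[1] < 1:
                raise ValueError(f"per_cohort_n entry {pair} must have both arms >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if isinstance(self.probes_per_gene, int):
            if self.probes_per_gene < 1:
                raise ValueError("probes_per_gene must be a positive integer")
        else:
            if len(self.probes_per_gene) != self.n_genes or any(
                p < 1 for p in self.probes_per_gene
            ):
                raise ValueError("probes_per_gene list must give a positive count per gene")
        if not 0 <= self.cohort_probe_dropout < 1:
            raise ValueError("cohort_probe_dropout must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted truth: which genes carry an effect and its realized size.

    ``per_cohort_effects`` holds one row per (signature gene, cohort) with
    the realized standardized effect; every other (gene, cohort) pair has
    a true effect of exactly 0 and is not stored — use :meth:`effect_of`.
    """

    signature_genes: frozenset[str]
    per_cohort_effects: pd.DataFrame  # columns: gene_symbol, cohort_id, true_effect

    def effect_of(self, gene: str, cohort_id: str) -> float:
        if gene not in self.signature_genes:
            return 0.0
        sel = self.per_cohort_effects[
            (self.per_cohort_effects["gene_symbol"] == gene)
            & (self.per_cohort_effects["cohort_id"] == cohort_id)
        ]
        return float(sel["true_effect"].iloc[0]) if len(sel) else 0.0


@dataclass
class MultiCohortSim:
    """Everything the generator produced for one configuration."""

    cohorts: list[CohortDataset]
    truth: GroundTruth
    probe_map: dict[str, str]
    latent: dict[str, pd.DataFrame]  # cohort_id -> gene-level matrix (no probe noise)
    config: SyntheticConfig


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_multicohort(config: SyntheticConfig) -> MultiCohortSim:
    """Generate K two-arm cohorts on log2 scale with planted effects.

    For each cohort k and signature gene g, treated samples are shifted by
    ``delta_{g,k} * sigma_g`` where ``delta_{g,k} ~ Normal(delta, tau2)``
    (or ``-delta`` for the down half when ``mixed_directions``).  Null
    genes are identically distributed in both arms.  Each gene is emitted
    as ``probes_per_gene`` probe rows: the gene value plus independent
    Normal(0, 0.1^2) probe noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = _gene_ids(G)

    sig_idx = np.sort(rng.choice(G, size=config.n_signature, replace=False))
    sig_genes = [genes[i] for i in sig_idx]
    directions = np.ones(config.n_signature)
    if config.mixed_directions and config.n_signature:
        flip = rng.random(config.n_signature) < 0.5
        directions[flip] = -1.0

    # per-gene baseline and noise SD, shared across cohorts (same biology)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, G)
    sigma2 = (
        config.var_prior_df
        * config.var_prior_scale
        / rng.chisquare(config.var_prior_df, G)
    )
    sigma = np.sqrt(sigma2)

    if isinstance(config.probes_per_gene, int):
        ppg = np.full(G, config.probes_per_gene, dtype=int)
    else:
        ppg = np.asarray(config.probes_per_gene, dtype=int)
    probe_ids = [f"{g}_P{j + 1}" for g, k in zip(genes, ppg) for j in range(k)]
    probe_gene = np.repeat(np.arange(G), ppg)
    probe_map = {p: genes[i] for p, i in zip(probe_ids, probe_gene)}

    cohorts: list[CohortDataset] = []
    latent: dict[str, pd.DataFrame] = {}
    truth_rows: list[tuple[str, str, float]] = []

    for k, (n_c, n_t) in enumerate(config.per_cohort_n):
        cid = f"cohort{k + 1:02d}"
        n = n_c + n_t
        sample_ids = [f"{cid}_C{i + 1}" for i in range(n_c)] + [
            f"{cid}_T{i + 1}" for i in range(n_t)
        ]
        groups = {s: ("control" if i < n_c else "treated") for i, s in enumerate(sample_ids)}

        X = mu[:, None] + sigma[:, None] * rng.standard_normal((G, n))
        delta_gk = directions * rng.normal(config.delta, np.sqrt(config.tau2),
                                           config.n_signature)
        X[sig_idx, n_c:] += (delta_gk * sigma[sig_idx])[:, None]
        truth_rows += [(g, cid, float(d)) for g, d in zip(sig_genes, delta_gk)]

        gene_frame = pd.DataFrame(X, index=genes, columns=sample_ids)
        latent[cid] = gene_frame

        P = X[probe_gene] + PROBE_NOISE_SD * rng.standard_normal((len(probe_ids), n))
        probe_frame = pd.DataFrame(P, index=probe_ids, columns=sample_ids)
        if config.cohort_probe_dropout > 0:
            keep = rng.random(len(probe_ids)) >= config.cohort_probe_dropout
            probe_frame = probe_frame.loc[keep]
        cohorts.append(
            CohortDataset(
                matrix=ExpressionMatrix(probe_frame, scale="log2"),
                groups=groups,
                cohort_id=cid,
            )
        )

    truth = GroundTruth(
        signature_genes=frozenset(sig_genes),
        per_cohort_effects=pd.DataFrame(
            truth_rows, columns=["gene_symbol", "cohort_id", "true_effect"]
        ),
    )
    return MultiCohortSim(
        cohorts=cohorts, truth=truth, probe_map=probe_map, latent=latent, config=config
    )


def write_fixture(
    sim: MultiCohortSim, directory: str | Path, create: bool = False
) -> dict[str, str]:
    """Write a simulated study to disk in the pipeline's TSV dialects.

    Emits, per cohort, an expression TSV (probes x samples) and a phenotype
    TSV, plus one shared probe-map TSV and one ground-truth TSV.  Returns a
    manifest of the written paths.  The directory must already exist unless
    ``create=True``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        if create:
            directory.mkdir(parents=True)
        else:
            raise FileNotFoundError(f"fixture directory does not exist: {directory}")

    manifest: dict[str, str] = {}
    for cohort in sim.cohorts:
        expr_path = directory / f"{cohort.cohort_id}_expression.tsv"
        frame = cohort.matrix.data.copy()
        frame.index.name = "probe_id"
        frame.to_csv(expr_path, sep="\t")
        manifest[f"{cohort.cohort_id}:expression"] = str(expr_path)

        pheno_path = directory / f"{cohort.cohort_id}_phenotype.tsv"
        pd.DataFrame(
            {
                "sample_id": cohort.matrix.sample_ids,
                "group": [cohort.groups[s] for s in cohort.matrix.sample_ids],
            }
        ).to_csv(pheno_path, sep="\t", index=False)
        manifest[f"{cohort.cohort_id}:phenotype"] = str(pheno_path)

    map_path = directory / "probe_map.tsv"
    pd.DataFrame(
        {"probe_id": list(sim.probe_map), "gene_symbol": list(sim.probe_map.values())}
    ).to_csv(map_path, sep="\t", index=False)
    manifest["probe_map"] = str(map_path)

    truth_path = directory / "ground_truth.tsv"
    sim.truth.per_cohort_effects.to_csv(truth_path, sep="\t", index=False)
    manifest["ground_truth"] = str(truth_path)
    return manifest


def make_toy_catalog(
    signature_genes: Sequence[str],
    universe_genes: Sequence[str],
    n_null_sets: int = 20,
    set_size: int = 25,
    seed: int = 0,
    planted_id: str = "PW_PLANT",
) -> PathwayCatalog:
    """A small pathway catalog whose first set is the planted signature.

    The remaining ``n_null_sets`` sets are random draws from the universe.
    A two-root hierarchy is attached (the planted pathway sits under
    ``ROOT_A``, null sets alternate between the two roots) so ancestor
    roll-up can be exercised end to end.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe_genes)
    sets: dict[str, tuple[str, frozenset[str]]] = {
        planted_id: ("planted signature pathway", frozenset(signature_genes))
    }
    hierarchy: list[tuple[str, str]] = [(planted_id, "ROOT_A")]
    for i in range(n_null_sets):
        pid = f"PW_NULL{i + 1:02d}"
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets[pid] = (f"random set {i + 1}", frozenset(members.tolist()))
        hierarchy.append((pid, "ROOT_A" if i % 2 == 0 else "ROOT_B"))
    return PathwayCatalog(sets=sets, hierarchy=hierarchy)
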
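"""Orchestration of the simulation study and the generic table mode.

``run_condition`` applies both methods — the linear-FA baseline and the
VAE — to one simulated dataset and produces per-item loading tables
(link fits at the generating family, plus data-driven link
classification), score-recovery reports, and a summary row.
``run_benchmark`` sweeps the six study conditions across replicate seeds;
``run_generic`` applies the same machinery to any delimited numeric table
without ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fa_baseline, link_fit, metrics, vae
from .simulate import (
    BENCHMARK_CONDITIONS,
    MeasurementSpec,
    SimulatedDataset,
    make_spec,
    simulate_dataset,
)

__all__ = [
    "ExperimentConfig",
    "MethodResult",
    "ConditionResult",
    "run_condition",
    "run_benchmark",
    "run_generic",
    "read_table",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved configuration of a study run."""

    n_subjects: int = 1000
    n_replicates: int = 5
    master_seed: int = 0
    vae: vae.VAEConfig = field(default_factory=vae.VAEConfig)
    score_method: str = "bartlett"  # or "regression"
    recon_mode: str = "mean"  # VAE reconstruction for metrics/fits ("sampled" = diagnostic)
    link_intercept: bool = False  # free intercept in link fits
    dip_boot: int = 0  # Monte-Carlo draws for the bimodality flag (0 = off)
    standardize: bool = True  # generic mode only
    outdir: str | None = None

    def replicate_seeds(self) -> list[int]:
        ss = np.random.SeedSequence([self.master_seed, 0xBE7C])
        return [int(s % 2**31) for s in ss.generate_state(self.n_replicates)]


@dataclass
class MethodResult:
    """One method's output on one dataset."""

    method: str  # "fa" | "vae"
    est_scores: np.ndarray
    reconstructed: np.ndarray
    report: metrics.RecoveryReport | None  # None when truth is unknown
    link_table: pd.DataFrame  # fits at the requested family
    classified: pd.DataFrame  # data-driven family choice
    explained_variance: float
    density: metrics.DensitySummary
    detail: object  # FactorSolution or VAESolution


@dataclass
class ConditionResult:
    name: str
    seed: int
    fa: MethodResult
    vae: MethodResult

    def summary_rows(self) -> list[dict]:
        rows = []
        for m in (self.fa, self.vae):
            rows.append(
                {
                    "condition": self.name,
                    "seed": self.seed,
                    "method": m.method,
                    "mae": m.report.mae if m.report else np.nan,
                    "rmse": m.report.rmse if m.report else np.nan,
                    "explained_variance": m.explained_variance,
                }
            )
        return rows


def _link_tables(
    scores_hat: np.ndarray,
    recon: np.ndarray,
    spec: MeasurementSpec | None,
    with_intercept: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-item link fits at the generating family plus classification."""
    scores_hat = np.atleast_2d(np.asarray(scores_hat, dtype=float).T).T
    p = recon.shape[1]
    fit_rows, cls_rows = [], []
    for j in range(p):
        if spec is not None:
            fac = spec.items[j].factor_index
            family = spec.items[j].link
        else:
            fac, family = 0, "linear"
        s = scores_hat[:, fac]
        res = link_fit.fit_link(s, recon[:, j], family, j, with_intercept)
        cls = link_fit.classify_link(s, recon[:, j], j, with_intercept)
        fit_rows.append(
            {
                "item": j + 1,
                "family": res.family,
                "loading": res.loading_hat,
                "se": res.loading_se,
                "converged": res.converged,
                "sse": res.sse,
            }
        )
        cls_rows.append(
            {
                "item": j + 1,
                "family": cls.family,
                "loading": cls.loading_hat,
                "se": cls.loading_se,
                "converged": cls.converged,
                "delta_aicc": cls.delta_aicc,
            }
        )
    return pd.DataFrame(fit_rows), pd.DataFrame(cls_rows)


def _run_fa(
    responses: np.ndarray,
    n_factors: int,
    spec: MeasurementSpec | None,
    true_scores: np.ndarray | None,
    config: ExperimentConfig,
) -> MethodResult:
    ref = spec.loadings if spec is not None else None
    sol = fa_baseline.fit_fa(responses, n_factors, reference_loadings=ref)
    sol = fa_baseline.estimate_scores(sol, responses, method=config.score_method)
    recon = fa_baseline.reconstruct(sol)
    ev = metrics.explained_variance(responses, recon)
    report = None
    if true_scores is not None:
        report = metrics.score_recovery(
            true_scores,
            sol.est_scores,
            explained_variance=ev,
            explained_variance_per_item=tuple(
                metrics.explained_variance_per_item(responses, recon)
            ),
        )
    density = metrics.density_summary(sol.est_scores, dip_boot=config.dip_boot)
    fit_table, cls_table = _link_tables(
        sol.est_scores, recon, spec, config.link_intercept
    )
    return MethodResult(
        method="fa",
        est_scores=sol.est_scores,
        reconstructed=recon,
        report=report,
        link_table=fit_table,
        classified=cls_table,
        explained_variance=ev,
        density=density,
        detail=sol,
    )


def _run_vae(
    responses: np.ndarray,
    n_factors: int,
    spec: MeasurementSpec | None,
    true_scores: np.ndarray | None,
    config: ExperimentConfig,
    seed: int,
) -> MethodResult:
    vconf = dataclasses.replace(
        config.vae,
        n_items=responses.shape[1],
        latent_dim=n_factors,
        seed=int(seed),
    )
    sol = vae.train(responses, vconf)
    scores_hat = vae.encode_scores(sol, responses, reference=true_scores)
    recon = vae.reconstruct(sol, mode=config.recon_mode)
    ev = metrics.explained_variance(responses, recon)
    report = None
    if true_scores is not None:
        report = metrics.score_recovery(
            true_scores,
            scores_hat,
            explained_variance=ev,
            explained_variance_per_item=tuple(
                metrics.explained_variance_per_item(responses, recon)
            ),
        )
    density = metrics.density_summary(scores_hat, dip_boot=config.dip_boot)
    fit_table, cls_table = _link_tables(
        scores_hat, recon, spec, config.link_intercept
    )
    return MethodResult(
        method="vae",
        est_scores=scores_hat,
        reconstructed=recon,
        report=report,
        link_table=fit_table,
        classified=cls_table,
        explained_variance=ev,
        density=density,
        detail=sol,
    )


def run_condition(dataset: SimulatedDataset, config: ExperimentConfig) -> ConditionResult:
    """Both methods on one simulated dataset, with ground-truth scoring."""
    spec = dataset.spec
    fa_res = _run_fa(
        dataset.responses, spec.n_factors, spec, dataset.true_scores, config
    )
    vae_res = _run_vae(
        dataset.responses, spec.n_factors, spec, dataset.true_scores, config,
        seed=dataset.seed,
    )
    return ConditionResult(
        name=dataset.name or "condition", seed=dataset.seed, fa=fa_res, vae=vae_res
    )


def run_benchmark(config: ExperimentConfig) -> tuple[pd.DataFrame, list[ConditionResult]]:
    """The six-condition matrix across replicate seeds.

    Returns a long-format summary (one row per condition x seed x method)
    and the full per-run results.  Mean and standard deviation across seeds
    are written alongside when an output directory is configured.
    """
    rows, results = [], []
    for rep_seed in config.replicate_seeds():
        for i, (cname, n_fac, n_sig) in enumerate(BENCHMARK_CONDITIONS):
            spec = make_spec(n_factors=n_fac, n_sigmoid_per_factor=n_sig)
            ds_seed = int(
                np.random.SeedSequence([rep_seed, i]).generate_state(1)[0] % 2**31
            )
            ds = simulate_dataset(spec, config.n_subjects, seed=ds_seed, name=cname)
            res = run_condition(ds, config)
            results.append(res)
            rows.extend(res.summary_rows())
    summary = pd.DataFrame(rows)
    if config.outdir:
        _write_benchmark(summary, results, Path(config.outdir))
    return summary, results


def _write_benchmark(summary: pd.DataFrame, results: list[ConditionResult], outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "summary_runs.csv", index=False)
    agg = (
        summary.groupby(["condition", "method"])[["mae", "rmse", "explained_variance"]]
        .agg(["mean", "std"])
    )
    agg.columns = ["_".join(c) for c in agg.columns]
    agg.reset_index().to_csv(outdir / "summary_aggregate.csv", index=False)
    # per-item tables for the first replicate only (results are in
    # replicate-major order)
    for res in results[: len(BENCHMARK_CONDITIONS)]:
        for m in (res.fa, res.vae):
            m.link_table.to_csv(
                outdir / f"{res.name}_{m.method}_link_fits.csv", index=False
            )
            m.classified.to_csv(
                outdir / f"{res.name}_{m.method}_link_classified.csv", index=False
            )


def read_table(table_path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited numeric table, reporting offending cells precisely."""
    df = pd.read_csv(table_path, delimiter=delimiter)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {r + 1}, column {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {r + 1}, column {df.columns[c]!r}")
    return numeric


def run_generic(
    table_path: str | Path,
    n_factors: int,
    config: ExperimentConfig | None = None,
) -> ConditionResult:
    """Both methods on an arbitrary subjects-by-items table.

    Columns are standardized before VAE training (configurable); item
    reconstructions are mapped back to the original units before link
    fitting so that the bounded sigmoid family keeps its natural scale.
    There are no true scores, so recovery metrics are skipped; the VAE
    latent axes are aligned against the first principal axes.
    """
    config = config or ExperimentConfig(
        vae=vae.VAEConfig(hidden_units=8), link_intercept=True
    )
    df = read_table(table_path)
    x = df.to_numpy(dtype=float)
    if n_factors >= x.shape[1]:
        raise ValueError(
            f"n_factors ({n_factors}) must be smaller than the number of items "
            f"({x.shape[1]})"
        )
    if config.standardize:
        mu, sd = x.mean(axis=0), x.std(axis=0)
        if np.any(sd == 0):
            dead = ", ".join(df.columns[sd == 0])
            raise ValueError(f"constant column(s): {dead}")
        xs = (x - mu) / sd
    else:
        mu, sd = np.zeros(x.shape[1]), np.ones(x.shape[1])
        xs = x

    fa_res = _run_fa(xs, n_factors, None, None, config)
    vae_res = _run_vae(xs, n_factors, None, None, config, seed=config.master_seed)
    # back to original units for link fitting and reporting
    for m in (fa_res, vae_res):
        m.reconstructed = m.reconstructed * sd + mu
        fit_table, cls_table = _link_tables(
            m.est_scores, m.reconstructed, None, config.link_intercept
        )
        m.link_table, m.classified = fit_table, cls_table
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        side_by_side = pd.DataFrame(
            {
                "item": df.columns,
                "fa_loading": fa_res.link_table["loading"],
                "fa_se": fa_res.link_table["se"],
                "vae_loading": vae_res.link_table["loading"],
                "vae_se": vae_res.link_table["se"],
                "vae_family": vae_res.classified["family"],
            }
        )
        side_by_side.to_csv(out / "generic_loadings.csv", index=False)
        vae_res.classified.to_csv(out / "generic_link_classified.csv", index=False)
    return ConditionResult(
        name=Path(table_path).stem, seed=config.master_seed, fa=fa_res, vae=vae_res
    )
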
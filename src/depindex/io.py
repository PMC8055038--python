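"""Readers/writers, run configuration, and the end-to-end pipeline.

One command (or one :func:`run_pipeline` call) takes a cohort CSV — or a
synthetic-cohort request — through preprocessing, optional
variable-selection diagnostics, pooled and hierarchical IRT fits, WAIC
comparison, ICC and index exports, and the outcome analysis, writing every
stage artifact plus a JSON run report. All randomness descends from one
master seed via per-stage child seeds, so identical config + seed gives
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, irt, outcome, preprocess, synthetic, varselect
from .containers import ItemResponseMatrix
from ._util import child_seed

__all__ = ["RunConfig", "read_cohort", "write_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "province")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV: requires id and province; empty strings -> missing;
    duplicate ids rejected; unknown columns carried through."""
    df = pd.read_csv(path, dtype={"id": str, "province": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required column(s): {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in cohort file")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def frame_to_matrix(
    df: pd.DataFrame, items: list[str] | None = None
) -> tuple[ItemResponseMatrix, pd.Series | None]:
    """Interpret an already-dichotomized cohort frame (0/1/empty items)."""
    idx = pd.Index(df["id"].astype(str), name="id")
    item_cols = (
        items
        if items is not None
        else [c for c in df.columns if c not in ("id", "province", "outcome")]
    )
    resp = df[item_cols].apply(pd.to_numeric, errors="coerce")
    resp.index = idx
    X = ItemResponseMatrix(resp, pd.Series(df["province"].to_numpy(), index=idx))
    y = None
    if "outcome" in df.columns:
        y = pd.Series(pd.to_numeric(df["outcome"], errors="coerce").to_numpy(), index=idx)
    return X, y


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of input_path / synthetic."""

    output_dir: str
    seed: int
    input_path: str | None = None
    synthetic: bool = False
    items: list[str] = field(default_factory=lambda: list(synthetic.PAPER9_ITEMS))
    min_province_n: int = preprocess.DEFAULT_MIN_PROVINCE_N
    run_varselect: bool = True
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    chains: int = 4
    prior_sd_outcome: float = 2.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if bool(self.input_path) == bool(self.synthetic):
            raise ValueError("exactly one of input_path / synthetic must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def mcmc(self) -> irt.McmcConfig:
        return irt.McmcConfig(
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            chains=self.chains,
            seed=child_seed(self.seed, "mcmc"),
        )


def _export_icc(draws: irt.PosteriorDraws, path: Path) -> None:
    frames = []
    provinces = list(draws.province_labels) + ["overall"]
    if draws.province_labels == ["pooled"]:
        provinces = ["overall"]
    for item in draws.item_labels:
        for prov in provinces:
            frames.append(evaluation.icc_curve(draws, item, prov).to_frame())
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        report["stages"].append(name)

    try:
        # ---- input -------------------------------------------------------
        stage("input")
        if config.synthetic:
            cohort_cfg = synthetic.default_config(
                seed=child_seed(config.seed, "synthetic")
            )
            X_all, y_all, truth = synthetic.simulate_cohort(cohort_cfg)
            y_all = pd.Series(y_all, index=X_all.responses.index)
            write_cohort(
                X_all.to_frame(outcome=y_all), out / "cohort_synthetic.csv"
            )
            truth_frame = truth.theta_frame(X_all.responses.index, X_all.province)
            truth_frame.to_csv(out / "truth_theta.csv", index=False)
        else:
            df = read_cohort(config.input_path)
            X_all, y_all = frame_to_matrix(df)

        # ---- preprocess --------------------------------------------------
        stage("preprocess")
        X_f, prov_report = preprocess.filter_small_provinces(
            X_all, config.min_province_n
        )
        X_cc, cc_report = preprocess.complete_cases(X_f, config.items)
        exclusions = {
            "n_input": prov_report.n_input,
            "n_after_province_filter": prov_report.n_after_province_filter,
            "excluded_provinces": prov_report.excluded_provinces,
            "n_complete": cc_report.n_complete,
            "per_item_missing": cc_report.per_item_missing,
        }
        report["exclusions"] = exclusions

        # ---- variable selection diagnostics ------------------------------
        if config.run_varselect:
            stage("varselect")
            X_vs, _ = preprocess.complete_cases(X_f)  # all candidates
            chi2 = varselect.pairwise_chi2(X_vs)
            mca_sol = varselect.mca(X_vs)
            sel = varselect.selection_report(chi2, mca_sol, config.items)
            (out / "selection_report.json").write_text(json.dumps(sel, indent=2))
            varselect.chi2_matrix(chi2, X_vs.items).to_csv(out / "chi2_matrix.csv")
            mca_sol.coordinates_frame().to_csv(
                out / "mca_coordinates.csv", index=False
            )
            report["selection_report"] = str(out / "selection_report.json")

        # ---- IRT fits ----------------------------------------------------
        mcmc = config.mcmc()
        K = len(X_cc.provinces)
        variants = ["pooled", "hierarchical"]
        if K < 2:
            logger.warning(
                "single province after filtering; hierarchical fit falls back to pooled"
            )
            variants = ["pooled"]
        fits: dict[str, irt.PosteriorDraws] = {}
        waics: dict[str, evaluation.WaicResult] = {}
        for variant in variants:
            stage(f"fit-{variant}")
            draws, diag = irt.fit(X_cc, irt.IrtModelSpec(variant=variant), mcmc)
            fits[variant] = draws
            waics[variant] = evaluation.waic_from_fit(draws, X_cc)
            report[f"diagnostics_{variant}"] = {
                "max_rhat": diag.max_rhat,
                "min_ess": diag.min_ess,
            }
        report["waic"] = {v: w.to_dict() for v, w in waics.items()}
        if len(variants) == 2:
            cmp = evaluation.compare_waic(waics["hierarchical"], waics["pooled"])
            report["waic_comparison"] = cmp
            chosen = "hierarchical" if cmp["preferred"] == "a" else "pooled"
        else:
            chosen = variants[0]
        report["chosen_model"] = chosen
        draws = fits[chosen]

        # ---- exports -----------------------------------------------------
        stage("exports")
        index_df = irt.posterior_index(draws)
        index_df.to_csv(out / "index_summary.csv", index=False)
        _export_icc(draws, out / "icc_curves.csv")
        evaluation.discrimination_table(draws).to_csv(
            out / "discrimination_table.csv", index=False
        )
        report["index_summary"] = str(out / "index_summary.csv")

        # ---- outcome analysis -------------------------------------------
        if y_all is not None:
            stage("outcome")
            y_cc = y_all.reindex(X_cc.responses.index)
            keep = y_cc.notna().to_numpy()
            yv = y_cc.to_numpy(dtype=float)[keep]
            idx_vals = index_df["theta_mean"].to_numpy()[keep]
            comps = X_cc.responses.loc[keep]
            out_mcmc = irt.McmcConfig(
                iterations=6000,
                burn_in=2000,
                thin=1,
                chains=2,
                seed=child_seed(config.seed, "outcome"),
            )
            uni = outcome.univariable_table(
                yv,
                pd.DataFrame({"index_score": idx_vals}).join(
                    comps.reset_index(drop=True)
                ),
                config.prior_sd_outcome,
                out_mcmc,
            )
            multi = outcome.bayes_logistic(
                yv, comps, config.prior_sd_outcome, out_mcmc
            )
            multi_tab = multi.or_summary().assign(analysis="multivariable")
            pd.concat([uni, multi_tab], ignore_index=True).to_csv(
                out / "outcome_or_table.csv", index=False
            )
            cmp_out = outcome.compare_index_vs_components(
                yv, idx_vals, comps, config.prior_sd_outcome, out_mcmc
            )
            (out / "outcome_comparison.json").write_text(
                json.dumps(cmp_out, indent=2)
            )
            report["outcome_comparison"] = cmp_out

        report["status"] = "ok"
    except Exception as err:
        report["status"] = "failed"
        report["failed_stage"] = report["stages"][-1] if report["stages"] else None
        report["error"] = str(err)
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
        raise
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
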
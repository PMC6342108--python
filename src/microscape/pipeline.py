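"""End-to-end analysis pipeline: popgen -> clustering -> IBD -> resistance
optimization -> bootstrap selection -> home range.

Stages run in the study's order, each writing its table to the report
directory as CSV; a machine-readable ``summary.json`` collects the headline
numbers and every seed used.  Landscape-genetics stages operate on the
pruned ("unrelated") dataset unless pruning is disabled, in which case the
run log says so prominently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import kmeans_bic_scan
from .ga import GaConfig
from .genotypes import GenotypeTable
from .homerange import TelemetryTrack, activity_metrics, kde_homerange, mwu_test, overlap_matrix
from .ibd import mantel_correlogram, mantel_test
from .mlpe import information_criteria
from .optimize import (
    ResistanceOptimizer,
    bootstrap_selection,
    candidates_from_models,
    spearman_filter,
)
from .popgen import PairwiseMatrix, allele_frequencies, diversity_summary, dps_matrix, hwe_test_all_loci
from .relatedness import calls_to_frame, classify_all_dyads, prune_first_order
from .surfaces import GridSurface

logger = logging.getLogger("microscape")


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "report"
    master_seed: int = 42
    prune_relatives: bool = True
    hwe_reps: int = 10_000
    k_max: int = 8
    mantel_permutations: int = 1000
    correlogram_class_width: float = 50.0
    ga: GaConfig = field(default_factory=GaConfig)
    bootstrap_iterations: int = 500
    bootstrap_fraction: float = 0.75
    spearman_threshold: float = 0.29
    isopleth_level: float = 0.95
    optimize_surfaces: bool = True
    max_composites: int = 3

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed expanded from the master seed."""
        h = np.random.default_rng([self.master_seed, abs(hash(stage)) % 2**31])
        return int(h.integers(0, 2**31 - 1))


def run_pipeline(
    cfg: AnalysisConfig,
    genotypes: GenotypeTable,
    surfaces: dict[str, GridSurface],
    telemetry: list[TelemetryTrack] | None = None,
) -> dict:
    """Run every stage; returns the machine-readable summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seeds": {}, "version": __version__, "stages": []}

    def stage(name: str):
        summary["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("diversity")
        div = diversity_summary(genotypes)
        div.to_csv(out / "diversity.csv")
        summary["diversity"] = {
            "mean_Ho": div.mean_Ho, "mean_uHe": div.mean_uHe,
            "mean_Na": div.mean_Na, "mean_Ne": div.mean_Ne,
            "overall_FIS": div.overall_FIS,
        }

        stage("hwe")
        seed = cfg.stage_seed("hwe")
        summary["seeds"]["hwe"] = seed
        hwe = hwe_test_all_loci(genotypes, reps=cfg.hwe_reps, seed=seed)
        hwe.to_csv(out / "hwe.csv", index=False)

        stage("relatedness")
        freqs = allele_frequencies(genotypes)
        calls = classify_all_dyads(genotypes, freqs)
        calls_to_frame(calls).to_csv(out / "relationships.csv", index=False)
        n_first_order = sum(c.first_order for c in calls)
        summary["n_first_order_dyads"] = n_first_order

        stage("prune")
        if cfg.prune_relatives:
            pruned, removed = prune_first_order(genotypes, calls)
            summary["removed_individuals"] = removed
        else:
            logger.warning(
                "PRUNING DISABLED: landscape stages use the full dataset "
                "including first-order relatives"
            )
            pruned, removed = genotypes, []
        summary["n_individuals_unrelated"] = pruned.n_individuals

        stage("dps")
        dps = dps_matrix(pruned)
        dps.to_csv(out / "dps.csv")

        stage("clustering")
        seed = cfg.stage_seed("clustering")
        summary["seeds"]["clustering"] = seed
        k_max = min(cfg.k_max, pruned.n_individuals - 1)
        scan = kmeans_bic_scan(pruned, K_max=k_max, seed=seed)
        scan.to_frame().to_csv(out / "bic_by_k.csv", index=False)
        summary["best_K"] = scan.best_K

        has_coords = pruned.x is not None and pruned.y is not None
        if has_coords:
            stage("mantel")
            seed = cfg.stage_seed("mantel")
            summary["seeds"]["mantel"] = seed
            euclid = PairwiseMatrix.from_coords(
                pruned.individual_ids, pruned.x, pruned.y
            )
            mt = mantel_test(dps, euclid, n_perm=cfg.mantel_permutations,
                             seed=seed)
            summary["mantel"] = {"r": mt.r, "p": mt.p}
            correlog = mantel_correlogram(
                dps, pruned.coords(), class_width=cfg.correlogram_class_width,
                n_perm=cfg.mantel_permutations,
                seed=cfg.stage_seed("correlogram"),
            )
            correlog.to_csv(out / "correlogram.csv")

        if cfg.optimize_surfaces and surfaces and has_coords:
            stage("optimization")
            seed = cfg.stage_seed("optimization")
            summary["seeds"]["optimization"] = seed
            points = pruned.coords()
            models = []
            for name, surf in surfaces.items():
                ga = GaConfig(**{**cfg.ga.__dict__, "seed": seed})
                opt = ResistanceOptimizer([surf], [name], kind="continuous",
                                          config=ga)
                opt.fit(dps, points)
                models.append(opt.best_model_)

            stage("spearman_filter")
            retained, rho = spearman_filter(surfaces, cfg.spearman_threshold)
            rho.to_csv(out / "surface_correlations.csv")

            stage("multisurface")
            for pair in retained[: cfg.max_composites]:
                ga = GaConfig(**{**cfg.ga.__dict__, "seed": seed + 1})
                opt = ResistanceOptimizer(
                    [surfaces[pair[0]], surfaces[pair[1]]], list(pair),
                    kind="composite", config=ga,
                )
                opt.fit(dps, points)
                models.append(opt.best_model_)

            comp = information_criteria([m.fit for m in models])
            comp.to_csv(out / "model_selection.csv")

            stage("bootstrap")
            seed = cfg.stage_seed("bootstrap")
            summary["seeds"]["bootstrap"] = seed
            cands = candidates_from_models(models, surfaces, dps, points)
            boot = bootstrap_selection(
                cands, dps, iterations=cfg.bootstrap_iterations,
                fraction=cfg.bootstrap_fraction, seed=seed,
            )
            boot.to_csv(out / "bootstrap_selection.csv")
            summary["best_model"] = boot.best()
            contrib_rows = []
            for m in models:
                for sid, pct in m.contributions.items():
                    contrib_rows.append(
                        {"model": m.name, "variable": sid, "contribution_pct": pct}
                    )
            if contrib_rows:
                import pandas as pd

                pd.DataFrame(contrib_rows).to_csv(
                    out / "contributions.csv", index=False
                )

        if telemetry:
            stage("home_range")
            import pandas as pd

            uds, rows = [], []
            for t in telemetry:
                ud, hr = kde_homerange(t, level=cfg.isopleth_level)
                uds.append(ud)
                rows.append({"Radio": t.individual_id, "Sex": t.sex,
                             "Locations": t.n_fixes, "HR_ha": hr.area_ha})
            hr_df = pd.DataFrame(rows)
            hr_df.to_csv(out / "home_ranges.csv", index=False)
            overlap_matrix(uds, cfg.isopleth_level).to_csv(out / "overlap.csv")
            act = pd.concat(
                [activity_metrics(t) for t in telemetry], ignore_index=True
            )
            act.to_csv(out / "activity.csv", index=False)
            males = hr_df.loc[hr_df["Sex"] == "M", "HR_ha"]
            females = hr_df.loc[hr_df["Sex"] == "F", "HR_ha"]
            if len(males) and len(females):
                test = mwu_test(males, females)
                summary["home_range"] = {
                    "mean_male_ha": float(males.mean()),
                    "mean_female_ha": float(females.mean()),
                    "U": test["U"], "p": test["p"],
                }
    except Exception as exc:
        failed = summary["stages"][-1] if summary["stages"] else "setup"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str, sort_keys=True)
    return summary
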
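"""End-to-end orchestration: read cohort -> fit sources -> fit models ->
compare -> derived predictions, with a self-describing output directory."""

from __future__ import annotations

import json
import logging
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import model_weights
from .inference import BCellFateModel
from .io import PipelineConfig, read_cohort
from .predictions import influx_decomposition, ln_count_correlations
from .sources import fit_sources_from_cohort, save_sources

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every requested stage; returns a result bundle (paths + objects).

    The output directory is created atomically (staged in a temporary sibling
    and renamed) and always contains the resolved config, the package
    version, the seed, and per-stage logs, so any result folder is
    self-describing.
    """
    out_dir = Path(config.output_dir)
    data = read_cohort(config.cohort_csv)  # fail before creating any outputs

    out_dir.parent.mkdir(parents=True, exist_ok=True)
    stage_dir = Path(tempfile.mkdtemp(prefix=".bcellfate_", dir=out_dir.parent))
    handler = logging.FileHandler(stage_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger("bcellfate").addHandler(handler)

    bundle = {"config": config, "output_dir": out_dir}
    try:
        config.to_yaml(stage_dir / "config.yaml")
        (stage_dir / "run_info.json").write_text(json.dumps({
            "package_version": __version__, "seed": config.seed,
            "config_hash": config.config_hash(),
            "python": sys.version.split()[0]}, indent=2))

        logger.info("stage=sources fitting driver-pool curves")
        sources = fit_sources_from_cohort(data, form=config.source_form)
        save_sources(sources, stage_dir / "sources.json")
        bundle["sources"] = sources

        fits = {}
        statuses = {}
        for name in config.models:
            logger.info("stage=fit model=%s", name)
            est = BCellFateModel(model=name, draws=config.draws, tune=config.tune,
                                 walkers=config.walkers, seed=config.seed,
                                 dt=config.dt, shared_nu=config.shared_nu)
            est.fit(data, sources=sources)
            fits[name] = est
            statuses[name] = bool(est.converged_)
            est.summary_.to_csv(stage_dir / f"posterior_{name}.csv", index=False)
        bundle["fits"] = fits
        bundle["converged"] = statuses

        if len(fits) >= 2:
            logger.info("stage=compare method=%s", config.comparison_method)
            table = model_weights(fits, method=config.comparison_method,
                                  seed=config.seed)
            table.to_csv(stage_dir / "model_weights.csv")
            table.layout_grid().to_csv(stage_dir / "model_weights_grid.csv")
            bundle["comparison"] = table
            best_name = table.best
        else:
            best_name = next(iter(fits))
        bundle["best_model"] = best_name

        best = fits[best_name]
        best.draws_frame().to_csv(stage_dir / f"draws_{best_name}.csv.gz",
                                  index=False, compression="gzip")
        times = np.asarray(config.prediction_times, dtype=float)
        logger.info("stage=predict influx decomposition")
        decomp = influx_decomposition(best, times)
        decomp.summary.to_csv(stage_dir / "influx_decomposition.csv", index=False)
        bundle["influx_decomposition"] = decomp

        from .plots import plot_influx_decomposition, plot_trajectory_fit
        fig_dir = stage_dir / "figures"
        fig_dir.mkdir()
        plot_trajectory_fit(best, data, fig_dir / "trajectory_fit.png", times)
        plot_influx_decomposition(decomp, fig_dir / "influx_decomposition.png")
        for group, pop in (("control", "GCB_CARpos"), ("control", "MZB_CARpos"),
                           ("n2ko", "MZB_CARpos")):
            env = best.trajectory_envelope(times, group=group, population=pop)
            env.to_csv(stage_dir / f"trajectory_{group}_{pop}.csv", index=False)

        pairs = [tuple(p) for p in config.correlation_pairs]
        if pairs:
            try:
                corr, paired = ln_count_correlations(data, pairs)
                corr.to_csv(stage_dir / "ln_count_correlations.csv", index=False)
                bundle["correlations"] = corr
            except Exception as exc:
                logger.warning("stage=predict correlations skipped: %s", exc)

        half = best.draws_frame()
        hl_cols = [c for c in ("half_life_ctrl", "half_life_n2ko") if c in half]
        if hl_cols:
            pd.DataFrame({
                "quantity": hl_cols,
                "median": [float(half[c].median()) for c in hl_cols],
                "ci_low": [float(half[c].quantile(0.025)) for c in hl_cols],
                "ci_high": [float(half[c].quantile(0.975)) for c in hl_cols],
            }).to_csv(stage_dir / "clonal_half_lives.csv", index=False)
    except Exception:
        logger.exception("pipeline failed; partial outputs discarded")
        handler.close()
        logging.getLogger("bcellfate").removeHandler(handler)
        import shutil
        shutil.rmtree(stage_dir, ignore_errors=True)
        raise
    handler.close()
    logging.getLogger("bcellfate").removeHandler(handler)

    if out_dir.exists():
        import shutil
        shutil.rmtree(out_dir)
    stage_dir.rename(out_dir)
    bundle["ok"] = all(statuses.values())
    return bundle
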
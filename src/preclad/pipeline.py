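"""Orchestration: one reproducible run of the full analysis.

``run_pipeline`` executes preprocess -> effects -> trajectory ->
discrimination -> longitudinal as toggled by the :class:`RunConfig`,
writing plain CSV reports, a machine-readable manifest (config echo,
derived seeds, package version, per-stage row counts) and a log.  Outputs
contain no timestamps, so two runs with the same config and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import config as cfg
from . import discrimination, effects, longitudinal, preprocess, schema, synthetic
from . import trajectory as traj

log = logging.getLogger("preclad.pipeline")

_STAGE_SEEDS = {"synthetic": 1, "trajectory_cl": 2, "trajectory_csf": 3}


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(_STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)
    log.info("wrote %s (%d rows)", path.name, len(df))


def run_pipeline(run_config: cfg.RunConfig,
                 cohort_config: synthetic.CohortConfig | None = None) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    rc = run_config
    rc.validate()
    outdir = Path(rc.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("preclad")
    root.addHandler(handler)
    try:
        return _run(rc, cohort_config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(rc: cfg.RunConfig, cohort_config, outdir: Path) -> dict:
    manifest: dict = {
        "package_version": __version__,
        "config": rc.to_dict(),
        "stage_seeds": {k: _stage_seed(rc.seed, k) for k in _STAGE_SEEDS},
        "stages": {},
        "notes": ["combined ROC models are in-sample logistic regressions "
                  "(apparent AUC, no cross-validation)"],
    }

    followup = None
    if rc.synthetic:
        cc = cohort_config or synthetic.CohortConfig(
            n=rc.n_participants, seed=_stage_seed(rc.seed, "synthetic"))
        cohort = synthetic.generate_cohort(cc, include_latent=True)
        followup = synthetic.generate_followup(cohort, cc)
        cohort_public = cohort.drop(columns=["latent_cl"])
        _write(cohort_public, outdir / "cohort.csv")
        _write(followup, outdir / "followup.csv")
        manifest["stages"]["synthetic"] = {
            "n": len(cohort), "seed": cc.seed,
            "followup_rows": int(followup.notna().any(axis=1).sum())}
        cohort = cohort_public
    else:
        cohort = schema.load_cohort(rc.cohort_csv, rc.column_mapping)
        if rc.followup_csv:
            followup = pd.read_csv(rc.followup_csv)

    problems = schema.validate_schema(
        cohort, require_apoe=rc.run_discrimination)
    if problems:
        raise ValueError("cohort schema violations:\n  " + "\n  ".join(problems))

    if not rc.run_preprocess:
        _write_manifest(manifest, outdir)
        return manifest
    pre = preprocess.preprocess_cohort(cohort, rc)
    _write(pre, outdir / "preprocessed.csv")
    manifest["stages"]["preprocess"] = {
        "n": len(pre), "reference_n": pre.attrs["reference_n"],
        "at_counts": pre["at_group"].value_counts().to_dict()}

    if rc.run_effects:
        for grouping in ("at", "csf_pet"):
            rep = effects.effects_report(pre, grouping)
            _write(rep["effect_sizes"], outdir / f"effects_{grouping}_cohens_d.csv")
            _write(rep["ancova"], outdir / f"effects_{grouping}_ancova.csv")
        manifest["stages"]["effects"] = {"groupings": ["at", "csf_pet"]}

    if rc.run_trajectory:
        crossings = []
        for proxy, stage in ((schema.CENTILOIDS, "trajectory_cl"),
                             (schema.CSF_AB4240, "trajectory_csf")):
            models, cross = traj.trajectory_panel(
                pre, proxy=proxy, n_boot=rc.n_boot,
                span_points=rc.span_points, seed=_stage_seed(rc.seed, stage),
                thresholds=rc.abnormality_thresholds)
            curves = pd.concat(
                [m.to_frame().assign(biomarker=b) for b, m in models.items()],
                ignore_index=True)
            _write(curves, outdir / f"trajectory_{proxy}.csv")
            crossings.append(cross)
        cross_all = pd.concat(crossings, ignore_index=True)
        _write(cross_all, outdir / "crossings.csv")
        manifest["stages"]["trajectory"] = {
            "n_boot": rc.n_boot, "span_points": rc.span_points,
            "n_crossing_rows": len(cross_all)}

    if rc.run_discrimination:
        tables = []
        for outcome in ("csf", "cl12", "cl30"):
            for cut in (None, rc.age_cutoff, rc.age_cutoff_median):
                tab = discrimination.model_comparison_table(
                    pre, outcome, age_cutoff=cut, run_config=rc)
                tab = tab.assign(outcome=outcome,
                                 age_cutoff=np.nan if cut is None else cut)
                tables.append(tab)
        disc = pd.concat(tables, ignore_index=True)
        # the unstratified table repeats across cutoffs; keep one copy
        disc = disc.drop_duplicates(
            subset=["outcome", "stratum", "model"], ignore_index=True)
        _write(disc, outdir / "discrimination.csv")
        (outdir / "discrimination.txt").write_text(
            discrimination.render_table(
                disc[(disc["outcome"] == "csf")
                     & disc["stratum"].isin(["all", f"age<={rc.age_cutoff:g}",
                                             f"age>{rc.age_cutoff:g}"])]))
        manifest["stages"]["discrimination"] = {"rows": len(disc)}

    if rc.run_longitudinal and followup is not None:
        chg = longitudinal.change_report(pre, followup, rc)
        _write(chg, outdir / "longitudinal.csv")
        manifest["stages"]["longitudinal"] = {"rows": len(chg)}

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
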
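"""End-to-end simulated study orchestration.

Runs the full simulated pipeline on a synthetic cohort: sequence
generation, response simulation, model fitting and comparison,
recovery suites, P(share) regressors, hierarchical discounting with
LOSO classification, and the perspective-taking transfer stage.  Every
stage draws its randomness from a named substream of one master seed
and communicates with later stages only through serialised artefacts
(CSV tables and JSON reports) written under the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (discounting, fbt_design, learning_models, model_fitting,
               recovery, share_tracker, synthetic_cohort, transfer_task)
from .learning_models import ModelSpec, ParamSet

__all__ = ["StudyConfig", "run_study"]

logger = logging.getLogger("selfother")

#: Default model subset fit in a study run: the generating leak /
#: no-leak pair plus richer variants of each class.
DEFAULT_MODEL_SUBSET = (
    ("single", "single", 0, 0),
    ("single", "single", 1, 0),
    ("single", "single", 1, 1),
    ("by_trial_class", "single", 1, 1),
    ("by_agent", "single", 1, 0),
    ("by_agent", "single", 1, 1),
)


@dataclass
class StudyConfig:
    """Configuration of a simulated study run."""

    n_subjects: int = 8
    contexts: tuple = ("hi_share", "lo_share")
    session: str = "train"
    seed: int = 1
    out_dir: str = "study_out"
    scale: str = "ci"               # ci | full
    n_restarts: int = 3
    eta_grid: tuple = share_tracker.ETA_GRID
    n_permutations: int = 500
    coupling: float = -0.4
    run_recovery: bool = True
    model_subset: tuple = DEFAULT_MODEL_SUBSET

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("contexts", "eta_grid"):
            if key in d:
                d[key] = tuple(d[key])
        if "model_subset" in d:
            d["model_subset"] = tuple(tuple(m) for m in d["model_subset"])
        return cls(**d)


def _subset_specs(config: StudyConfig) -> list[ModelSpec]:
    all_specs = learning_models.enumerate_model_space()
    lookup = {(s.alpha_structure, s.tau_structure, s.n_delta, s.n_lambda): s
              for s in all_specs}
    return [lookup[tuple(m)] for m in config.model_subset]


def _seed_for(ss: np.random.SeedSequence, *path: str) -> int:
    """Stable per-stage integer seed derived from the master sequence."""
    import zlib
    key = tuple(zlib.crc32(p.encode()) for p in path)
    child = np.random.SeedSequence(ss.entropy, spawn_key=key)
    return int(child.generate_state(1)[0] % (2**31))


def run_study(config: StudyConfig) -> dict:
    """Run the full simulated study; returns the summary dict.

    All artefacts (sequence CSVs, fit tables, regressors, reports) and
    a ``summary.json`` land in ``config.out_dir``.  Reproducible:
    identical (config, seed) gives byte-identical summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    summary: dict = {"config": dataclasses.asdict(config)}

    # -- stage 1: trial sequences --------------------------------------
    logger.info("generating trial sequences")
    sequences = {}
    for ctx in config.contexts:
        seq = fbt_design.generate_sequence(ctx, config.session,
                                           seed=_seed_for(ss, "seq", ctx))
        sequences[ctx] = seq
        fbt_design.sequence_to_csv(seq, out / f"sequence_{ctx}.csv")
    summary["sequences"] = {
        ctx: {"n_trials": len(seq), "n_probes": seq.n_probes()}
        for ctx, seq in sequences.items()}

    # -- stage 2: cohort + FBT responses -------------------------------
    logger.info("sampling cohort of %d subjects", config.n_subjects)
    cohort_cfg = synthetic_cohort.CohortConfig(coupling=config.coupling)
    subjects = synthetic_cohort.sample_cohort(config.n_subjects, cohort_cfg,
                                              seed=_seed_for(ss, "cohort"))
    gen_specs = synthetic_cohort.default_specs()
    responses = {ctx: [] for ctx in config.contexts}
    for subj in subjects:
        for ctx in config.contexts:
            params = ParamSet.from_values(gen_specs[ctx], subj.fbt_params[ctx])
            responses[ctx].append(synthetic_cohort.simulate_fbt_responses(
                params, sequences[ctx], seed=subj.seeds["fbt"]))
    manifest = [{"subject_id": s.subject_id, "fbt_params": s.fbt_params,
                 "itc_params": s.itc_params, "seeds": s.seeds}
                for s in subjects]
    (out / "cohort.json").write_text(json.dumps(manifest, indent=1))

    # -- stage 3: model fitting + comparison ---------------------------
    specs = _subset_specs(config)
    logger.info("fitting %d models x %d subjects x %d contexts",
                len(specs), config.n_subjects, len(config.contexts))
    comparison = {}
    winners = {}
    fit_values = {}
    for ctx in config.contexts:
        fits = {}
        for spec in specs:
            fits[spec.id] = [
                model_fitting.fit_subject(
                    sequences[ctx], responses[ctx][i], spec,
                    n_restarts=config.n_restarts,
                    seed=_seed_for(ss, "fit", ctx, spec.id, str(i)))
                for i in range(config.n_subjects)]
        winner, table = model_fitting.compare_models(fits)
        table.to_csv(out / f"bic_table_{ctx}.csv", index=False)
        spec_by_id = {s.id: s for s in specs}
        comparison[ctx] = {
            "winner": winner,
            "winner_has_lambda": spec_by_id[winner].has_lambda,
            "table": table.to_dict(orient="records")}
        winners[ctx] = spec_by_id[winner]
        fit_values[ctx] = {sid: [f.values for f in fs]
                           for sid, fs in fits.items()}
    summary["model_comparison"] = comparison

    # -- stage 4: recovery suites --------------------------------------
    if config.run_recovery:
        logger.info("parameter recovery on the Hi-Share generating model")
        ctx = config.contexts[0]
        spec = gen_specs[ctx]
        truth = [s.fbt_params[ctx] for s in subjects]
        rho = recovery.parameter_recovery(
            spec, truth, [sequences[ctx]],
            seed=_seed_for(ss, "param_recovery"),
            n_restarts=config.n_restarts)
        summary["parameter_recovery"] = rho
        leak_spec = gen_specs["hi_share"]
        noleak_spec = gen_specs["lo_share"]
        sim_values = [
            [s.fbt_params["hi_share"] for s in subjects],
            [s.fbt_params["lo_share"] for s in subjects],
        ]
        mat = recovery.model_recovery(
            [leak_spec, noleak_spec], sim_values, [sequences[ctx]],
            seed=_seed_for(ss, "model_recovery"),
            n_restarts=config.n_restarts)
        mat.to_frame("p_sim_given_fit").to_csv(out / "model_recovery.csv")
        summary["model_recovery"] = {
            "model_ids": mat.model_ids,
            "p_fit_given_sim": mat.p_fit_given_sim.tolist(),
            "p_sim_given_fit": mat.p_sim_given_fit.tolist()}

    # -- stage 5: P(share) regressors ----------------------------------
    for ctx in config.contexts:
        for eta in config.eta_grid:
            trace = share_tracker.trace_sequence(sequences[ctx], eta)
            reg = share_tracker.make_regressors(trace, zscore=True)
            reg.to_csv(out / f"pshare_{ctx}_eta{eta}.csv", index=False)
    summary["pshare"] = {"eta_grid": list(config.eta_grid)}

    # -- stage 6: discounting ------------------------------------------
    logger.info("hierarchical discounting fit")
    battery = discounting.generate_battery(seed=_seed_for(ss, "battery"))
    cohort_choices = [
        synthetic_cohort.simulate_itc_choices(s.itc_params, battery,
                                              seed=s.seeds["itc"])
        for s in subjects]
    fits = {}
    for model in ("hyper1", "hyper2"):
        fits[model] = discounting.em_fit(cohort_choices, model=model,
                                         seed=_seed_for(ss, "ibic", model))
    fit2 = fits["hyper2"]
    (out / "discount_fit.json").write_text(json.dumps(fit2.to_dict(), indent=1))
    aucs = [discounting.discounting_auc(c) for c in cohort_choices]
    summary["discounting"] = {
        "ibic": {m: fits[m].ibic for m in fits},
        "mean_auc": float(np.mean(aucs)),
        "auc_logkS_spearman": float(pd.Series(aucs).corr(
            pd.Series(fit2.log_kS), method="spearman")),
        "n_permutations": config.n_permutations}
    if config.n_subjects >= 10:
        lam = np.array([s.fbt_params["hi_share"]["lambda"] for s in subjects])
        loso = discounting.loso_classify(
            lam, fit2.log_kS, n_permutations=config.n_permutations,
            seed=_seed_for(ss, "loso"))
        summary["discounting"]["loso_median_ce"] = loso.median_ce
        summary["discounting"]["loso_p"] = loso.p_value

    # -- stage 7: perspective-taking transfer --------------------------
    logger.info("transfer-task simulation")
    design = transfer_task.build_pt_design(
        repeats_per_cell=8, seed=_seed_for(ss, "pt_design"))
    base = transfer_task.DDMParams()
    shift = {"lo_share": 0.25, "hi_share": -0.25, "arrow": 0.1}
    trans_means = {key: v + shift[key[0]]
                   for key, v in base.drift_means.items()}
    trans = transfer_task.DDMParams(drift_means=trans_means)
    data = transfer_task.simulate_dataset(base, design,
                                          seed=_seed_for(ss, "pt_sim"))
    data.to_csv(out / "pt_baseline.csv", index=False)
    corrected = {}
    for avatar in ("lo_share", "hi_share"):
        cells = [(avatar, p, c) for p in transfer_task.PERSPECTIVES
                 for c in transfer_task.CONDITIONS]
        arrows = [("arrow", p, c) for p in transfer_task.PERSPECTIVES
                  for c in transfer_task.CONDITIONS]
        v_b = float(np.mean([base.drift_means[c] for c in cells]))
        v_t = float(np.mean([trans.drift_means[c] for c in cells]))
        a_b = float(np.mean([base.drift_means[c] for c in arrows]))
        a_t = float(np.mean([trans.drift_means[c] for c in arrows]))
        corrected[avatar] = transfer_task.corrected_change(v_b, v_t, a_b, a_t)
    summary["transfer"] = {
        "n_trials": len(design),
        "excluded_frac": float(data["excluded"].mean()),
        "corrected_change": corrected}

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    return summary
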
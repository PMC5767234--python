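"""End-to-end orchestration of the co-culture labeling analysis.

Stages: simulate (or load) the feature matrix -> detect induced features ->
simulate/extract isotopologue ladders -> natural-abundance correction and
incorporation metrics with replicate t-tests -> producer assignment,
supernatant-dependence and physical-interaction flags -> optional molecular
network -> summary report.  Each stage writes a delimited table so any stage
can be re-run from saved upstream outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import induction, labeling, network, producer, simdata, spectra
from .chem import correction_matrix, parse_formula

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "analyze_labeling"]

log = logging.getLogger("cocultrace")


@dataclass
class PipelineConfig:
    """All thresholds and paths of the pipeline in one place."""

    seed: int = 0
    output_dir: str = "results"
    scenario_path: str | None = None  # None -> packaged study scenario
    n_background: int = 4000
    fold_threshold: float = induction.FOLD_THRESHOLD
    detection_floor: float = induction.DETECTION_FLOOR
    p_threshold: float = 0.05
    enrichment_floor: float = labeling.DEFAULT_ENRICHMENT_FLOOR
    high_signal_floor: float = producer.HIGH_SIGNAL_FLOOR
    mz_tol_ppm: float = 10.0
    rt_window_min: float = 0.2
    rt_dedup_tol_min: float = 0.2
    noise_rel_sd: float | None = None  # None -> scenario default
    run_network: bool = False
    min_cosine: float = 0.65
    min_matched: int = 6
    max_component: int = 50
    min_cluster: int = 2

    def __post_init__(self) -> None:
        for name in (
            "fold_threshold", "detection_floor", "p_threshold",
            "enrichment_floor", "high_signal_floor", "mz_tol_ppm",
            "rt_window_min", "rt_dedup_tol_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineReport:
    counts: dict = field(default_factory=dict)
    induced_table: pd.DataFrame | None = None
    labeling_table: pd.DataFrame | None = None
    producer_table: pd.DataFrame | None = None
    network_components: list | None = None


def analyze_labeling(
    sc: simdata.Scenario,
    feature: simdata.FeatureTruth,
    organism: str,
    day: int,
    condition: str,
    cfg: PipelineConfig,
    baseline_by_bio: dict[int, float] | None = None,
) -> labeling.LabelingResult:
    """Run extraction + correction + incorporation for one feature arm.

    Analytical replicates are averaged within each biological replicate
    before statistics, so the t-test unit is the biological replicate (n=3).
    """
    formula = parse_formula(feature.formula)
    cm = correction_matrix(formula)
    target = feature.target()
    per_bio: dict[int, list[float]] = {}
    for b in range(1, sc.n_bio + 1):
        vals = []
        for a in range(1, sc.n_ana + 1):
            specs = simdata.simulate_labeling_spectra(
                sc, organism, day, condition, b, a, noise_rel_sd=cfg.noise_rel_sd
            )
            meas = spectra.extract_isotopologues(
                specs, target, mz_tol_ppm=cfg.mz_tol_ppm,
                rt_window_min=cfg.rt_window_min,
                sample_id=f"{organism}_d{day}_{condition}_b{b}_a{a}",
            )
            mid = labeling.correct_natural_abundance(meas.intensities, cm)
            vals.append(labeling.total_incorporation(mid))
        per_bio[b] = vals
    reps = [float(np.mean(v)) for v in per_bio.values()]
    result = labeling.LabelingResult(
        feature_id=feature.feature_id,
        group=organism,
        timepoint=day,
        condition=condition,
        replicate_incorporations=reps,
    )
    if baseline_by_bio is not None:
        base = [baseline_by_bio[b] for b in sorted(baseline_by_bio)]
        result.baseline_incorporations = base
        result.p_value, result.labeled = labeling.labeling_significance(
            reps, base, alpha=cfg.p_threshold, enrichment_floor=cfg.enrichment_floor
        )
    return result


def _extract_all_arms(sc, cfg):
    """Labeling results for every induced feature x organism x day x condition.

    Spectra are simulated once per sample and all features extracted from the
    cached sample, which keeps the stage linear in the number of samples.
    """
    arms = [("baseline", sc.days[0])] + [
        (cond, day) for day in sc.days for cond in ("with_sup", "without_sup")
    ]
    cms = {}
    for f in sc.induced:
        if f.formula not in cms:
            cms[f.formula] = correction_matrix(parse_formula(f.formula))
    # per-arm, per-feature incorporation averaged over analytical reps
    incorp: dict[tuple, dict[int, float]] = {}
    worst_residual: dict[str, float] = {}
    import warnings as _warnings

    for org in simdata.ORGANISMS:
        for cond, day in arms:
            for b in range(1, sc.n_bio + 1):
                per_ana: dict[str, list[float]] = {f.feature_id: [] for f in sc.induced}
                for a in range(1, sc.n_ana + 1):
                    specs = simdata.simulate_labeling_spectra(
                        sc, org, day, cond, b, a, noise_rel_sd=cfg.noise_rel_sd
                    )
                    for f in sc.induced:
                        meas = spectra.extract_isotopologues(
                            specs, f.target(), mz_tol_ppm=cfg.mz_tol_ppm,
                            rt_window_min=cfg.rt_window_min,
                        )
                        with _warnings.catch_warnings():
                            _warnings.simplefilter("ignore", UserWarning)
                            mid = labeling.correct_natural_abundance(
                                meas.intensities, cms[f.formula]
                            )
                        worst_residual[f.feature_id] = max(
                            worst_residual.get(f.feature_id, 0.0), mid.residual
                        )
                        per_ana[f.feature_id].append(labeling.total_incorporation(mid))
                for fid, vals in per_ana.items():
                    incorp.setdefault((fid, org, cond, day), {})[b] = float(
                        np.mean(vals)
                    )
    for fid, res in sorted(worst_residual.items()):
        if res > labeling.RESIDUAL_TOL:
            log.warning(
                "feature %s: correction residual up to %.2f (possible "
                "co-eluting isobaric interference)", fid, res,
            )
    results: dict[tuple, labeling.LabelingResult] = {}
    for f in sc.induced:
        for org in simdata.ORGANISMS:
            base = incorp[(f.feature_id, org, "baseline", sc.days[0])]
            base_reps = [base[b] for b in sorted(base)]
            for day in sc.days:
                for cond in ("with_sup", "without_sup"):
                    by_bio = incorp[(f.feature_id, org, cond, day)]
                    reps = [by_bio[b] for b in sorted(by_bio)]
                    res = labeling.LabelingResult(
                        feature_id=f.feature_id, group=org, timepoint=day,
                        condition=cond, replicate_incorporations=reps,
                        baseline_incorporations=base_reps,
                    )
                    res.p_value, res.labeled = labeling.labeling_significance(
                        reps, base_reps, alpha=cfg.p_threshold,
                        enrichment_floor=cfg.enrichment_floor,
                    )
                    results[(f.feature_id, org, day, cond)] = res
    return results


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute induction -> labeling -> producer (-> optional network)."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.scenario_path is not None:
        if not Path(cfg.scenario_path).exists():
            raise FileNotFoundError(f"scenario file not found: {cfg.scenario_path}")
        sc = simdata.Scenario.from_yaml(cfg.scenario_path)
    else:
        sc = simdata.study_scenario(seed=cfg.seed, n_background=cfg.n_background)
    log.info("scenario: %d features (%d induced)", len(sc.features), len(sc.induced))

    # --- induction stage
    fm = simdata.simulate_feature_matrix(sc, noise_rel_sd=cfg.noise_rel_sd)
    induced = induction.detect_induced(
        fm, fold_threshold=cfg.fold_threshold, detection_floor=cfg.detection_floor
    )
    induced_df = pd.DataFrame(
        [
            dict(
                feature_id=i.feature_id,
                induction_class=i.induction_class,
                fold=i.fold,
                fold_sd=i.fold_sd,
                co_mean=i.co_mean,
            )
            for i in induced
        ]
    )
    induced_df.to_csv(out / "induced_features.tsv", sep="\t", index=False)
    log.info("induction: %d induced features (%.1fs)", len(induced), time.time() - t0)

    # --- labeling stage (on induced features present in the scenario roster)
    truth_by_id = {f.feature_id: f for f in sc.induced}
    induced_ids = [i.feature_id for i in induced if i.feature_id in truth_by_id]
    sub = simdata.Scenario(
        seed=sc.seed,
        features=[truth_by_id[i] for i in induced_ids],
        msms_families=sc.msms_families,
        days=sc.days,
        n_bio=sc.n_bio,
        n_ana=sc.n_ana,
        noise_rel_sd=sc.noise_rel_sd,
    )
    arm_results = _extract_all_arms(sub, cfg)
    lab_rows = []
    for (fid, org, day, cond), r in arm_results.items():
        lab_rows.append(
            dict(
                feature_id=fid, organism=org, day=day, condition=cond,
                incorporation_pct=r.mean_incorporation,
                incorporation_sd=r.sd_incorporation,
                p_value=r.p_value, labeled=r.labeled,
            )
        )
    lab_df = pd.DataFrame(lab_rows)
    lab_df.to_csv(out / "labeling_results.tsv", sep="\t", index=False)
    log.info("labeling: %d arms analyzed (%.1fs)", len(lab_rows), time.time() - t0)

    # --- producer stage
    co_mean = {i.feature_id: i.co_mean for i in induced}
    calls = []
    for fid in induced_ids:
        res_a = [arm_results[(fid, "A", d, "with_sup")] for d in sc.days]
        res_b = [arm_results[(fid, "B", d, "with_sup")] for d in sc.days]
        call = producer.assign_producer(fid, res_a, res_b)
        wo_a = [arm_results[(fid, "A", d, "without_sup")] for d in sc.days]
        wo_b = [arm_results[(fid, "B", d, "without_sup")] for d in sc.days]
        call.supernatant_dependent = producer.supernatant_dependence(
            res_a + res_b, wo_a + wo_b
        )
        call.physical_interaction_candidate = producer.flag_physical_interaction(
            co_mean[fid], call, high_signal_floor=cfg.high_signal_floor
        )
        calls.append(call)
    targets = {f.feature_id: f.target() for f in sc.induced}
    compound_calls = producer.deduplicate_features(
        calls, targets, rt_tol_min=cfg.rt_dedup_tol_min
    )
    prod_df = pd.DataFrame(
        [
            dict(
                feature_id=c.feature_id,
                call=c.call,
                supernatant_dependent=c.supernatant_dependent,
                physical_interaction_candidate=c.physical_interaction_candidate,
                conflict=c.conflict_note or "",
            )
            for c in compound_calls
        ]
    )
    prod_df.to_csv(out / "producer_calls.tsv", sep="\t", index=False)

    counts = {
        "total_features": len(sc.features),
        "induced": len(induced),
        "newly_synthesized": sum(
            i.induction_class == "newly_synthesized" for i in induced
        ),
        "fold_increased": sum(i.induction_class == "fold_increased" for i in induced),
        "A_only": sum(c.call == "A_only" for c in compound_calls),
        "B_only": sum(c.call == "B_only" for c in compound_calls),
        "both": sum(c.call == "both" for c in compound_calls),
        "unassigned": sum(c.call == "unassigned" for c in compound_calls),
        "labeled": sum(c.call != "unassigned" for c in compound_calls),
        "physical_interaction_candidates": sum(
            c.physical_interaction_candidate for c in compound_calls
        ),
    }

    report = PipelineReport(
        counts=counts,
        induced_table=induced_df,
        labeling_table=lab_df,
        producer_table=prod_df,
    )

    # --- optional molecular network stage
    if cfg.run_network:
        msms = []
        for fam in sc.msms_families:
            msms.extend(
                simdata.simulate_msms_family(
                    fam.backbone, fam.precursors, group=fam.group,
                    name=fam.name, seed=sc.seed,
                )
            )
        net = network.build_network(
            msms, min_cosine=cfg.min_cosine, min_matched=cfg.min_matched,
            max_component=cfg.max_component, min_cluster=cfg.min_cluster,
        )
        network.export_network(net, out / "molecular_network.graphml")
        report.network_components = net.components()
        counts["network_components"] = len(report.network_components)

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(counts, fh, sort_keys=False)
    log.info("pipeline done in %.1fs: %s", time.time() - t0, counts)
    return report
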
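"""End-to-end orchestration: medication log -> report bundle.

Stages: load -> summary -> classify -> screen -> interact -> network ->
chord -> associate. Each stage's outputs land in the configured output
directory; ``manifest.json`` records package version, seed, per-output row
counts, and which stages ran or were skipped. Any stage failure aborts with
the stage name attached. When no interaction knowledge base is configured,
the interaction-dependent stages are skipped and marked as such, and the
remaining stages complete.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import round_half_up
from .atc import MEDICATION_LEVEL, annotation_map, classify_cohort, level_tally, load_formulary
from .interactions import detect_cohort, interaction_summary, load_kb, write_detections
from .medlog import assemble_patients, cohort_summary, read_medication_log, read_synonyms, regular_med_count
from .network import build_network, chord_matrix, compute_metrics, write_chord_matrix, write_edge_list
from .pim import class_breakdown, load_ruleset, pim_prevalence, write_flags
from .stats import association_table

logger = logging.getLogger(__name__)

ASSOCIATION_VARIABLES = (
    "age_band", "gender", "race", "education", "income", "marital_status",
    "cancer_type", "kps", "life_expectancy",
)
ASSOCIATION_REFERENCES = {
    "age_band": "70-74", "gender": "male", "race": "white",
    "education": "< high school", "income": "<=50k",
    "marital_status": "single", "cancer_type": "gastrointestinal",
    "kps": "20-60", "life_expectancy": "<=12 months",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    medlog: Path
    covariates: Path
    formulary: Path
    ruleset: Path
    outdir: Path
    kb: Path | None = None
    synonyms: Path | None = None
    threshold_poly: int = 5
    threshold_excessive: int = 10
    chord_min_count_all: int = 20   # all-interaction chord export threshold
    chord_min_count_major: int = 3  # major-interaction chord export threshold
    seed: int | None = None
    pct_decimals: int = 1
    or_decimals: int = 2

    def __post_init__(self) -> None:
        for name in ("medlog", "covariates", "formulary", "ruleset"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        if self.kb is not None and not Path(self.kb).exists():
            raise FileNotFoundError(f"kb input not found: {self.kb}")
        if min(self.threshold_poly, self.threshold_excessive,
               self.chord_min_count_all, self.chord_min_count_major) < 1:
            raise ValueError("thresholds must be positive")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "polyrisk_version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def _stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise PipelineError(name, str(exc)) from exc
            manifest["stages"][name] = "ok"
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return deco

    state: dict = {}

    @_stage("load")
    def _load():
        synonyms = read_synonyms(config.synonyms) if config.synonyms else {}
        records = read_medication_log(config.medlog)
        covs = pd.read_csv(config.covariates, dtype={"patient_id": str})
        state["cohort"] = assemble_patients(records, covs, synonyms)
        state["cov_df"] = covs

    @_stage("summary")
    def _summary():
        s = cohort_summary(state["cohort"])
        _write_json(outdir / "cohort_summary.json", dataclasses.asdict(s), manifest)

    @_stage("classify")
    def _classify():
        formulary = load_formulary(config.formulary)
        state["formulary"] = formulary
        assignments, unclassified = classify_cohort(state["cohort"], formulary)
        state["assignments"] = assignments
        _write_csv(outdir / "atc_unclassified.csv", unclassified, manifest)
        tally = level_tally(assignments, 2).rename("occurrences").reset_index()
        _write_csv(outdir / "atc_level2_tally.csv", tally, manifest)

    @_stage("screen")
    def _screen():
        rules = load_ruleset(config.ruleset)
        prev, flags = pim_prevalence(state["cohort"], rules, state["formulary"])
        state["pim_flags"] = flags
        state["pim_prev"] = prev
        _write_json(
            outdir / "pim_prevalence.json",
            {
                "n_patients": prev.n_patients,
                "pct_by_source": prev.pct_by_source,
                "pct_union": prev.pct_union,
                "nonrx_share_of_flags": prev.nonrx_share_of_flags,
                "n_flags_by_source": prev.n_flags_by_source,
            },
            manifest,
        )
        _write_csv(
            outdir / "pim_class_breakdown.csv",
            class_breakdown(flags, state["cohort"], state["formulary"]),
            manifest,
        )
        flags_path = outdir / "pim_flags.csv"
        write_flags(flags, flags_path)
        manifest["outputs"]["pim_flags.csv"] = len(flags)

    if config.kb is not None:
        @_stage("interact")
        def _interact():
            kb = load_kb(config.kb)
            state["detections"] = detect_cohort(state["cohort"], kb)
            summary = interaction_summary(state["cohort"], kb)
            _write_json(
                outdir / "interaction_summary.json", dataclasses.asdict(summary), manifest
            )
            det_path = outdir / "interaction_detections.csv"
            write_detections(state["detections"], det_path)
            manifest["outputs"]["interaction_detections.csv"] = len(state["detections"])

        @_stage("network")
        def _network():
            metrics = {}
            for level in (MEDICATION_LEVEL, 1, 2, 3):
                ann = annotation_map(state["formulary"], level)
                net = build_network(state["detections"], level, ann)
                m = compute_metrics(net)
                metrics[str(level)] = {
                    **dataclasses.asdict(m),
                    "self_pair_count": net.self_pair_count,
                    "unmapped_count": net.unmapped_count,
                }
                write_edge_list(net, outdir / f"network_edges_level_{level}.csv")
                manifest["outputs"][f"network_edges_level_{level}.csv"] = net.n_edges
            _write_json(outdir / "network_metrics.json", metrics, manifest)

        @_stage("chord")
        def _chord():
            ann = annotation_map(state["formulary"], 2)
            all_det = [d for d in state["detections"]]
            major_det = [d for d in state["detections"] if d.major]
            for tag, det, min_count in (
                ("all", all_det, config.chord_min_count_all),
                ("major", major_det, config.chord_min_count_major),
            ):
                mat, labels = chord_matrix(det, 2, ann, min_count)
                path = outdir / f"chord_level2_{tag}.csv"
                write_chord_matrix(mat, labels, path)
                manifest["outputs"][path.name] = len(labels)
    else:
        for name in ("interact", "network", "chord"):
            manifest["stages"][name] = "skipped (no knowledge base configured)"

    @_stage("associate")
    def _associate():
        cohort = state["cohort"]
        df = state["cov_df"].copy()
        counts = {p.patient_id: regular_med_count(p) for p in cohort}
        df["med_count"] = df["patient_id"].map(counts)
        df["polypharmacy"] = df["med_count"] >= config.threshold_poly
        pim_counts = state["pim_prev"].per_patient_flag_counts
        df["any_pim"] = df["patient_id"].map(pim_counts).fillna(0) > 0
        variables = [v for v in ASSOCIATION_VARIABLES if v in df.columns]
        refs = {v: ASSOCIATION_REFERENCES[v] for v in variables}
        tables = []
        for outcome in ("polypharmacy", "any_pim"):
            t = association_table(df, outcome, variables, refs)
            t.insert(0, "outcome", outcome)
            tables.append(t)
        out = pd.concat(tables, ignore_index=True)
        for col in ("por", "ci_low", "ci_high"):
            out[col] = out[col].map(
                lambda x: x if pd.isna(x) else round_half_up(x, config.or_decimals)
            )
        _write_csv(outdir / "associations.csv", out, manifest)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _write_json(path: Path, obj, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
    manifest["outputs"][path.name] = len(obj) if hasattr(obj, "__len__") else 1


def _write_csv(path: Path, df: pd.DataFrame, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = len(df)
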
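"""End-to-end orchestration: encode -> exclude -> build samples -> filter ->
screens -> discovery, with a machine-readable run manifest.

The pipeline is deterministic for a fixed master seed: per-variable forest
seeds are derived by stable hashing of (seed, variable_id), so results do not
depend on iteration order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .discovery import DiscoveryReport, comparison_table, dual_discovery, volcano_table
from .matched_analysis import results_to_frame, run_matched_screen
from .propensity_analysis import run_propensity_screen
from .questionnaire_model import (
    ExclusionConfig,
    QuestionnaireSpec,
    StudyDataset,
    apply_exclusions,
    build_matched_sample,
    build_propensity_sample,
    encode_variables,
    read_participants,
    read_responses,
    sd_filter,
)

__all__ = ["PipelineConfig", "RunManifest", "run_all", "load_inputs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of one pipeline run (exclusion thresholds, test levels, forest)."""

    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    alpha: float = 0.05
    propensity_k: int = 10
    rf_n_trees: int = 500

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reconciled per-stage counts plus provenance of one run."""

    config_hash: str
    seed: int
    software_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    analyses: list[str] = field(default_factory=list)

    def reconcile(self) -> None:
        c = self.counts
        excluded = sum(v for k, v in c.items() if k.startswith("excluded_"))
        if c["participants_in"] != c["participants_retained"] + excluded:
            raise AssertionError(
                "manifest counts do not reconcile: "
                f"{c['participants_in']} != {c['participants_retained']} + {excluded}"
            )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_inputs(participants_path, responses_path, spec_path) -> tuple[StudyDataset, dict]:
    """Read and validate the three input files into a StudyDataset."""
    spec = QuestionnaireSpec.from_yaml(spec_path)
    participants = read_participants(participants_path)
    responses = read_responses(responses_path)
    dataset = StudyDataset(
        participants=participants, raw_responses=responses, spec=spec
    )
    digests = {
        "participants": _file_digest(participants_path),
        "responses": _file_digest(responses_path),
        "questionnaire": _file_digest(spec_path),
    }
    return dataset, digests


def run_all(
    dataset: StudyDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir=None,
    matched: bool = True,
    propensity: bool = True,
    input_digests: dict[str, str] | None = None,
) -> tuple[DiscoveryReport | None, RunManifest, dict]:
    """Execute the full screening pipeline on a dataset.

    Returns (discovery report or None when only one screen ran, manifest,
    artifacts dict of in-memory tables).  When ``outdir`` is given, all
    module outputs are written there as TSV/JSON; on a stage failure partial
    outputs are removed and a stage-labeled error is raised.
    """
    if config is None:
        config = PipelineConfig()
    manifest = RunManifest(
        config_hash=config.digest(),
        seed=seed,
        software_version=__version__,
        input_digests=input_digests or {},
    )
    artifacts: dict = {}
    written: list[str] = []
    stage = "setup"

    def _write(name: str, frame: pd.DataFrame) -> None:
        if outdir is None:
            return
        path = os.path.join(outdir, name)
        frame.to_csv(path, sep="\t", index=name == "encoded_matrix.tsv",
                     index_label="participant_id" if name == "encoded_matrix.tsv" else None)
        written.append(path)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
    try:
        stage = "encode"
        encoded = encode_variables(dataset.raw_responses, dataset.spec)
        artifacts["encoded_matrix"] = encoded
        _write("encoded_matrix.tsv", encoded)

        stage = "exclusions"
        manifest.counts["participants_in"] = len(dataset.participants)
        filtered, log = apply_exclusions(dataset, config.exclusions)
        for rule, n in sorted(log.counts().items()):
            manifest.counts[f"excluded_{rule}"] = int(n)
        manifest.counts["participants_retained"] = len(filtered.participants)
        artifacts["exclusion_log"] = log

        results_m = results_p = None
        if matched:
            stage = "matched_sample"
            strata = build_matched_sample(filtered, log)
            manifest.counts["matched_strata"] = len(strata)
            member_ids = [pid for s in strata for pid in s.member_ids]
            manifest.counts["matched_sample_size"] = len(member_ids)

            stage = "matched_sd_filter"
            kept_m, dropped_m = sd_filter(
                encoded, member_ids, config.exclusions.sd_min
            ) if strata else ([], pd.DataFrame())
            manifest.counts["matched_variables_kept"] = len(kept_m)
            manifest.counts["matched_variables_filtered"] = (
                len(encoded.columns) - len(kept_m)
            )
            artifacts["matched_sd_dropped"] = dropped_m

            stage = "matched_screen"
            results = run_matched_screen(strata, encoded, dataset.spec, kept_m)
            results_m = results_to_frame(results).drop(
                columns=["effective_k", "rf_seed"]
            )
            artifacts["matched_results"] = results_m
            _write("matched_results.tsv", results_m)
            for status, n in results_m["status"].value_counts().items():
                manifest.counts[f"matched_tests_{status}"] = int(n)
            manifest.analyses.append("matched")

        if propensity:
            stage = "propensity_sample"
            prop_ids = build_propensity_sample(filtered, log)
            manifest.counts["propensity_sample_size"] = len(prop_ids)
            sample = filtered.participants.loc[
                filtered.participants["participant_id"].isin(set(prop_ids))
            ]

            stage = "propensity_sd_filter"
            kept_p, dropped_p = sd_filter(
                encoded, prop_ids, config.exclusions.sd_min
            ) if prop_ids else ([], pd.DataFrame())
            manifest.counts["propensity_variables_kept"] = len(kept_p)
            manifest.counts["propensity_variables_filtered"] = (
                len(encoded.columns) - len(kept_p)
            )
            artifacts["propensity_sd_dropped"] = dropped_p

            stage = "propensity_screen"
            results = run_propensity_screen(
                sample,
                encoded,
                dataset.spec,
                seed=seed,
                variables=kept_p,
                k=config.propensity_k,
                n_trees=config.rf_n_trees,
            )
            results_p = results_to_frame(results)
            artifacts["propensity_results"] = results_p
            _write("propensity_results.tsv", results_p)
            for status, n in results_p["status"].value_counts().items():
                manifest.counts[f"propensity_tests_{status}"] = int(n)
            manifest.analyses.append("propensity")

        stage = "discovery"
        report = None
        if results_m is not None:
            volcano_m, thr_m = volcano_table(results_m, config.alpha)
            artifacts["volcano_matched"] = (volcano_m, thr_m)
            _write("volcano_matched.tsv", volcano_m)
        if results_p is not None:
            volcano_p, thr_p = volcano_table(results_p, config.alpha)
            artifacts["volcano_propensity"] = (volcano_p, thr_p)
            _write("volcano_propensity.tsv", volcano_p)
        if results_m is not None and results_p is not None:
            report = dual_discovery(results_m, results_p, config.alpha)
            artifacts["discovery_report"] = report
            _write("discovery_report.tsv", report.table)
            comparison, lines = comparison_table(results_m, results_p, config.alpha)
            artifacts["comparison"] = (comparison, lines)
            _write("comparison.tsv", comparison)
            manifest.counts["discovered"] = len(report.discovered)

        stage = "manifest"
        manifest.reconcile()
        if outdir is not None:
            log.to_tsv(os.path.join(outdir, "exclusions.tsv"))
            written.append(os.path.join(outdir, "exclusions.tsv"))
            manifest.to_json(os.path.join(outdir, "manifest.json"))
        return report, manifest, artifacts
    except Exception as exc:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
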
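"""End-to-end orchestration: readings CSV in, stage artifacts + JSON report out.

Stage order: parse -> extract nocturnal segments -> exclusion filter ->
imputation -> NH episode detection -> NH/non-NH partition -> per-group
standardization, silhouette-guided Ward clustering, cluster summaries and
medoids -> Monte Carlo reliability test.  Every stage writes a CSV artifact
so any stage can be audited or re-run; the report is fully determined by
(input, config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cgm_io import (
    apply_exclusion_filter,
    exclusion_manifest,
    extract_nocturnal_segments,
    impute_gaps,
    parse_cgm_csv,
    standardize,
    write_segments_csv,
)
from .clustering import select_k, summaries_to_frame, summarize_cluster
from .config import PipelineConfig
from .monte_carlo import reliability_test
from .nh_detection import detect_nh_episodes, episodes_to_frame, partition_by_nh

logger = logging.getLogger(__name__)


def _stage_seed(seed: int, counter: int) -> int:
    """Fan the global seed out to independently reproducible per-stage seeds."""
    return int(np.random.default_rng([seed, counter]).integers(0, 2**31 - 1))


def _analyze_group(name, segments, config, seed, out_dir):
    """Cluster one NH/non-NH group and run its reliability test."""
    if len(segments) == 0:
        return {"group": name, "skipped": "empty group"}
    if len(segments) <= config.k_min:
        return {"group": name, "skipped": f"too few segments (n={len(segments)})"}
    zsegs = [standardize(s) for s in segments]
    override = config.k_override_nh if name == "NH" else config.k_override_non_nh
    sel = select_k(
        zsegs, config.k_min, min(config.k_max, len(segments) - 1),
        override=override, group=name,
    )
    sel.curve_frame().to_csv(out_dir / f"ss_curve_{name}.csv", index=False)

    labels = sel.solution.labels
    labels_df = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in segments],
            "night_date": [str(s.night_date) for s in segments],
            "cluster": labels,
        }
    )
    labels_df.to_csv(out_dir / f"labels_{name}.csv", index=False)

    summaries = []
    medoid_rows = []
    for cid in range(1, sel.solution.k + 1):
        idx = np.flatnonzero(labels == cid)
        members = [segments[i] for i in idx]
        member_eps = [
            detect_nh_episodes(segments[i], config.nh_threshold, config.min_duration_min)
            for i in idx
        ]
        summary = summarize_cluster(
            members,
            episodes=member_eps if name == "NH" else None,
            cluster_id=cid,
            standardized_members=[zsegs[i] for i in idx],
        )
        summaries.append(summary)
        med = segments[idx[summary.medoid_index]]
        medoid_rows.append(
            {
                "cluster": cid,
                "patient_id": med.patient_id,
                "night_date": str(med.night_date),
                **{f"slot_{i}": med.values[i] for i in range(len(med.values))},
            }
        )
    summaries_to_frame(summaries).to_csv(out_dir / f"summary_{name}.csv", index=False)
    pd.DataFrame(medoid_rows).to_csv(out_dir / f"medoids_{name}.csv", index=False)

    mc = reliability_test(
        zsegs,
        k=sel.solution.k,
        n_reps=config.n_reps,
        seed=seed,
        quantile_level=config.quantile_level,
        max_lag=config.max_lag,
        bias_correct=config.bias_correct,
        group=name,
    )
    pd.DataFrame({"rep": np.arange(config.n_reps), "null_ss": mc.null_ss}).to_csv(
        out_dir / f"null_ss_{name}.csv", index=False
    )
    return {
        "group": name,
        "n_segments": len(segments),
        "k_best": sel.k_best,
        "k_used": sel.solution.k,
        "k_overridden": sel.overridden,
        "silhouette": sel.solution.silhouette,
        "ss_curve": {int(k): float(s) for k, s in zip(sel.ks, sel.scores)},
        "cluster_sizes": {int(c): int((labels == c).sum()) for c in range(1, sel.solution.k + 1)},
        "monte_carlo": mc.to_dict(),
    }


def run_pipeline(input_csv, out_dir, config: PipelineConfig | None = None) -> dict:
    """Run the full analysis and return the report (also written as JSON)."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = parse_cgm_csv(
        input_csv,
        oor_policy=config.oor_policy,
        device_min=config.device_min,
        device_max=config.device_max,
    )
    logger.info("stage parse: %d records", len(records))

    raw_segments = []
    for rec in records:
        raw_segments.extend(extract_nocturnal_segments(rec, config.cadence_tol_s))
    logger.info("stage extract: %d raw segments", len(raw_segments))

    decisions = [
        apply_exclusion_filter(s, config.gap_run_exclude, config.missing_frac_exclude)
        for s in raw_segments
    ]
    exclusion_manifest(raw_segments, decisions).to_csv(
        out_dir / "exclusions.csv", index=False
    )
    kept = [impute_gaps(s) for s, d in zip(raw_segments, decisions) if d.keep]
    n_excluded = {"LONG_GAP": 0, "TOO_MANY_MISSING": 0}
    for d in decisions:
        if not d.keep:
            n_excluded[d.reason.value] += 1
    logger.info("stage filter+impute: kept %d, excluded %s", len(kept), n_excluded)
    write_segments_csv(kept, out_dir / "segments.csv")

    partition = partition_by_nh(kept, config.nh_threshold, config.min_duration_min)
    episodes_to_frame(partition, kept).to_csv(out_dir / "episodes.csv", index=False)
    pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in kept],
            "night_date": [str(s.night_date) for s in kept],
            "group": [
                "NH" if partition.episodes[(s.patient_id, s.night_date)] else "NON_NH"
                for s in kept
            ],
        }
    ).to_csv(out_dir / "partition.csv", index=False)
    logger.info(
        "stage partition: %d NH, %d non-NH",
        len(partition.nh_group), len(partition.non_nh_group),
    )

    groups = {}
    for i, (name, segs) in enumerate(
        (("NON_NH", partition.non_nh_group), ("NH", partition.nh_group))
    ):
        groups[name] = _analyze_group(name, segs, config, _stage_seed(config.seed, i), out_dir)

    report = {
        "software": {"name": "nocturne", "version": __version__},
        "seed": config.seed,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "input": {
            "path": str(input_csv),
            "n_records": len(records),
            "n_raw_segments": len(raw_segments),
            "n_kept": len(kept),
            "n_excluded": n_excluded,
            "n_imputed_slots": int(sum(s.imputed_mask.sum() for s in kept)),
        },
        "partition": {
            "n_nh": len(partition.nh_group),
            "n_non_nh": len(partition.non_nh_group),
        },
        "groups": groups,
    }
    assert report["input"]["n_kept"] + sum(n_excluded.values()) == len(raw_segments)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
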
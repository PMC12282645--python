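"""End-to-end analysis pipeline over an events table.

Stage order mirrors the validation analysis: rater consensus builds the
Reference, TSO windows are derived and short windows excluded per source,
scratch tracks are gap-merged and duration-filtered, epoch-level confusion
matrices are pooled into detection metrics, night-level normalized outcomes
feed participant and group characterization plus itch stratification, and
finally the agreement statistics (repeated-measures Bland-Altman of TSO
duration, mixed-model ICC of the scratch outcomes with cluster-bootstrap
CIs) compare each device to the Reference.

Every stage logs counts in/out; every night of input ends up either in an
analysis table or in the exclusion log, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as nio
from .agreement import BlandAltmanResult, ICCResult, bland_altman_repeated, bootstrap_icc
from .config import PipelineConfig
from .consensus import bout_consensus, tso_consensus
from .epochs import ConfusionMatrix, label_epochs, make_epochs, pool_and_score, score_night
from .intervals import EventTrack, Interval, filter_min_duration, merge_gaps, normalize_track
from .outcomes import (
    ProResponse,
    filter_pro_responses,
    group_summary,
    night_summary,
    participant_summary,
    stratify_by_itch,
)
from .tso import TsoRecord, derive_device_tso, exclude_short_tso, exclusion_summary, paired_overlap_window

logger = logging.getLogger(__name__)

REFERENCE = "Reference"


@dataclass
class PipelineResult:
    consensus_provenance: pd.DataFrame
    tso_table: pd.DataFrame
    exclusion_log: pd.DataFrame
    exclusion_counts: pd.DataFrame
    metrics: pd.DataFrame
    night_summaries: pd.DataFrame
    participant_summaries: pd.DataFrame
    group_summaries: pd.DataFrame
    itch_stratified: pd.DataFrame
    itch_band_summaries: pd.DataFrame
    agreement_icc: pd.DataFrame
    agreement_ba: pd.DataFrame
    out_dir: Optional[Path] = None


def _empty_track(pid: str, nid: str, source: str, kind: str = "scratch") -> EventTrack:
    return normalize_track([], participant_id=pid, night_id=nid, source=source, kind=kind)


def _single_interval(track: Optional[EventTrack]) -> Optional[Interval]:
    if track is None or track.is_empty:
        return None
    arr = track.intervals
    return Interval(float(arr[0, 0]), float(arr[-1, 1]))


def _metrics_row(metrics, device, epoch_s, level, group) -> dict:
    cm = metrics.counts
    return {
        "epoch_s": epoch_s,
        "device": device,
        "level": level,
        "group": group,
        "n_participants": metrics.n_participants,
        "n_participant_nights": metrics.n_participant_nights,
        "tp": cm.tp,
        "fp": cm.fp,
        "tn": cm.tn,
        "fn": cm.fn,
        "sensitivity": metrics.sensitivity,
        "precision": metrics.precision,
        "f1": metrics.f1,
        "balanced_accuracy": metrics.balanced_accuracy,
        "prevalence": metrics.prevalence,
    }


def run_pipeline(
    config: PipelineConfig,
    events: Optional[pd.DataFrame] = None,
    pros: Optional[pd.DataFrame] = None,
    participants: Optional[pd.DataFrame] = None,
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Run the full analysis; inputs may be DataFrames or config file paths.

    Deterministic given inputs, config and ``config.seed``.  When ``out_dir``
    (or ``config.out_dir``) is set, the report bundle is written there.
    """
    if events is None:
        if config.events_csv is None:
            raise ValueError("no events provided (neither DataFrame nor config.events_csv)")
        events, row_errors = nio.read_events(config.events_csv)
        for err in row_errors:
            logger.warning("events row error at line %d: %s", err.line, err.message)
    if pros is None and config.pro_csv:
        pros = pd.read_csv(config.pro_csv, dtype={"participant_id": str, "timestamp": str})
    if participants is None and config.participants_csv:
        participants = pd.read_csv(config.participants_csv, dtype=str)

    tracks = nio.events_to_tracks(events)
    nights = sorted({(k[0], k[1]) for k in tracks})
    devices = sorted({k[2] for k in tracks if k[3] == "sleep_period"})
    logger.info("loaded %d intervals over %d participant-nights; devices: %s",
                len(events), len(nights), devices)

    cohort_of: dict[str, str] = {}
    if participants is not None:
        cohort_of = dict(zip(participants["participant_id"], participants["cohort"]))

    # ----- consensus: Reference scratch track and Reference TSO per night
    provenance_rows = []
    ref_scratch: dict[tuple, EventTrack] = {}
    tso_records: list[TsoRecord] = []
    scratch_by_source: dict[tuple, EventTrack] = {}

    for pid, nid in nights:
        def rater(name: str, kind: str = "scratch") -> Optional[EventTrack]:
            return tracks.get((pid, nid, name, kind))

        r = {name: rater(name) or _empty_track(pid, nid, name) for name in ("R1", "R2", "R3", "R4", "R5")}
        res = bout_consensus(r["R1"], r["R2"], r["R3"], r["R4"], r["R5"], config.iou_threshold)
        ref_scratch[(pid, nid)] = res.final_track
        provenance_rows.append(
            {
                "participant_id": pid,
                "night_id": nid,
                "round_reached": res.round_reached,
                "iou_round1": res.iou_round1,
                "iou_round2": res.iou_round2,
            }
        )

        r1_tso = _single_interval(rater("R1", "tso"))
        r2_tso = _single_interval(rater("R2", "tso"))
        adj_tso = _single_interval(rater("R3", "tso"))
        if r1_tso is None or r2_tso is None:
            ref_tso = None
            adjudicated = None
        else:
            tso_res = tso_consensus(r1_tso, r2_tso, adj_tso, config.tso_tolerance_s)
            ref_tso = tso_res.final_tso
            adjudicated = tso_res.adjudicated
        tso_records.append(TsoRecord(pid, nid, REFERENCE, ref_tso))
        provenance_rows[-1]["tso_adjudicated"] = adjudicated

        for device in devices:
            sleep = tracks.get((pid, nid, device, "sleep_period"))
            dev_tso = (
                derive_device_tso(sleep, config.tso_merge_gap_min) if sleep is not None else None
            )
            tso_records.append(TsoRecord(pid, nid, device, dev_tso))
            scratch_by_source[(pid, nid, device)] = tracks.get(
                (pid, nid, device, "scratch")
            ) or _empty_track(pid, nid, device)

    consensus_provenance = pd.DataFrame(provenance_rows)
    n_adj = int(consensus_provenance["tso_adjudicated"].fillna(False).sum())
    logger.info("consensus: %d nights, rounds reached %s, %d TSO adjudications",
                len(consensus_provenance),
                consensus_provenance["round_reached"].value_counts().to_dict(), n_adj)

    # ----- TSO exclusion
    kept_records, exclusion_log = exclude_short_tso(tso_records, config.tso_min_hours)
    excl_counts = exclusion_summary(tso_records)
    logger.info("TSO exclusion (<%s h): %d of %d records excluded",
                config.tso_min_hours, len(exclusion_log), len(tso_records))
    kept: dict[tuple, TsoRecord] = {(r.participant_id, r.night_id, r.source): r for r in kept_records}

    tso_table = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "night_id": r.night_id,
                "source": r.source,
                "start_s": None if r.tso is None else r.tso.start_s,
                "end_s": None if r.tso is None else r.tso.end_s,
                "duration_h": r.duration_h,
                "excluded": r.excluded,
                "reason": r.exclusion_reason,
            }
            for r in tso_records
        ]
    )

    # ----- bout post-processing (merge small gaps, drop short bouts)
    def post(track: EventTrack) -> EventTrack:
        return filter_min_duration(
            merge_gaps(track, config.merge_gap_s), config.min_bout_s
        )

    ref_scratch = {key: post(t) for key, t in ref_scratch.items()}
    scratch_by_source = {key: post(t) for key, t in scratch_by_source.items()}

    # ----- within-night epoch metrics, pooled at cohort / participant level
    epoch_sizes = [config.epoch_s]
    if config.sensitivity_epoch_s:
        epoch_sizes.append(config.sensitivity_epoch_s)
    metric_rows = []
    per_night_cms: dict[tuple, dict[tuple, ConfusionMatrix]] = {}
    for eps in epoch_sizes:
        for device in devices:
            cms: dict[tuple, ConfusionMatrix] = {}
            for pid, nid in nights:
                ref_rec = kept.get((pid, nid, REFERENCE))
                dev_rec = kept.get((pid, nid, device))
                if ref_rec is None or dev_rec is None:
                    continue
                window = paired_overlap_window(ref_rec, dev_rec)
                if window is None:
                    logger.warning("night %s/%s: disjoint TSO windows for %s", pid, nid, device)
                    continue
                grid = make_epochs(window, eps)
                if grid.n_epochs == 0:
                    continue
                ref_labels = label_epochs(grid, ref_scratch[(pid, nid)])
                dev_labels = label_epochs(grid, scratch_by_source[(pid, nid, device)])
                cms[(pid, nid)] = score_night(ref_labels, dev_labels)
            per_night_cms[(eps, device)] = cms
            if not cms:
                continue
            pids = sorted({pid for pid, _ in cms})
            metric_rows.append(
                _metrics_row(
                    pool_and_score(list(cms.values()), len(pids), len(cms)),
                    device, eps, "overall", "all",
                )
            )
            by_cohort: dict[str, list] = {}
            for (pid, nid), cm in cms.items():
                by_cohort.setdefault(cohort_of.get(pid, "Unknown"), []).append((pid, cm))
            for cohort, items in sorted(by_cohort.items()):
                cohort_pids = sorted({pid for pid, _ in items})
                metric_rows.append(
                    _metrics_row(
                        pool_and_score([cm for _, cm in items], len(cohort_pids), len(items)),
                        device, eps, "cohort", cohort,
                    )
                )
            for pid in pids:
                items = [cm for (p, _), cm in cms.items() if p == pid]
                metric_rows.append(
                    _metrics_row(pool_and_score(items, 1, len(items)), device, eps, "participant", pid)
                )
    metrics = pd.DataFrame(metric_rows)

    # ----- night-level outcomes per source
    summary_rows = []
    for (pid, nid, source), rec in kept.items():
        track = ref_scratch[(pid, nid)] if source == REFERENCE else scratch_by_source[(pid, nid, source)]
        summary_rows.append(vars(night_summary(track, rec)))
    night_summaries = pd.DataFrame(summary_rows).sort_values(
        ["participant_id", "night_id", "source"]
    ).reset_index(drop=True)

    participant_summaries = participant_summary(night_summaries, offset=config.log_offset)
    participant_summaries["cohort"] = participant_summaries["participant_id"].map(
        lambda p: cohort_of.get(p, "Unknown")
    )
    ref_part = participant_summaries[participant_summaries["source"] == REFERENCE]
    group_summaries = group_summary(ref_part, "cohort") if len(ref_part) else pd.DataFrame()

    # ----- itch stratification (Reference nights, AD participants carry PROs)
    itch_stratified = pd.DataFrame()
    itch_band_summaries = pd.DataFrame()
    if pros is not None and len(pros):
        import datetime as _dt

        responses = [
            ProResponse(
                participant_id=str(row.participant_id),
                date=_dt.date.fromisoformat(str(row.date)),
                administration=str(row.administration),
                timestamp=_dt.time.fromisoformat(str(row.timestamp)),
                itch_nrs=int(row.itch_nrs),
            )
            for row in pros.itertuples()
        ]
        valid = filter_pro_responses(
            responses,
            _dt.time.fromisoformat(config.pro_window_start),
            _dt.time.fromisoformat(config.pro_window_end),
        )
        logger.info("PRO filter: %d of %d responses valid", len(valid), len(responses))
        bands = [tuple(b) for b in config.itch_bands]
        ref_nights = night_summaries[night_summaries["source"] == REFERENCE]
        itch_stratified = stratify_by_itch(ref_nights, valid, bands)
        if len(itch_stratified):
            itch_band_summaries = group_summary(itch_stratified, "itch_band")

    # ----- agreement statistics
    ba_rows, ba_results = [], {}
    icc_rows = []
    seed = int(config.seed)
    for i, device in enumerate(devices):
        pairs = []
        for pid, nid in nights:
            ref_rec = kept.get((pid, nid, REFERENCE))
            dev_rec = kept.get((pid, nid, device))
            if ref_rec is None or dev_rec is None:
                continue
            pairs.append(
                {
                    "participant": pid,
                    "night": nid,
                    "dht_tso_hours": dev_rec.duration_h,
                    "ref_tso_hours": ref_rec.duration_h,
                }
            )
        if len(pairs) >= 2:
            ba = bland_altman_repeated(
                pd.DataFrame(pairs), n_boot=config.bootstrap_n, seed=seed + 17 * (i + 1)
            )
            ba_results[device] = ba
            ba_rows.append(
                {
                    "device": device,
                    "n_pairs": ba.n_pairs,
                    "n_participants": ba.n_participants,
                    "bias_h": ba.bias,
                    "loa_low_h": ba.loa_low,
                    "loa_high_h": ba.loa_high,
                    "bias_ci_low": ba.bias_ci[0],
                    "bias_ci_high": ba.bias_ci[1],
                    "loa_low_ci_low": ba.loa_low_ci[0],
                    "loa_low_ci_high": ba.loa_low_ci[1],
                    "loa_high_ci_low": ba.loa_high_ci[0],
                    "loa_high_ci_high": ba.loa_high_ci[1],
                    "method": ba.method,
                }
            )

        for outcome in ("norm_duration", "norm_frequency"):
            rows = []
            for pid, nid in nights:
                if (pid, nid, REFERENCE) not in kept or (pid, nid, device) not in kept:
                    continue
                for source in (REFERENCE, device):
                    sub = night_summaries[
                        (night_summaries["participant_id"] == pid)
                        & (night_summaries["night_id"] == nid)
                        & (night_summaries["source"] == source)
                    ]
                    rows.append(
                        {
                            "participant": pid,
                            "night": nid,
                            "source": source,
                            "y": float(np.log(sub[outcome].iloc[0] + config.log_offset)),
                        }
                    )
            if not rows:
                continue
            long = pd.DataFrame(rows)
            for j, definition in enumerate(("adjusted", "unadjusted")):
                icc = bootstrap_icc(
                    long,
                    n_boot=config.bootstrap_n,
                    seed=seed + 101 * (i + 1) + j,
                    definition=definition,
                )
                icc_rows.append(
                    {
                        "outcome": outcome,
                        "comparison": f"{REFERENCE} vs {device}",
                        "definition": definition,
                        "estimate": icc.estimate,
                        "ci_low": icc.ci_low,
                        "ci_high": icc.ci_high,
                        "n_bootstrap": icc.n_bootstrap,
                        "n_used": icc.n_used,
                        "flagged": icc.flagged,
                        "var_participant": icc.components.var_participant,
                        "var_night": icc.components.var_night,
                        "var_residual": icc.components.var_residual,
                        "method": icc.components.method,
                    }
                )
    agreement_ba = pd.DataFrame(ba_rows)
    agreement_icc = pd.DataFrame(icc_rows)

    result = PipelineResult(
        consensus_provenance=consensus_provenance,
        tso_table=tso_table,
        exclusion_log=exclusion_log,
        exclusion_counts=excl_counts,
        metrics=metrics,
        night_summaries=night_summaries,
        participant_summaries=participant_summaries,
        group_summaries=group_summaries,
        itch_stratified=itch_stratified,
        itch_band_summaries=itch_band_summaries,
        agreement_icc=agreement_icc,
        agreement_ba=agreement_ba,
    )

    target = out_dir or config.out_dir
    if target:
        result.out_dir = write_report(result, config, target)
    return result


_REPORT_FILES = {
    "consensus_provenance": "consensus_provenance.csv",
    "tso_table": "tso.csv",
    "exclusion_log": "exclusions.csv",
    "exclusion_counts": "exclusion_counts.csv",
    "metrics": "metrics.csv",
    "night_summaries": "night_summaries.csv",
    "participant_summaries": "participant_summaries.csv",
    "group_summaries": "group_summaries.csv",
    "itch_stratified": "itch_stratified.csv",
    "itch_band_summaries": "itch_band_summaries.csv",
    "agreement_icc": "agreement_icc.csv",
    "agreement_ba": "agreement_ba.csv",
}


def write_report(result: PipelineResult, config: PipelineConfig, out_dir) -> Path:
    """Write the report bundle (CSVs + provenance JSON) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _REPORT_FILES.items():
        df = getattr(result, attr)
        df.to_csv(out / fname, index=False)
    config.write_provenance(out / "provenance.json")
    return out
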
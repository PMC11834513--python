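"""End-to-end convenience chain: recording -> windowed series -> summary."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .amplitude import (artifact_intervals_from_beats, compute_amp,
                        compute_mean_icp, summarize_patient, summary_frame)
from .io import ICPRecording, PatientMeta
from .morphology import classify_all, compute_psi
from .pulses import extract_pulses


def process_recording(rec: ICPRecording, psi_window_s: float = 300.0,
                      psi_shift_s: float = 10.0, min_pulses: int = 60
                      ) -> dict:
    """Run extraction, classification and windowed metrics on one recording.

    Returns a dict with the classified pulses and the three windowed
    series (``psi``, ``amp``, ``mean_icp``) every summary consumes.
    """
    pulses, valid_beats, artifact_beats, onsets = extract_pulses(rec)
    classified = classify_all(pulses)
    psi = compute_psi(classified, window_s=psi_window_s,
                      shift_s=psi_shift_s, min_pulses=min_pulses)
    amp = compute_amp(
        rec, artifact_intervals=artifact_intervals_from_beats(artifact_beats))
    icp = compute_mean_icp(rec)
    return {"onsets": onsets, "valid_beats": valid_beats,
            "artifact_beats": artifact_beats, "classified": classified,
            "psi": psi, "amp": amp, "mean_icp": icp}


def summarize_cohort(recordings: Sequence[ICPRecording],
                     metas: Sequence[PatientMeta],
                     psi_window_s: float = 300.0,
                     min_pulses: int = 60) -> pd.DataFrame:
    """Per-patient seven-day summaries for a cohort of recordings."""
    by_id = {m.patient_id: m for m in metas}
    summaries = []
    for rec in recordings:
        meta = by_id[rec.patient_id]
        out = process_recording(rec, psi_window_s=psi_window_s,
                                min_pulses=min_pulses)
        summaries.append(summarize_patient(meta, out["amp"], out["psi"],
                                           out["mean_icp"]))
    return summary_frame(summaries)
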
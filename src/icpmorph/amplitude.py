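"""Pulse amplitude (AmpICP), mean ICP, and per-patient summaries.

AmpICP is the peak-to-peak pressure (max - min) of the ICP signal within
non-overlapping 2-s windows; at heart rates of 60 bpm and above each
window holds at least two full beats, so the window range approximates the
pulse's peak-to-peak amplitude.  Patient summaries average the valid
windows of the first seven days of recording (truncated at decompressive
craniectomy when one occurred) and apply the cohort inclusion filters:
no EVD-measured ICP, no craniectomy before monitoring started, and no
terminal intracranial hypertension (mean ICP > 40 mm Hg).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ICPRecording, PatientMeta

#: seven days in seconds — the per-patient averaging horizon
SEVEN_DAYS_S = 168.0 * 3600.0

#: inclusion filter: terminal intracranial hypertension threshold, mm Hg
MEAN_ICP_EXCLUSION = 40.0


@dataclass
class PatientSummary:
    patient_id: str
    mean_icp: float | None
    amp_icp: float | None
    psi: float | None
    age: int
    rotterdam: int | None
    died6m: bool | None
    included: bool
    exclusion_reason: str | None = None


def compute_amp(rec: ICPRecording, window_s: float = 2.0,
                artifact_intervals: Sequence[tuple[float, float]] = (),
                ) -> pd.DataFrame:
    """AmpICP per non-overlapping window (max - min of the raw signal).

    A window is invalid if it overlaps any artifact interval (seconds,
    half-open) or any masked sample; the trailing partial window is
    dropped.  Returns columns ``time`` (window start, s), ``amp``,
    ``valid``.
    """
    n_win = int(rec.samples.size // round(window_s * rec.fs))
    wlen = int(round(window_s * rec.fs))
    mask = rec.mask()
    rows = []
    for k in range(n_win):
        lo, hi = k * wlen, (k + 1) * wlen
        t0, t1 = lo / rec.fs, hi / rec.fs
        seg = rec.samples[lo:hi]
        valid = bool(mask[lo:hi].all())
        if valid:
            for a, b in artifact_intervals:
                if a < t1 and b > t0:
                    valid = False
                    break
        rows.append({"time": t0, "amp": float(seg.max() - seg.min()),
                     "valid": valid})
    return pd.DataFrame(rows, columns=["time", "amp", "valid"])


def compute_mean_icp(rec: ICPRecording, window_s: float = 10.0
                     ) -> pd.DataFrame:
    """Mean ICP per window (mean of valid samples; NaN if < 50% valid)."""
    wlen = int(round(window_s * rec.fs))
    n_win = int(rec.samples.size // wlen)
    mask = rec.mask()
    rows = []
    for k in range(n_win):
        lo, hi = k * wlen, (k + 1) * wlen
        m = mask[lo:hi]
        if m.mean() >= 0.5:
            val = float(rec.samples[lo:hi][m].mean())
        else:
            val = np.nan
        rows.append({"time": lo / rec.fs, "mean_icp": val})
    return pd.DataFrame(rows, columns=["time", "mean_icp"])


def artifact_intervals_from_beats(artifact_beats) -> list[tuple[float, float]]:
    """Time intervals (s) covered by beats rejected as artifacts."""
    return [(b.t_onset, b.t_onset + b.duration_s) for b in artifact_beats]


def summarize_patient(meta: PatientMeta, amp: pd.DataFrame,
                      psi: pd.DataFrame, icp: pd.DataFrame,
                      monitor_start: float = 0.0) -> PatientSummary:
    """Seven-day patient summary with cohort inclusion filters.

    Window values contribute if their start time precedes
    ``min(168 h, dc_time - monitor_start)``.  Each summary value is the
    unweighted mean of its valid contributing windows.  Exclusion reasons:
    ``evd`` (ICP measured through a ventricular drain cannot give pulse
    morphology during drainage), ``dc-before-monitoring``, ``high-icp``
    (mean ICP > 40 mm Hg), or ``no-data``.
    """
    cutoff = SEVEN_DAYS_S
    dc_elapsed = None
    if meta.dc_time is not None:
        dc_elapsed = meta.dc_time - monitor_start
        cutoff = min(cutoff, max(dc_elapsed, 0.0))

    def _mean(df: pd.DataFrame, col: str, valid_col: str | None) -> float | None:
        if df is None or df.empty:
            return None
        sel = df[df["time"] < cutoff]
        if valid_col is not None:
            sel = sel[sel[valid_col]]
        vals = sel[col].dropna()
        return float(vals.mean()) if len(vals) else None

    mean_icp = _mean(icp, "mean_icp", None)
    amp_icp = _mean(amp, "amp", "valid")
    psi_val = _mean(psi, "psi", None)

    included, reason = True, None
    if meta.monitoring_modality == "evd":
        included, reason = False, "evd"
    elif dc_elapsed is not None and dc_elapsed <= 0:
        included, reason = False, "dc-before-monitoring"
    elif mean_icp is None and amp_icp is None and psi_val is None:
        included, reason = False, "no-data"
    elif mean_icp is not None and mean_icp > MEAN_ICP_EXCLUSION:
        included, reason = False, "high-icp"

    return PatientSummary(
        patient_id=meta.patient_id, mean_icp=mean_icp, amp_icp=amp_icp,
        psi=psi_val, age=meta.age, rotterdam=meta.rotterdam,
        died6m=meta.died6m, included=included, exclusion_reason=reason)


def summary_frame(summaries: Sequence[PatientSummary]) -> pd.DataFrame:
    """Patient summaries as a DataFrame (one row per patient)."""
    return pd.DataFrame([{
        "patient_id": s.patient_id, "mean_icp": s.mean_icp,
        "amp_icp": s.amp_icp, "psi": s.psi, "age": s.age,
        "rotterdam": s.rotterdam, "died6m": s.died6m,
        "included": s.included, "exclusion_reason": s.exclusion_reason,
    } for s in summaries])
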
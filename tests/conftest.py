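"""Shared fixtures: typical simulated recordings and scoring helpers."""

from __future__ import annotations

import numpy as np
import pytest

import icpmorph as im
from icpmorph.simulate import PatientDraw

#: a mid-cohort reference patient: 50 years, mean ICP 12 mm Hg, pulse
#: amplitude 8 mm Hg, balanced class mix
TYPICAL_PROBS = np.array([0.25, 0.35, 0.25, 0.15])


def typical_patient(amp: float = 8.0, mean_icp: float = 12.0,
                    probs: np.ndarray = TYPICAL_PROBS) -> PatientDraw:
    return PatientDraw(patient_id="P0", age=50, mean_icp=mean_icp,
                       class_probs=probs, amp_mean=amp, p_death=0.2,
                       died=False, rotterdam=3, gose6m=5)


def onset_scores(detected: np.ndarray, truth: np.ndarray, fs: float,
                 tol_s: float = 0.02) -> tuple[float, float]:
    """(recall, precision) of detected onsets vs ground truth, one-to-one
    matching within +/- tol_s."""
    tol = tol_s * fs
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    for g in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - g)
        j = int(np.argmin(d))
        if d[j] <= tol and not used[j]:
            used[j] = True
            matched += 1
    recall = matched / len(truth) if len(truth) else 1.0
    precision = matched / len(detected) if len(detected) else 1.0
    return recall, precision


@pytest.fixture(scope="session")
def clean_recording():
    """Two minutes of artifact-free ICP at 60 bpm with ground truth."""
    cfg = im.CohortSimConfig(seed=21, duration_s=120.0, hr_mean=60,
                             hr_sd=2.0, artifact_rate=0.0)
    rec, gt = im.synth_recording(cfg, typical_patient(),
                                 np.random.default_rng(21))
    return rec, gt


@pytest.fixture(scope="session")
def summary_cohort():
    """A 400-patient summary-level cohort for the statistics tests."""
    cfg = im.CohortSimConfig(n_patients=400, seed=101)
    return im.synth_cohort_summaries(cfg)
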
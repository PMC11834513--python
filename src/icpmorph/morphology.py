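"""Four-class pulse morphology rules and the pulse shape index (PSI).

The ICP pulse classically shows three sub-peaks: P1 (percussion), P2
(tidal) and P3 (dicrotic).  As cerebrospinal compliance falls the later
peaks grow relative to P1 until the pulse rounds into a single-peak wave.
Four classes span that progression:

* class 1 — normal waveform, dominant P1;
* class 2 — P2 elevated above P1, but P1 still higher than P3;
* class 3 — both P2 and P3 elevated above P1;
* class 4 — rounded/triangular pathological wave with one visible peak.

The classifier here realizes those definitions as deterministic rules on
detected sub-peak heights; it is a pure function of the normalized pulse
and sits behind a small interface so a learned model could be swapped in.

PSI summarizes a window of classified pulses as the fraction-weighted sum
of class numbers, PSI = sum_i i * p_i over classes i = 1..4 — equivalently
the mean class number — on a continuous 1-4 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .pulses import NormalizedPulse

#: label used for pulses with no detectable sub-peak
ARTIFACT = 0

#: sub-peak latency bands on the 180-sample normalized axis
#: (5-35%, 35-55%, 55-85% of the cycle)
ROLE_BANDS: dict[str, tuple[int, int]] = {
    "P1": (9, 63),
    "P2": (63, 99),
    "P3": (99, 153),
}


@dataclass(frozen=True)
class SubPeak:
    index: int        # sample index on the 180-sample axis
    height: float     # pulse value at the peak (smoothed)
    prominence: float


@dataclass
class ClassifiedPulse:
    pulse: NormalizedPulse
    label: int                       # 1-4, or ARTIFACT (0)
    subpeaks: dict[str, SubPeak] = field(default_factory=dict)
    t_onset: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (ARTIFACT, 1, 2, 3, 4):
            raise ValueError(f"invalid label {self.label}")
        if self.label == 4 and len(self.subpeaks) != 1:
            raise ValueError("class 4 requires exactly one detected sub-peak")


def detect_subpeaks(pulse: NormalizedPulse, prominence: float = 0.02,
                    smooth_sigma: float = 4.0) -> dict[str, SubPeak]:
    """Find sub-peak candidates and assign P1/P2/P3 roles by latency band.

    Local maxima of the (Gaussian-smoothed) pulse with topographic
    prominence >= ``prominence`` are candidates; each is assigned the role
    of the latency band it falls in, the most prominent candidate winning
    when a band holds several.  Candidates outside all bands are ignored.
    Smoothing (sigma in samples of the 180-sample axis) suppresses noise
    ripple that would otherwise masquerade as sub-peaks.
    """
    v = pulse.values
    if smooth_sigma > 0:
        v = gaussian_filter1d(v, smooth_sigma, mode="nearest")
    idx, props = sps.find_peaks(v, prominence=prominence)
    roles: dict[str, SubPeak] = {}
    for i, prom in zip(idx, props["prominences"]):
        for role, (lo, hi) in ROLE_BANDS.items():
            if lo <= i < hi:
                cand = SubPeak(index=int(i), height=float(v[i]),
                               prominence=float(prom))
                if role not in roles or cand.prominence > roles[role].prominence:
                    roles[role] = cand
                break
    return roles


def classify_pulse(pulse: NormalizedPulse, prominence: float = 0.02,
                   smooth_sigma: float = 4.0,
                   t_onset: float | None = None) -> ClassifiedPulse:
    """Assign the morphology class from detected sub-peak heights.

    With heights h1, h2, h3 (an absent role counts as -inf), in order:
    no roles -> artifact; exactly one role -> class 4; h1 >= h2 and
    h1 >= h3 -> class 1; h2 > h1 and h1 >= h3 -> class 2; otherwise ->
    class 3.  Ties fall to the lower class number (conservative).
    """
    roles = detect_subpeaks(pulse, prominence=prominence,
                            smooth_sigma=smooth_sigma)
    if not roles:
        label = ARTIFACT
    elif len(roles) == 1:
        label = 4
    else:
        h1 = roles["P1"].height if "P1" in roles else -np.inf
        h2 = roles["P2"].height if "P2" in roles else -np.inf
        h3 = roles["P3"].height if "P3" in roles else -np.inf
        if h1 >= h2 and h1 >= h3:
            label = 1
        elif h2 > h1 and h1 >= h3:
            label = 2
        else:
            label = 3
    return ClassifiedPulse(pulse=pulse, label=label, subpeaks=roles,
                           t_onset=t_onset)


def classify_all(pulses: Sequence[NormalizedPulse],
                 prominence: float = 0.02,
                 smooth_sigma: float = 4.0) -> list[ClassifiedPulse]:
    """Classify a sequence of pulses, carrying beat onset times along."""
    out = []
    for p in pulses:
        t = p.source_beat.t_onset if p.source_beat is not None else None
        out.append(classify_pulse(p, prominence=prominence,
                                  smooth_sigma=smooth_sigma, t_onset=t))
    return out


def compute_psi(classified: Sequence[ClassifiedPulse] | None = None,
                window_s: float = 300.0, shift_s: float = 10.0,
                min_pulses: int = 60,
                labels: Sequence[int] | None = None,
                times: Sequence[float] | None = None) -> pd.DataFrame:
    """PSI in sliding windows over time-ordered classified pulses.

    Each window [t, t + window_s) collects the class fractions p_i of its
    non-artifact pulses and evaluates PSI = sum_i i * p_i.  Windows with
    fewer than ``min_pulses`` non-artifact pulses yield NaN.  Labels and
    onset times may be passed directly instead of ClassifiedPulse objects.

    Returns a DataFrame with columns ``time`` (window center, s), ``psi``,
    ``n_pulses``, and class fractions ``p1``..``p4``.
    """
    if classified is not None:
        labels = [c.label for c in classified]
        times = [c.t_onset for c in classified]
        if any(t is None for t in times):
            raise ValueError("classified pulses must carry onset times")
    labels = np.asarray(labels, dtype=int)
    times = np.asarray(times, dtype=float)
    if labels.size != times.size:
        raise ValueError("labels and times must have equal length")
    if np.any(np.diff(times) < 0):
        raise ValueError("pulses must be time-ordered")

    rows = []
    if times.size:
        t_start = times[0]
        t_end = times[-1]
        starts = np.arange(t_start, max(t_start, t_end - window_s) + 1e-9,
                           shift_s)
        if starts.size == 0:
            starts = np.array([t_start])
        for w0 in starts:
            sel = labels[(times >= w0) & (times < w0 + window_s)]
            sel = sel[sel != ARTIFACT]
            n = sel.size
            if n >= min_pulses:
                fr = np.array([(sel == k).mean() for k in (1, 2, 3, 4)])
                psi = float(np.dot([1, 2, 3, 4], fr))
            else:
                fr = np.full(4, np.nan)
                psi = np.nan
            rows.append({"time": w0 + window_s / 2, "psi": psi,
                         "n_pulses": n, "p1": fr[0], "p2": fr[1],
                         "p3": fr[2], "p4": fr[3]})
    return pd.DataFrame(rows, columns=["time", "psi", "n_pulses",
                                       "p1", "p2", "p3", "p4"])
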
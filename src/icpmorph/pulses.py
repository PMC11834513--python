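"""Beat segmentation, artifact rejection, and pulse normalization.

The onset detector works in three passes: band-pass the signal to the
cardiac band, estimate the dominant cycle length per 10-s block by
autocorrelation, mark candidate systolic upstrokes as maxima of the first
difference with a refractory period, then localize each onset at the
preceding signal minimum.  Blocks without a dominant cardiac periodicity
yield no onsets and are reported as flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ICPRecording

#: cardiac band in Hz (40-180 bpm)
CARDIAC_BAND = (0.66, 3.0)

#: autocorrelation block length, seconds
BLOCK_S = 10.0

#: minimum normalized autocorrelation peak to accept a block as pulsatile
MIN_PERIODICITY = 0.15


@dataclass
class PulseBeat:
    """One cardiac pulse: the half-open sample span [onset, offset)."""

    onset_idx: int
    offset_idx: int
    raw: np.ndarray
    t_onset: float
    fs: float

    def __post_init__(self) -> None:
        if self.offset_idx <= self.onset_idx:
            raise ValueError("offset must exceed onset")
        self.raw = np.asarray(self.raw, dtype=float)

    @property
    def duration_s(self) -> float:
        return (self.offset_idx - self.onset_idx) / self.fs


@dataclass
class NormalizedPulse:
    """Amplitude-normalized pulse resampled to 180 samples in [0, 1]."""

    values: np.ndarray
    source_beat: PulseBeat | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != 180:
            raise ValueError(f"expected 180 samples, got {self.values.size}")
        if abs(self.values.min()) > 1e-9 or abs(self.values.max() - 1) > 1e-9:
            raise ValueError("normalized pulse must span [0, 1]")


@dataclass
class ArtifactThresholds:
    """Physiological-plausibility limits for single beats (all mm Hg / s).

    Defaults: beat duration within 0.3-2.0 s (40-200 bpm), peak-to-peak
    within 0.1-50 mm Hg, absolute pressure within -10..100 mm Hg, and no
    one-sample jump above 10 mm Hg.
    """

    min_duration_s: float = 0.3
    max_duration_s: float = 2.0
    min_range: float = 0.1
    max_range: float = 50.0
    min_pressure: float = -10.0
    max_pressure: float = 100.0
    max_jump: float = 10.0


def detect_onsets(rec: ICPRecording, return_flagged: bool = False):
    """Detect pulse onsets (sample indices of each beat's foot).

    Returns a strictly increasing integer array; with
    ``return_flagged=True`` also returns the list of (start_s, stop_s)
    block intervals in which no dominant cardiac periodicity was found.
    """
    fs = rec.fs
    x = rec.samples
    if x.size < 3 * fs:
        raise ValueError("recording shorter than 3 s")

    sos = sps.butter(2, CARDIAC_BAND, btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # light smoothing for derivative peaks and onset localization
    win = max(5, int(round(0.05 * fs)) | 1)
    deriv = np.gradient(sps.savgol_filter(x, win, 2))
    loc_win = max(5, int(round(0.05 * fs)) | 1)
    loc = np.convolve(x, np.ones(loc_win) / loc_win, mode="same")
    half = loc_win // 2

    block_n = int(BLOCK_S * fs)
    n_blocks = max(1, int(np.ceil(x.size / block_n)))
    upstrokes: list[tuple[int, float, int]] = []  # (index, strength, cycle)
    flagged: list[tuple[float, float]] = []
    for b in range(n_blocks):
        lo, hi = b * block_n, min(x.size, (b + 1) * block_n)
        if hi - lo < int(2 * fs):
            continue
        cycle = _dominant_cycle(bp[lo:hi], fs)
        if cycle is None:
            flagged.append((lo / fs, hi / fs))
            continue
        seg = deriv[lo:hi]
        height = 0.25 * np.percentile(seg, 98)
        if height <= 0:
            flagged.append((lo / fs, hi / fs))
            continue
        peaks, _ = sps.find_peaks(seg, height=height,
                                  distance=max(1, int(0.6 * cycle)))
        upstrokes.extend((lo + int(p), float(seg[p]), cycle) for p in peaks)

    # the per-block refractory period cannot see across block boundaries:
    # suppress any upstroke within 0.55 cycles of a stronger one globally
    kept = _suppress_close(upstrokes)
    candidates = set()
    for u, _, cycle in kept:
        w0 = max(0, u - int(0.4 * cycle))
        m = w0 + int(np.argmin(loc[w0:u + 1]))
        candidates.add(_debias_min(loc, m, half, x.size))

    onsets = _dedupe(np.array(sorted(candidates), dtype=int), fs)
    if return_flagged:
        return onsets, flagged
    return onsets


def _debias_min(loc: np.ndarray, m: int, half: int, n: int) -> int:
    """Correct the smoothing bias of a minimum found on a moving average.

    The moving-average minimum of an asymmetric V-shaped valley sits
    ``half * (a_L - a_R) / (a_L + a_R)`` samples into the shallower side,
    where a_L/a_R are the falling/rising slopes.  The pulse foot is such a
    valley (slow diastolic runoff, fast systolic upstroke), so the shift
    is estimated from local slopes and undone.
    """
    k = 2 * half + 1
    if m - k < 0 or m + k + 1 > n:
        return m
    a_left = max(0.0, float(np.mean(-np.diff(loc[m - k:m + 1]))))
    a_right = max(0.0, float(np.mean(np.diff(loc[m:m + k + 1]))))
    if a_left + a_right <= 0:
        return m
    return m + int(round(half * (a_right - a_left) / (a_right + a_left)))


def _suppress_close(upstrokes: list[tuple[int, float, int]]
                    ) -> list[tuple[int, float, int]]:
    """Non-maximum suppression of candidate upstrokes by derivative strength."""
    kept: list[tuple[int, float, int]] = []
    for u, s, c in sorted(upstrokes, key=lambda t: -t[1]):
        if all(abs(u - v) >= 0.55 * min(c, c2) for v, _, c2 in kept):
            kept.append((u, s, c))
    return sorted(kept)


def _dominant_cycle(bp_block: np.ndarray, fs: float) -> int | None:
    """Dominant cardiac cycle length (samples) by autocorrelation, or None."""
    z = bp_block - bp_block.mean()
    if np.allclose(z, 0):
        return None
    ac = sps.correlate(z, z, mode="full")[z.size - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    lo = int(fs / CARDIAC_BAND[1])
    hi = min(int(fs / CARDIAC_BAND[0]), ac.size - 1)
    if hi <= lo:
        return None
    peaks, props = sps.find_peaks(ac[lo:hi], height=MIN_PERIODICITY)
    if peaks.size == 0:
        return None
    best = peaks[np.argmax(props["peak_heights"])]
    return lo + int(best)


def _dedupe(onsets: np.ndarray, fs: float) -> np.ndarray:
    """Enforce a minimum separation of 0.25 s between onsets."""
    if onsets.size == 0:
        return onsets
    min_sep = int(0.25 * fs)
    keep = [int(onsets[0])]
    for o in onsets[1:]:
        if o - keep[-1] >= min_sep:
            keep.append(int(o))
    return np.array(keep, dtype=int)


def segment_beats(rec: ICPRecording, onsets: np.ndarray) -> list[PulseBeat]:
    """Cut the recording into beats spanning consecutive onsets.

    Beat k is [onset_k, onset_{k+1}); the last onset has no closing
    boundary and is discarded.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size and np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    beats = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        beats.append(PulseBeat(onset_idx=int(a), offset_idx=int(b),
                               raw=rec.samples[a:b].copy(),
                               t_onset=a / rec.fs, fs=rec.fs))
    return beats


def reject_artifacts(beats: list[PulseBeat],
                     thresholds: ArtifactThresholds | None = None,
                     valid_mask: np.ndarray | None = None,
                     ) -> tuple[list[PulseBeat], list[PulseBeat]]:
    """Split beats into (valid, artifact) by plausibility rules.

    A beat is an artifact if its duration, peak-to-peak range, absolute
    pressure, or maximum one-sample jump is outside the configured limits,
    or if it overlaps a masked (invalid) region of the recording.
    """
    th = thresholds or ArtifactThresholds()
    valid, artifacts = [], []
    for beat in beats:
        if _is_artifact(beat, th, valid_mask):
            artifacts.append(beat)
        else:
            valid.append(beat)
    return valid, artifacts


def _is_artifact(beat: PulseBeat, th: ArtifactThresholds,
                 valid_mask: np.ndarray | None) -> bool:
    if not (th.min_duration_s <= beat.duration_s <= th.max_duration_s):
        return True
    rng = beat.raw.max() - beat.raw.min()
    if not (th.min_range <= rng <= th.max_range):
        return True
    if beat.raw.min() < th.min_pressure or beat.raw.max() > th.max_pressure:
        return True
    if beat.raw.size > 1 and np.max(np.abs(np.diff(beat.raw))) > th.max_jump:
        return True
    if valid_mask is not None and not valid_mask[
            beat.onset_idx:beat.offset_idx].all():
        return True
    return False


def normalize_pulse(beat: PulseBeat) -> NormalizedPulse:
    """Resample a beat to 180 samples and min-max normalize it to [0, 1].

    The result is invariant under positive affine transforms of the raw
    beat (``a*x + b`` with a > 0), so downstream shape classification is
    independent of pulse amplitude and absolute pressure; resampling to a
    fixed length removes heart-rate dependence.
    """
    raw = beat.raw
    rng = raw.max() - raw.min()
    if rng <= 0:
        raise ValueError("zero-range beat cannot be normalized "
                         "(should have been rejected as artifact)")
    src = np.linspace(0.0, 1.0, raw.size)
    tgt = np.linspace(0.0, 1.0, 180)
    resampled = np.interp(tgt, src, raw)
    lo, hi = resampled.min(), resampled.max()
    values = (resampled - lo) / (hi - lo)
    return NormalizedPulse(values=values, source_beat=beat)


def extract_pulses(rec: ICPRecording,
                   thresholds: ArtifactThresholds | None = None):
    """Full extraction chain: onsets -> beats -> artifact split -> normalize.

    Returns (normalized_pulses, valid_beats, artifact_beats, onsets).
    """
    onsets = detect_onsets(rec)
    beats = segment_beats(rec, onsets)
    valid, artifacts = reject_artifacts(beats, thresholds,
                                        valid_mask=rec.valid_mask)
    normalized = [normalize_pulse(b) for b in valid]
    return normalized, valid, artifacts, onsets
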
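"""Epoch extraction, pulse-artifact excision, and anti-aliased decimation.

Conventions used throughout the pipeline: sample windows are half-open,
0-based, and t = 0 sits at the alignment event sample.  Recordings are assumed
referenced on ingest; no re-referencing stage exists.  The optional two-round
ICA cleanup used on real data is delegated to an external decomposition
routine behind :func:`apply_component_rejection` and is disabled by default on
synthetic data.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .containers import EpochSet, Recording

__all__ = [
    "extract_epochs",
    "excise_tms_artifact",
    "decimate",
    "apply_component_rejection",
]

log = logging.getLogger(__name__)


def extract_epochs(
    rec: Recording,
    align_label: str,
    window: tuple[float, float],
    baseline: tuple[float, float] | None = None,
    metadata: pd.DataFrame | None = None,
) -> EpochSet:
    """Extract event-aligned epochs from a continuous recording.

    ``window = (pre, post)`` in seconds yields the half-open sample window
    ``[event - pre*fs, event + post*fs)``; events whose window falls outside
    the recording are dropped with a logged count.  If ``baseline`` (start,
    end, seconds relative to the alignment event) is given, the per-channel
    mean over that interval is subtracted per trial.  If ``metadata`` carries
    a ``<label>_sample`` column (e.g. ``tms_sample``), rows are matched to
    events by sample index and attached.
    """
    pre, post = window
    fs = rec.fs
    pre_n = int(round(pre * fs))
    post_n = int(round(post * fs))
    n_times = pre_n + post_n
    if n_times <= 0:
        raise ValueError("window must span at least one sample")
    samples = rec.event_samples(align_label)
    if samples.size == 0:
        raise ValueError(f"no events labeled {align_label!r} in recording")
    keep = (samples - pre_n >= 0) & (samples + post_n <= rec.n_samples)
    if not np.all(keep):
        log.info("extract_epochs: dropped %d/%d events with incomplete windows",
                 int((~keep).sum()), samples.size)
    samples = samples[keep]
    if samples.size == 0:
        raise ValueError("every alignment event falls outside the recording")
    data = np.stack([rec.signal[:, s - pre_n:s + post_n] for s in samples])
    times = (np.arange(n_times) - pre_n) / fs
    if baseline is not None:
        b0, b1 = baseline
        if b0 < times[0] or b1 > times[-1] + 1.0 / fs:
            raise ValueError("baseline interval must lie inside the epoch window")
        sel = (times >= b0) & (times < b1)
        if not sel.any():
            raise ValueError("baseline interval contains no samples")
        data = data - data[:, :, sel].mean(axis=2, keepdims=True)
    md = None
    if metadata is not None:
        col = f"{align_label.lower()}_sample"
        if col in metadata.columns:
            lut = {int(s): i for i, s in enumerate(metadata[col])}
            rows = [lut[int(s)] for s in samples if int(s) in lut]
            if len(rows) != samples.size:
                raise ValueError("metadata does not cover every alignment event")
            md = metadata.iloc[rows].reset_index(drop=True)
        else:
            if len(metadata) != samples.size:
                raise ValueError("metadata rows do not match epoch count")
            md = metadata.reset_index(drop=True)
    return EpochSet(data=data, times=times, fs=fs, channels=list(rec.channels),
                    align_label=align_label, metadata=md)


def excise_tms_artifact(
    ep: EpochSet,
    pulse_offset: float = 0.0,
    discard_ms: float = 60.0,
) -> EpochSet:
    """Replace the post-pulse discard window by linear interpolation.

    Samples in the half-open window ``[pulse_offset, pulse_offset +
    discard_ms)`` are replaced, per channel and trial, by linear interpolation
    between the last retained sample before and the first retained sample
    after the window, and flagged in the bad-sample mask.  All other samples
    are returned bit-identical.  If the window covers an epoch edge, the
    nearest retained value is held (one-sided), logged.
    """
    out = ep.copy()
    if discard_ms <= 0:
        return out
    fs = ep.fs
    t0 = int(round((pulse_offset - ep.times[0]) * fs))
    n_disc = int(round(discard_ms / 1000.0 * fs))
    t1 = t0 + n_disc
    n = ep.n_times
    if t1 <= 0 or t0 >= n:
        raise ValueError("discard window does not intersect the epoch")
    lo = max(t0, 0)
    hi = min(t1, n)
    left = lo - 1
    right = hi
    if left < 0 and right >= n:
        raise ValueError("discard window covers the entire epoch")
    idx = np.arange(lo, hi)
    if left < 0:
        log.info("excise_tms_artifact: window touches epoch start; holding right value")
        out.data[:, :, idx] = out.data[:, :, right][:, :, None]
    elif right >= n:
        log.info("excise_tms_artifact: window touches epoch end; holding left value")
        out.data[:, :, idx] = out.data[:, :, left][:, :, None]
    else:
        w = (idx - left) / (right - left)
        a = out.data[:, :, left][:, :, None]
        b = out.data[:, :, right][:, :, None]
        out.data[:, :, idx] = a + (b - a) * w[None, None, :]
    out.mask[:, idx] = True
    return out


def _design_final_lowpass(fs_in: float, target_fs: float) -> np.ndarray:
    """Kaiser FIR with 6 dB point at 0.4*target_fs, stopband from 0.5*target_fs."""
    width_hz = 0.2 * target_fs  # transition band centered on the cutoff
    numtaps, beta = scipy.signal.kaiserord(50.0, width_hz / (fs_in / 2.0))
    numtaps |= 1
    return scipy.signal.firwin(numtaps, 0.4 * target_fs, window=("kaiser", beta), fs=fs_in)


def decimate(ep: EpochSet, target_fs: float) -> EpochSet:
    """Anti-aliased integer decimation to ``target_fs``.

    Zero-phase low-pass at 0.4 × target_fs, then integer downsampling.  The
    decimation factor is derived from the rates; non-integer ratios are
    rejected with the nearest valid rates named.  Large factors are realized
    in stages (intermediate FIR decimation, then the final 0.4×target filter)
    to keep filter lengths short relative to the epoch.
    """
    ratio = ep.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        valid = sorted({ep.fs / q for q in (factor, factor + 1) if q >= 1})
        raise ValueError(
            f"target_fs={target_fs:g} does not integer-divide fs={ep.fs:g}; "
            f"nearest valid rates: {', '.join(f'{v:g}' for v in valid)} Hz"
        )
    if factor == 1:
        return ep.copy()
    data = ep.data
    fs = ep.fs
    rem = factor
    # stages of <= 4x each; every stage is a zero-phase Kaiser FIR (odd-symmetric
    # padding, so constants and affine trends survive the epoch edges) + slicing
    while rem > 1:
        q = 4 if rem % 4 == 0 else (2 if rem % 2 == 0 else rem)
        stage_fs = fs / q
        taps = _design_final_lowpass(fs, target_fs if stage_fs == target_fs else stage_fs)
        padlen = min(3 * len(taps), data.shape[2] - 1)
        data = scipy.signal.filtfilt(taps, [1.0], data, axis=2, padlen=padlen)
        data = data[:, :, ::q]
        fs = stage_fs
        rem //= q
    times = ep.times[::factor][: data.shape[2]]
    # an output sample is bad if any source sample in its block was bad
    n_out = data.shape[2]
    pad = n_out * factor - ep.mask.shape[1]
    src = np.pad(ep.mask, ((0, 0), (0, max(pad, 0))))[:, : n_out * factor]
    mask = src.reshape(ep.mask.shape[0], n_out, factor).any(axis=2)
    return EpochSet(data=data, times=times, fs=target_fs, channels=list(ep.channels),
                    align_label=ep.align_label,
                    metadata=None if ep.metadata is None else ep.metadata.copy(),
                    mask=mask)


def apply_component_rejection(
    ep: EpochSet,
    decompose: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None,
    reject: Callable[[np.ndarray], Sequence[int]] | None,
) -> EpochSet:
    """Narrow interface for an external component-rejection (ICA-style) pass.

    ``decompose`` maps the concatenated (channels x samples) data to
    ``(mixing, sources)``; ``reject`` returns indices of source components to
    zero out before back-projection.  With either callable ``None`` the input
    is returned unchanged — the default on synthetic data.
    """
    if decompose is None or reject is None:
        return ep.copy()
    out = ep.copy()
    flat = np.concatenate(list(out.data), axis=1)  # channels x (trials*time)
    mixing, sources = decompose(flat)
    bad = list(reject(sources))
    sources = sources.copy()
    sources[bad, :] = 0.0
    cleaned = mixing @ sources
    out.data = cleaned.reshape(out.n_channels, out.n_trials, out.n_times).transpose(1, 0, 2)
    return out
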
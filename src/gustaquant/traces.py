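"""Response extraction from integrated nerve and fura-2 ratio recordings.

Nerve responses: the integrated whole-nerve signal is averaged over each
30 s stimulus window (S) and over the 10 s immediately before onset (B);
the reported response is the baseline-normalized ``R = (S − B)/B``, which
makes recordings comparable across animals without assuming any one
stimulus is spared. An optional mode re-normalizes R to a reference
stimulus (e.g. NH4Cl) instead.

Calcium responses: the 340/380 emission ratio's baseline B is the mean of
the first 10–15 s of recording; the peak P is the maximum during the
stimulus window when a response is visible, otherwise the value 30 s
after stimulus onset. ``ΔR = P − B`` and the normalized response is
``ΔR/P``. "Visible" is operationalized reproducibly: the lightly smoothed
trace must exceed baseline by ``k`` baseline noise SDs (default k = 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Stimulus, TraceRecording

__all__ = ["nerve_response", "calcium_response"]


def _window_slice(trace: TraceRecording, start_s: float, end_s: float) -> slice:
    fs = trace.sampling_rate
    i0 = int(np.ceil(start_s * fs - 1e-9))
    i1 = int(np.floor(end_s * fs - 1e-9)) + 1
    return slice(max(i0, 0), min(i1, len(trace.values)))


def nerve_response(
    trace: TraceRecording,
    baseline_s: float = 10.0,
    normalize_to: str | None = None,
) -> pd.DataFrame:
    """Baseline-normalized mean response per stimulus.

    Per stimulus: ``B`` = mean over the ``baseline_s`` seconds immediately
    before onset, ``S`` = mean over the stimulus window, ``R = (S − B)/B``.
    R is invariant to rescaling the whole trace by any positive constant.
    ``normalize_to`` optionally divides every R by the R of the named
    stimulus (reference-normalized mode).

    Raises if any baseline is non-positive (normalization undefined) or a
    baseline window would overlap the preceding stimulus.
    """
    if trace.kind != "nerve":
        raise ValueError("nerve_response requires a nerve recording")
    rows = []
    prev_offset = 0.0
    for stim in trace.stimuli:
        b_start = stim.onset - baseline_s
        if b_start < -1e-9:
            raise ValueError(
                f"stimulus {stim.label!r} has less than {baseline_s} s of "
                "recording before onset"
            )
        if b_start < prev_offset - 1e-9:
            raise ValueError(
                f"baseline window of {stim.label!r} overlaps the previous "
                "stimulus"
            )
        b = float(np.mean(trace.values[_window_slice(trace, b_start, stim.onset)]))
        s = float(np.mean(trace.values[_window_slice(trace, stim.onset, stim.offset)]))
        if b <= 0:
            raise ValueError(
                f"non-positive baseline for {stim.label!r}: normalization "
                "undefined"
            )
        rows.append(
            {
                "stimulus": stim.label,
                "onset_s": stim.onset,
                "baseline": b,
                "response_mean": s,
                "response": (s - b) / b,
            }
        )
        prev_offset = stim.offset
    table = pd.DataFrame(rows)
    if normalize_to is not None:
        ref = table.loc[table["stimulus"] == normalize_to, "response"]
        if ref.empty:
            raise ValueError(f"reference stimulus {normalize_to!r} not found")
        table["response_relative"] = table["response"] / float(ref.iloc[0])
    return table


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(x)]
    return out


def calcium_response(
    trace: TraceRecording,
    baseline_s: float = 10.0,
    k_sd: float = 3.0,
    smooth_samples: int = 5,
    fallback_delay_s: float = 30.0,
    normalize_to_max: bool = False,
) -> pd.DataFrame:
    """Peak ΔR per stimulus from a fura-2 ratio trace.

    ``B`` is the mean of the first ``baseline_s`` seconds of recording
    (10–15 s supported). The trace is lightly smoothed with a
    ``smooth_samples`` moving average (1 disables smoothing); a response
    is "visible" when the smoothed trace exceeds ``B + k_sd·SD`` within
    the stimulus window, where SD is the raw baseline noise SD. ``P`` is
    then the smoothed maximum over the window — reading the peak off the
    smoothed trace keeps the max-of-noise bias at the level of the
    smoothed noise. Otherwise ``P`` is the raw value ``fallback_delay_s``
    after onset and the row is flagged ``no_visible_response``.
    ``ΔR = P − B``; ``normalized = ΔR/P`` per trace (or ΔR divided by the
    largest P across stimuli when ``normalize_to_max`` is set). ΔR is
    invariant to adding a constant to the whole trace.
    """
    if trace.kind != "calcium":
        raise ValueError("calcium_response requires a calcium recording")
    if not 10.0 - 1e-9 <= baseline_s <= 15.0 + 1e-9:
        raise ValueError("baseline window must lie in the 10-15 s range")
    if trace.stimuli and trace.stimuli[0].onset < baseline_s - 1e-9:
        raise ValueError(
            "first stimulus begins before the baseline window ends"
        )
    base_sl = _window_slice(trace, 0.0, baseline_s)
    baseline_raw = trace.values[base_sl]
    b = float(np.mean(baseline_raw))
    smooth = _moving_average(trace.values, smooth_samples)
    sd_raw = float(np.std(baseline_raw, ddof=1)) if base_sl.stop > 1 else 0.0

    rows = []
    for stim in trace.stimuli:
        win = _window_slice(trace, stim.onset, stim.offset)
        visible = bool(np.max(smooth[win]) - b > k_sd * sd_raw)
        if visible:
            p = float(np.max(smooth[win]))
        else:
            t_fb = stim.onset + fallback_delay_s
            idx = int(round(t_fb * trace.sampling_rate))
            if idx >= len(trace.values):
                raise ValueError(
                    f"recording too short for the {fallback_delay_s:g} s "
                    f"fallback reading of {stim.label!r}"
                )
            p = float(trace.values[idx])
        dr = p - b
        rows.append(
            {
                "stimulus": stim.label,
                "onset_s": stim.onset,
                "baseline": b,
                "peak": p,
                "delta_r": dr,
                "no_visible_response": not visible,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        denom = table["peak"].max() if normalize_to_max else table["peak"]
        with np.errstate(divide="ignore", invalid="ignore"):
            table["normalized"] = np.where(
                np.asarray(denom) != 0, table["delta_r"] / denom, np.nan
            )
    return table
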
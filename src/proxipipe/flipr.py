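"""Quantification of membrane-potential (FLIPR-style) fluorescence traces.

A trace records well fluorescence over time: a baseline period, addition of
a cAMP agonist (forskolin) that stimulates channel-dependent membrane
depolarization seen as a fluorescence rise, and a later addition of a
channel inhibitor that collapses the channel-dependent component.  The
readout is normalized as dF/F0 against the mean baseline fluorescence; the
response is the peak dF/F0 in the agonist window and the inhibitor-sensitive
fraction is the drop after inhibitor addition relative to that peak — 1 for
a fully channel-dependent response, ~0 for an inhibitor-insensitive one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

BASELINE_WINDOW = 180.0  # seconds of baseline read before the agonist


@dataclass
class FLIPRTrace:
    time: np.ndarray  # seconds, strictly increasing
    fluorescence: np.ndarray  # arbitrary units, >= 0
    fsk_time: float  # agonist addition
    inh_time: float  # inhibitor addition

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValidationError("time and fluorescence differ in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(self.fluorescence < 0):
            raise ValidationError("fluorescence must be non-negative")
        if not (self.time[0] <= self.fsk_time < self.inh_time <= self.time[-1]):
            raise ValidationError(
                "event times must satisfy start <= fsk_time < inh_time <= end"
            )


@dataclass(frozen=True)
class FLIPRResponse:
    f0: float
    peak_dff0: float
    inhibitor_sensitive_fraction: float  # NaN when no agonist response
    responded: bool  # False mirrors uninduced / trafficking-dead controls
    fraction_in_range: bool  # fraction within [0, 1]


def compute_dff0(
    trace: FLIPRTrace, baseline_window: float = BASELINE_WINDOW
) -> tuple[np.ndarray, float]:
    """Normalize a trace to (F - F0) / F0 with F0 the mean baseline.

    The baseline is the window [t0, t0 + baseline_window] and must end at
    or before the agonist addition and contain >= 3 samples.
    """
    t0 = trace.time[0]
    if t0 + baseline_window > trace.fsk_time:
        raise ValidationError("baseline window extends past the agonist addition")
    sel = trace.time <= t0 + baseline_window
    if sel.sum() < 3:
        raise ValidationError("fewer than 3 samples in the baseline window")
    f0 = float(trace.fluorescence[sel].mean())
    if f0 <= 0:
        raise ValidationError("non-positive baseline fluorescence")
    return (trace.fluorescence - f0) / f0, f0


def quantify_response(
    trace: FLIPRTrace,
    baseline_window: float = BASELINE_WINDOW,
    smooth_width: int = 1,
) -> FLIPRResponse:
    """Peak dF/F0 after the agonist and the inhibitor-sensitive fraction.

    The peak is the maximum normalized sample in (fsk_time, inh_time]; with
    ``smooth_width > 1`` a centred moving average of that many samples is
    applied first.  The post-inhibitor level is the mean over the final 20%
    of samples after inh_time, and the inhibitor-sensitive fraction is
    (peak - post) / peak when the peak is positive; otherwise the trace is
    flagged as not responding.
    """
    dff0, f0 = compute_dff0(trace, baseline_window)
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        dff0 = np.convolve(dff0, kernel, mode="same")
    window = (trace.time > trace.fsk_time) & (trace.time <= trace.inh_time)
    if not window.any():
        raise ValidationError("no samples in the agonist window")
    peak = float(dff0[window].max())
    post_idx = np.nonzero(trace.time > trace.inh_time)[0]
    if post_idx.size == 0:
        raise ValidationError("no samples after the inhibitor addition")
    n_tail = max(1, int(np.ceil(0.2 * post_idx.size)))
    post_level = float(dff0[post_idx[-n_tail:]].mean())
    if peak <= 0:
        warnings.warn("no agonist response (peak dF/F0 <= 0)")
        return FLIPRResponse(f0, peak, float("nan"), False, False)
    fraction = (peak - post_level) / peak
    in_range = 0.0 <= fraction <= 1.0
    if not in_range:
        warnings.warn(f"inhibitor-sensitive fraction outside [0, 1]: {fraction:.3f}")
    return FLIPRResponse(f0, peak, float(fraction), True, in_range)


# -- TSV IO ----------------------------------------------------------------


def read_traces(trace_path, events_path) -> dict[str, FLIPRTrace]:
    """Read per-well traces from a (time, well, fluorescence) TSV plus an
    events sidecar (well, fsk_time, inh_time)."""
    traces = pd.read_csv(trace_path, sep="\t")
    for col in ("time", "well", "fluorescence"):
        if col not in traces.columns:
            raise ParseError(f"trace file missing column {col!r}", path=trace_path, line=1)
    events = pd.read_csv(events_path, sep="\t")
    for col in ("well", "fsk_time", "inh_time"):
        if col not in events.columns:
            raise ParseError(f"events file missing column {col!r}", path=events_path, line=1)
    events = events.set_index("well")
    out = {}
    for well, grp in traces.groupby("well"):
        if well not in events.index:
            raise ValidationError(f"no event times for well {well!r}")
        grp = grp.sort_values("time")
        out[str(well)] = FLIPRTrace(
            time=grp["time"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
            fsk_time=float(events.at[well, "fsk_time"]),
            inh_time=float(events.at[well, "inh_time"]),
        )
    return out


def write_traces(traces: dict[str, FLIPRTrace], trace_path, events_path) -> None:
    rows = []
    ev = []
    for well in sorted(traces):
        tr = traces[well]
        rows.extend((t, well, f) for t, f in zip(tr.time, tr.fluorescence))
        ev.append((well, tr.fsk_time, tr.inh_time))
    pd.DataFrame(rows, columns=["time", "well", "fluorescence"]).to_csv(
        trace_path, sep="\t", index=False, lineterminator="\n"
    )
    pd.DataFrame(ev, columns=["well", "fsk_time", "inh_time"]).to_csv(
        events_path, sep="\t", index=False, lineterminator="\n"
    )
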
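"""Extracted-ion-chromatogram (XIC) peak areas from MS1 scans.

For every called product the elution peak is integrated in two passes:
within each MS1 scan, centroid intensities inside a narrow m/z window
around the product ion are summed (the m/z dimension); across scans inside
a retention-time window around the triggering MS2 scan, the resulting
per-scan signal is integrated by the trapezoid rule (the time dimension),
after trimming leading/trailing scans below a fraction of the apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msio import RawRun

__all__ = ["XicConfig", "XicResult", "integrate_xic"]


@dataclass
class XicConfig:
    """mz_halfwidth (Da), rt_halfwindow (minutes), boundary trim fraction."""

    mz_halfwidth: float = 0.005
    rt_halfwindow: float = 0.5
    boundary_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.mz_halfwidth <= 0 or self.rt_halfwindow <= 0:
            raise ValueError("mz_halfwidth and rt_halfwindow must be > 0")
        if not (0 <= self.boundary_fraction < 1):
            raise ValueError("boundary_fraction must be in [0, 1)")


@dataclass
class XicResult:
    auc: float  # intensity * minutes
    rt_bounds: tuple[float, float] | None
    n_scans: int
    empty_window: bool = False


def integrate_xic(
    run: RawRun,
    target_mz: float,
    anchor_rt: float,
    config: XicConfig | None = None,
) -> XicResult:
    """Trapezoidal XIC area at ``target_mz`` around ``anchor_rt``.

    Linear in intensity and additive over disjoint retention-time segments;
    returns 0 (flagged) when no MS1 scan falls in the window.
    """
    config = config or XicConfig()
    times: list[float] = []
    signal: list[float] = []
    for scan in run.ms1():
        if abs(scan.retention_time - anchor_rt) > config.rt_halfwindow:
            continue
        lo = np.searchsorted(scan.mz, target_mz - config.mz_halfwidth, side="left")
        hi = np.searchsorted(scan.mz, target_mz + config.mz_halfwidth, side="right")
        times.append(scan.retention_time)
        signal.append(float(scan.intensity[lo:hi].sum()))
    if not times:
        return XicResult(auc=0.0, rt_bounds=None, n_scans=0, empty_window=True)

    t = np.asarray(times)
    s = np.asarray(signal)
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]

    if s.max() > 0 and config.boundary_fraction > 0:
        floor = config.boundary_fraction * s.max()
        keep = np.nonzero(s >= floor)[0]
        if keep.size == 0:
            return XicResult(auc=0.0, rt_bounds=None, n_scans=0, empty_window=True)
        t, s = t[keep[0] : keep[-1] + 1], s[keep[0] : keep[-1] + 1]

    auc = float(np.trapezoid(s, t)) if t.size > 1 else 0.0
    return XicResult(
        auc=auc, rt_bounds=(float(t[0]), float(t[-1])), n_scans=int(t.size)
    )
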
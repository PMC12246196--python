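"""MS2 spectral preprocessing and precursor-window feature extraction.

Every experimental and reference fragment spectrum passes through the same
four cleaning steps before scoring:

1. strip the precursor and all high-mass fragments (m/z >= precursor - margin),
2. drop fragments below a fraction of the surviving base peak,
3. sum intensities into fixed-width m/z bins anchored at zero,
4. normalise to base peak = 1.

Feature extraction is MS2-centric: an experimental "feature" is a single
data-dependent MS2 scan whose recorded precursor m/z falls within a tight
absolute window (default 3 mDa) of an expected glycoside adduct m/z for the
reaction mix; MS1 scans are consulted only later for peak-area integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .msio import PeakSpectrum, RawRun

logger = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "Feature", "clean_spectrum", "bin_peaks", "extract_features"]


@dataclass
class PreprocessConfig:
    """Cleaning knobs. Defaults follow the screening protocol.

    precursor_strip_margin : Da
        Fragments at or above ``precursor_mz - margin`` are removed (1.6).
    intensity_floor_fraction : unitless
        Fragments below this fraction of the surviving base peak are removed
        (0.01, i.e. 1%).
    bin_width : Da
        Width of the half-open m/z bins intensities are summed into (0.020).
    normalize : bool
        Scale so the base peak is 1.0 after binning.
    """

    precursor_strip_margin: float = 1.6
    intensity_floor_fraction: float = 0.01
    bin_width: float = 0.020
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.precursor_strip_margin < 0:
            raise ValueError("precursor_strip_margin must be >= 0")
        if not (0 <= self.intensity_floor_fraction < 1):
            raise ValueError("intensity_floor_fraction must be in [0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass
class Feature:
    """An MS2 scan admitted by the precursor filter, with cleaned peaks."""

    run_id: str
    scan_id: str
    precursor_mz: float
    retention_time: float
    spectrum: PeakSpectrum  # cleaned
    matched_target: tuple[str, int, str]  # (compound_id, degree, adduct label)
    target_mz: float


def bin_peaks(
    mz: np.ndarray, intensity: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sum intensities into half-open bins [i*w, (i+1)*w); m/z = bin centre.

    Conserves total intensity and is idempotent at fixed width (a bin centre
    maps back into its own bin).
    """
    if mz.size == 0:
        return mz, intensity
    idx = np.floor(mz / bin_width).astype(np.int64)
    uniq, inverse = np.unique(idx, return_inverse=True)
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, intensity)
    centers = (uniq + 0.5) * bin_width
    return centers, summed


def clean_spectrum(
    spectrum: PeakSpectrum, config: PreprocessConfig | None = None
) -> PeakSpectrum:
    """Apply strip -> floor -> bin -> normalise to one MS2 spectrum.

    An empty result is valid (returned with zero peaks) — it simply scores 0
    against every reference.
    """
    config = config or PreprocessConfig()
    if spectrum.precursor_mz is None:
        raise ValueError("clean_spectrum requires a precursor m/z")
    mz, intensity = spectrum.mz, spectrum.intensity

    keep = mz < spectrum.precursor_mz - config.precursor_strip_margin
    mz, intensity = mz[keep], intensity[keep]

    if intensity.size:
        floor = config.intensity_floor_fraction * intensity.max()
        keep = intensity >= floor
        mz, intensity = mz[keep], intensity[keep]

    mz, intensity = bin_peaks(mz, intensity, config.bin_width)

    if config.normalize and intensity.size:
        intensity = intensity / intensity.max()

    return replace(spectrum, mz=mz, intensity=intensity)


def extract_features(
    run: RawRun,
    targets: Sequence[tuple[str, int, str, float]],
    tol: float = 0.003,
    config: PreprocessConfig | None = None,
) -> list[Feature]:
    """Admit MS2 scans whose precursor lies within ``tol`` Da of a target.

    ``targets`` are (compound_id, degree, adduct_label, expected_mz) tuples,
    e.g. from :func:`glycoscreen.chemcore.make_inclusion_list`. A scan that
    matches several targets yields one Feature per matching target.
    """
    config = config or PreprocessConfig()
    if not targets:
        return []
    target_arr = sorted(targets, key=lambda t: t[3])
    target_mz = np.array([t[3] for t in target_arr])

    features: list[Feature] = []
    n_dropped = 0
    for scan in run.ms2():
        lo = np.searchsorted(target_mz, scan.precursor_mz - tol, side="left")
        hi = np.searchsorted(target_mz, scan.precursor_mz + tol, side="right")
        if lo == hi:
            n_dropped += 1
            continue
        cleaned = clean_spectrum(scan, config)
        for cid, k, adduct, expected in target_arr[lo:hi]:
            features.append(
                Feature(
                    run_id=run.run_id,
                    scan_id=scan.scan_id,
                    precursor_mz=scan.precursor_mz,
                    retention_time=scan.retention_time,
                    spectrum=cleaned,
                    matched_target=(cid, k, adduct),
                    target_mz=expected,
                )
            )
    logger.info(
        "run %s: %d features from %d MS2 scans (%d outside precursor windows)",
        run.run_id,
        len(features),
        len(run.ms2()),
        n_dropped,
    )
    return features
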
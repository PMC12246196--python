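"""Greedy cosine scoring and glycoside product calling.

The similarity between an experimental MS2 spectrum and a simulated
glycoside reference is the greedy cosine: fragment peaks are paired across
the two spectra within an absolute m/z tolerance, highest intensity-product
pairs first, each peak used at most once, and the score is the matched dot
product normalised by the full vector norms — 1.0 for identical patterns,
0 when nothing pairs. Candidate references are restricted by precursor m/z
(ppm window over the reaction mix's expected product ions); a feature is
assigned to its best-scoring candidate if the score exceeds the storage
cutoff, and assignments at or above the decision threshold become product
calls. Products also seen in enzyme-free control runs of the same mix, or
on blacklisted background substrates, are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .glycolib import SimulatedLibraryEntry
from .specproc import Feature

__all__ = [
    "ScoringConfig",
    "MatchResult",
    "ProductCall",
    "cosine_greedy",
    "assign_candidate",
    "call_products",
    "exclude_controls",
    "ExclusionReport",
]


@dataclass
class ScoringConfig:
    """Greedy-cosine and candidate-assignment parameters.

    fragment_tolerance : Da
        Max |Δm/z| for two fragments to pair (0.15).
    mz_power, intensity_power :
        Peak weight = mz**mz_power * intensity**intensity_power (0, 1.0).
    top_k_peaks :
        Each side truncated to its strongest peaks before scoring (50).
    candidate_ppm :
        Precursor window for candidate references (50 ppm).
    storage_cutoff :
        Minimum score (strict >) to record an assignment (0.5).
    decision_threshold :
        Minimum score (inclusive >=) to call a product (0.85).
    """

    fragment_tolerance: float = 0.15
    mz_power: float = 0.0
    intensity_power: float = 1.0
    top_k_peaks: int = 50
    candidate_ppm: float = 50.0
    storage_cutoff: float = 0.5
    decision_threshold: float = 0.85

    def __post_init__(self) -> None:
        if not (0 <= self.storage_cutoff <= self.decision_threshold <= 1):
            raise ValueError(
                "need 0 <= storage_cutoff <= decision_threshold <= 1"
            )
        if self.fragment_tolerance <= 0:
            raise ValueError("fragment_tolerance must be > 0")
        if self.top_k_peaks < 1:
            raise ValueError("top_k_peaks must be >= 1")


@dataclass
class MatchResult:
    feature: Feature
    entry: SimulatedLibraryEntry
    cosine_score: float
    n_matched_peaks: int
    precursor_ppm_error: float


@dataclass
class ProductCall:
    """One putative enzymatic glycosylation product."""

    enzyme: str
    compound_id: str
    degree: int
    adduct: str
    cosine_score: float
    retention_time: float
    run_id: str
    scan_id: str
    mix: str = ""
    precursor_mz: float = 0.0  # observed
    expected_mz: float = 0.0  # library entry's expected product ion m/z
    n_matched_peaks: int = 0
    auc: float = 0.0


def _prepare(
    mz: np.ndarray, intensity: np.ndarray, config: ScoringConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Base-peak normalise, truncate to top_k (ties at the rank boundary go
    to lower m/z), and weight peaks."""
    if mz.size == 0:
        return mz, intensity
    intensity = intensity / intensity.max()
    if mz.size > config.top_k_peaks:
        order = np.lexsort((mz, -intensity))[: config.top_k_peaks]
        order = np.sort(order)
        mz, intensity = mz[order], intensity[order]
    weights = np.power(mz, config.mz_power) * np.power(
        intensity, config.intensity_power
    )
    return mz, weights


def cosine_greedy(
    query_mz: np.ndarray,
    query_intensity: np.ndarray,
    ref_mz: np.ndarray,
    ref_intensity: np.ndarray,
    config: ScoringConfig | None = None,
) -> tuple[float, int]:
    """Greedy cosine between two peak lists; returns (score, n_matched).

    Candidate pairs within the tolerance are accepted greedily in order of
    descending weight product, tie-broken by smaller |Δm/z| then smaller
    min(m/z); each peak is used at most once. The score is the accepted dot
    product over the product of full-vector norms, so it lies in [0, 1] and
    is symmetric in its arguments.
    """
    config = config or ScoringConfig()
    q_mz = np.asarray(query_mz, dtype=float)
    q_int = np.asarray(query_intensity, dtype=float)
    r_mz = np.asarray(ref_mz, dtype=float)
    r_int = np.asarray(ref_intensity, dtype=float)
    if q_mz.size == 0 or r_mz.size == 0:
        return 0.0, 0

    q_mz, q_w = _prepare(q_mz, q_int, config)
    r_mz, r_w = _prepare(r_mz, r_int, config)

    # candidate pairs within tolerance, via searchsorted on the sorted ref
    pairs: list[tuple[float, float, float, int, int]] = []
    lo = np.searchsorted(r_mz, q_mz - config.fragment_tolerance, side="left")
    hi = np.searchsorted(r_mz, q_mz + config.fragment_tolerance, side="right")
    for qi in range(q_mz.size):
        for ri in range(lo[qi], hi[qi]):
            pairs.append(
                (
                    -(q_w[qi] * r_w[ri]),
                    abs(q_mz[qi] - r_mz[ri]),
                    min(q_mz[qi], r_mz[ri]),
                    qi,
                    ri,
                )
            )
    if not pairs:
        return 0.0, 0
    pairs.sort()

    used_q = np.zeros(q_mz.size, dtype=bool)
    used_r = np.zeros(r_mz.size, dtype=bool)
    accepted = 0.0
    n_matched = 0
    for neg_prod, _, _, qi, ri in pairs:
        if used_q[qi] or used_r[ri]:
            continue
        used_q[qi] = used_r[ri] = True
        accepted += -neg_prod
        n_matched += 1
    norm = np.sqrt(np.sum(q_w**2)) * np.sqrt(np.sum(r_w**2))
    if norm == 0:
        return 0.0, 0
    return float(min(accepted / norm, 1.0)), n_matched


def assign_candidate(
    feature: Feature,
    library: Sequence[SimulatedLibraryEntry],
    config: ScoringConfig | None = None,
) -> MatchResult | None:
    """Best-scoring candidate reference for one feature, or None.

    Candidates are entries whose expected precursor m/z is within
    ``candidate_ppm`` of the observed precursor. All reference spectra of a
    candidate are scored and its best kept; the winning candidate must
    strictly exceed the storage cutoff. Ties break on smaller precursor ppm
    error, then lexicographic entry id.
    """
    config = config or ScoringConfig()
    best: MatchResult | None = None
    for entry in library:
        expected = entry.expected_precursor_mz
        ppm_err = abs(feature.precursor_mz - expected) / expected * 1e6
        if ppm_err > config.candidate_ppm:
            continue
        score, n_matched = cosine_greedy(
            feature.spectrum.mz,
            feature.spectrum.intensity,
            entry.reference_mz,
            entry.reference_intensity,
            config,
        )
        candidate = MatchResult(feature, entry, score, n_matched, ppm_err)
        if best is None or _better(candidate, best):
            best = candidate
    if best is not None and best.cosine_score > config.storage_cutoff:
        return best
    return None


def _better(a: MatchResult, b: MatchResult) -> bool:
    return (
        -a.cosine_score,
        a.precursor_ppm_error,
        a.entry.entry_id,
    ) < (-b.cosine_score, b.precursor_ppm_error, b.entry.entry_id)


def call_products(
    matches: Iterable[MatchResult],
    threshold: float = 0.85,
    enzyme: str = "",
    mix: str = "",
) -> list[ProductCall]:
    """Matches at or above the decision threshold become product calls."""
    calls = []
    for m in matches:
        if m.cosine_score >= threshold:
            calls.append(
                ProductCall(
                    enzyme=enzyme,
                    compound_id=m.entry.compound_id,
                    degree=m.entry.degree,
                    adduct=m.entry.adduct.label,
                    cosine_score=m.cosine_score,
                    retention_time=m.feature.retention_time,
                    run_id=m.feature.run_id,
                    scan_id=m.feature.scan_id,
                    mix=mix,
                    precursor_mz=m.feature.precursor_mz,
                    expected_mz=m.entry.expected_precursor_mz,
                    n_matched_peaks=m.n_matched_peaks,
                )
            )
    return calls


@dataclass
class ExclusionReport:
    n_removed_control: int = 0
    n_removed_blacklist: int = 0


def exclude_controls(
    calls: Sequence[ProductCall],
    control_calls: Sequence[ProductCall],
    substrate_blacklist: Iterable[str] = (),
) -> tuple[list[ProductCall], ExclusionReport]:
    """Drop calls that the pipeline also produced in enzyme-free controls.

    A call is removed if its (compound_id, degree) was called in a control
    run of the same mix, or if its compound is blacklisted outright.
    """
    control_keys = {(c.mix, c.compound_id, c.degree) for c in control_calls}
    blacklist = set(substrate_blacklist)
    report = ExclusionReport()
    kept: list[ProductCall] = []
    for call in calls:
        if call.compound_id in blacklist:
            report.n_removed_blacklist += 1
        elif (call.mix, call.compound_id, call.degree) in control_keys:
            report.n_removed_control += 1
        else:
            kept.append(call)
    return kept, report
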
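"""End-to-end screen orchestration: runs in, product table out.

Control runs (enzyme-free lysate) are processed first with the identical
feature-extraction/scoring path; every (mix, compound, degree) they yield is
then excluded from the sample-run calls, along with any blacklisted
substrates. Each call is quantified by XIC integration anchored at its
triggering MS2 scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chemcore import (
    CompoundRecord,
    DEFAULT_SHIFT,
    FEATURE_ADDUCTS,
    GlycoShift,
    Pool,
    make_inclusion_list,
)
from .glycolib import SimulatedLibraryEntry
from .msio import RawRun
from .quant import XicConfig, integrate_xic
from .scoring import (
    MatchResult,
    ProductCall,
    ScoringConfig,
    assign_candidate,
    call_products,
    exclude_controls,
)
from .specproc import PreprocessConfig, extract_features

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "screen_run", "screen", "products_to_frame"]


@dataclass
class RunReport:
    """Counts at every filter stage of one run, for the machine-readable log."""

    run_id: str
    n_ms2: int = 0
    n_features: int = 0
    n_candidates_scored: int = 0
    n_stored_matches: int = 0
    n_calls: int = 0


def screen_run(
    run: RawRun,
    pool: Pool,
    compounds: Mapping[str, CompoundRecord],
    library: Sequence[SimulatedLibraryEntry],
    enzyme: str,
    preprocess: PreprocessConfig | None = None,
    scoring: ScoringConfig | None = None,
    xic: XicConfig | None = None,
    precursor_tol: float = 0.003,
    shift: GlycoShift = DEFAULT_SHIFT,
    quantify: bool = True,
) -> tuple[list[ProductCall], list[MatchResult], RunReport]:
    """Process one chromatogram against its reaction mix.

    Returns decision-threshold calls, all stored matches (> storage cutoff),
    and the per-stage report. The candidate library is restricted to the
    pool's compounds; cross-mix matching is disabled.
    """
    preprocess = preprocess or PreprocessConfig()
    scoring = scoring or ScoringConfig()
    xic = xic or XicConfig()

    targets = make_inclusion_list(
        pool, compounds, degrees=(1, 2), adducts=FEATURE_ADDUCTS, shift=shift
    )
    features = extract_features(run, targets, tol=precursor_tol, config=preprocess)

    member_set = set(pool.members)
    pool_library = [e for e in library if e.compound_id in member_set]

    report = RunReport(run_id=run.run_id, n_ms2=len(run.ms2()), n_features=len(features))
    matches: list[MatchResult] = []
    seen: set[tuple[str, str]] = set()  # (scan_id, entry_id): dedupe multi-target scans
    for feature in features:
        report.n_candidates_scored += 1
        match = assign_candidate(feature, pool_library, scoring)
        if match is None:
            continue
        key = (feature.scan_id, match.entry.entry_id)
        if key in seen:
            continue
        seen.add(key)
        matches.append(match)
    report.n_stored_matches = len(matches)

    calls = call_products(
        matches, threshold=scoring.decision_threshold, enzyme=enzyme,
        mix=pool.pool_id,
    )
    report.n_calls = len(calls)

    if quantify:
        for call in calls:
            # integrate at the entry's expected ion m/z: exact by construction,
            # unlike the jittered observed precursor
            call.auc = integrate_xic(
                run, call.expected_mz, call.retention_time, xic
            ).auc
    logger.info(
        "run %s: ms2=%d features=%d stored=%d calls=%d",
        run.run_id, report.n_ms2, report.n_features, report.n_stored_matches,
        report.n_calls,
    )
    return calls, matches, report


def screen(
    runs: Iterable[RawRun],
    manifest: pd.DataFrame,
    pools: Sequence[Pool],
    compounds: Mapping[str, CompoundRecord],
    library: Sequence[SimulatedLibraryEntry],
    blacklist: Iterable[str] = (),
    **kwargs,
) -> tuple[list[ProductCall], list[RunReport], pd.DataFrame]:
    """Screen many runs. ``manifest`` columns: run_id, enzyme, mix, is_control.

    Control runs are screened first; their calls define the per-mix exclusion
    set applied to all sample-run calls.
    """
    pool_by_id = {p.pool_id: p for p in pools}
    meta = manifest.set_index("run_id")
    run_list = list(runs)
    by_id = {r.run_id: r for r in run_list}

    def rows(control: bool):
        for run_id, row in meta.iterrows():
            if bool(row["is_control"]) == control:
                if run_id not in by_id:
                    raise KeyError(f"manifest run {run_id!r} not among loaded runs")
                yield by_id[run_id], row

    control_calls: list[ProductCall] = []
    reports: list[RunReport] = []
    for run, row in rows(control=True):
        calls, _, report = screen_run(
            run, pool_by_id[row["mix"]], compounds, library,
            enzyme=str(row["enzyme"]), **kwargs,
        )
        control_calls.extend(calls)
        reports.append(report)

    sample_calls: list[ProductCall] = []
    match_rows: list[dict] = []
    for run, row in rows(control=False):
        calls, matches, report = screen_run(
            run, pool_by_id[row["mix"]], compounds, library,
            enzyme=str(row["enzyme"]), **kwargs,
        )
        sample_calls.extend(calls)
        reports.append(report)
        match_rows.extend(
            {
                "run_id": run.run_id,
                "enzyme": str(row["enzyme"]),
                "mix": str(row["mix"]),
                "scan_id": m.feature.scan_id,
                "compound_id": m.entry.compound_id,
                "degree": m.entry.degree,
                "adduct": m.entry.adduct.label,
                "cosine": round(m.cosine_score, 6),
            }
            for m in matches
        )

    kept, excl = exclude_controls(sample_calls, control_calls, blacklist)
    logger.info(
        "excluded %d control-matched and %d blacklisted calls",
        excl.n_removed_control, excl.n_removed_blacklist,
    )
    matches_df = pd.DataFrame(
        match_rows,
        columns=[
            "run_id", "enzyme", "mix", "scan_id", "compound_id", "degree",
            "adduct", "cosine",
        ],
    )
    return kept, reports, matches_df


def products_to_frame(calls: Sequence[ProductCall]) -> pd.DataFrame:
    """Product table sorted by (enzyme, compound_id, degree)."""
    df = pd.DataFrame(
        [
            {
                "run_id": c.run_id,
                "enzyme": c.enzyme,
                "mix": c.mix,
                "compound_id": c.compound_id,
                "degree": c.degree,
                "adduct": c.adduct,
                "precursor_mz": round(c.precursor_mz, 4),
                "rt_min": round(c.retention_time, 4),
                "cosine": round(c.cosine_score, 6),
                "n_matched": c.n_matched_peaks,
                "auc": c.auc,
                "scan_id": c.scan_id,
            }
            for c in calls
        ],
        columns=[
            "run_id", "enzyme", "mix", "compound_id", "degree", "adduct",
            "precursor_mz", "rt_min", "cosine", "n_matched", "auc", "scan_id",
        ],
    )
    return df.sort_values(["enzyme", "compound_id", "degree"]).reset_index(drop=True)
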
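"""Simulated glycoside MS/MS reference library construction.

The central trick of the screen: a glycoside's MS2 spectrum under collision
energies that cleave the glycosidic bond is dominated by aglycone fragments,
so a glycoside reference library can be *simulated* from aglycone reference
spectra by shifting only the expected precursor m/z (+162.0533 Da per hexose
unit, over the identification adduct set) while copying the fragment peaks
unchanged. Aglycone references are cleaned with the same preprocessing as
experimental spectra so both sides of every cosine comparison are treated
symmetrically.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chemcore import (
    Adduct,
    CompoundRecord,
    DEFAULT_SHIFT,
    GlycoShift,
    IDENTIFICATION_ADDUCTS,
    expected_precursor_mz,
    glycoside_neutral_mass,
)
from .msio import PeakSpectrum, ReferenceRecord, read_msp, write_msp
from .specproc import PreprocessConfig, clean_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedLibraryEntry",
    "CoverageReport",
    "curate_aglycone_library",
    "simulate_library",
    "write_library",
    "read_library",
]


@dataclass
class SimulatedLibraryEntry:
    """One (aglycone spectrum, glycosylation degree, adduct) reference."""

    entry_id: str
    compound_id: str
    source_record_id: str
    degree: int
    adduct: Adduct
    expected_precursor_mz: float
    reference_mz: np.ndarray
    reference_intensity: np.ndarray


@dataclass
class CoverageReport:
    """Which substrates have reference spectra, and which records went unused."""

    covered: list[str] = field(default_factory=list)
    uncovered: list[str] = field(default_factory=list)
    unmatched_records: list[str] = field(default_factory=list)

    @property
    def n_covered(self) -> int:
        return len(self.covered)


_PAREN_PREFIX = re.compile(r"^\([^)]*\)\s*-?\s*")


def _norm_name(name: str) -> str:
    return " ".join(name.lower().split())


def _strip_stereo(name: str) -> str:
    return _PAREN_PREFIX.sub("", name)


def curate_aglycone_library(
    records: Sequence[ReferenceRecord],
    substrates: Sequence[CompoundRecord],
    cross_map: Mapping[str, str] | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[dict[str, list[ReferenceRecord]], CoverageReport]:
    """Match reference spectra to substrates and clean the matched spectra.

    Matching is by case/whitespace-insensitive name; if that fails, by the
    name with a leading parenthesised stereo-prefix removed. An explicit
    ``cross_map`` of record_id -> compound_id overrides heuristics. Each
    matched record's peaks are cleaned with the standard preprocessing,
    using the record's own precursor m/z; records without a precursor are
    kept unstripped (floor/bin/normalise still apply).
    """
    config = config or PreprocessConfig()
    by_name: dict[str, str] = {}
    by_stripped: dict[str, str] = {}
    for comp in substrates:
        by_name[_norm_name(comp.name)] = comp.compound_id
        by_stripped[_norm_name(_strip_stereo(comp.name))] = comp.compound_id

    out: dict[str, list[ReferenceRecord]] = {}
    report = CoverageReport()
    for rec in records:
        cid = None
        if cross_map and rec.record_id in cross_map:
            cid = cross_map[rec.record_id]
        else:
            key = _norm_name(rec.name)
            cid = by_name.get(key) or by_stripped.get(
                _norm_name(_strip_stereo(rec.name))
            )
        if cid is None:
            report.unmatched_records.append(rec.record_id or rec.name)
            logger.info("reference record %r matched no substrate", rec.name)
            continue
        cleaned = _clean_record(rec, config)
        if cleaned is None:
            report.unmatched_records.append(rec.record_id or rec.name)
            continue
        out.setdefault(cid, []).append(cleaned)

    for comp in substrates:
        (report.covered if comp.compound_id in out else report.uncovered).append(
            comp.compound_id
        )
    return out, report


def _clean_record(
    rec: ReferenceRecord, config: PreprocessConfig
) -> ReferenceRecord | None:
    if rec.precursor_mz is not None:
        spec = PeakSpectrum(
            mz=rec.mz,
            intensity=rec.intensity,
            level=2,
            precursor_mz=rec.precursor_mz,
            scan_id=rec.record_id,
        )
        cleaned = clean_spectrum(spec, config)
        mz, intensity = cleaned.mz, cleaned.intensity
    else:
        from .specproc import bin_peaks

        intensity = rec.intensity
        floor = config.intensity_floor_fraction * intensity.max()
        keep = intensity >= floor
        mz, intensity = bin_peaks(rec.mz[keep], intensity[keep], config.bin_width)
        if config.normalize and intensity.size:
            intensity = intensity / intensity.max()
    if mz.size == 0:
        logger.warning("record %r empty after cleaning; dropped", rec.name)
        return None
    return ReferenceRecord(
        name=rec.name,
        mz=mz,
        intensity=intensity,
        record_id=rec.record_id,
        precursor_mz=rec.precursor_mz,
        adduct=rec.adduct,
        metadata=dict(rec.metadata),
    )


def simulate_library(
    aglycone_map: Mapping[str, Sequence[ReferenceRecord]],
    substrates: Sequence[CompoundRecord],
    degrees: Iterable[int] = (1, 2),
    adducts: Sequence[Adduct] = IDENTIFICATION_ADDUCTS,
    shift: GlycoShift = DEFAULT_SHIFT,
) -> list[SimulatedLibraryEntry]:
    """Enumerate glycoside references: every (spectrum, degree, adduct) combo.

    Fragment peaks are copied unchanged from the cleaned aglycone reference;
    only the expected precursor m/z is shifted. Entry count is
    sum over compounds of n_spectra * n_degrees * n_adducts.
    """
    by_id = {c.compound_id: c for c in substrates}
    entries: list[SimulatedLibraryEntry] = []
    for cid, recs in aglycone_map.items():
        comp = by_id.get(cid)
        if comp is None or comp.neutral_mass is None:
            logger.warning("compound %r lacks a neutral mass; skipped", cid)
            continue
        for ri, rec in enumerate(recs):
            for k in degrees:
                product_mass = glycoside_neutral_mass(comp.neutral_mass, k, shift)
                for adduct in adducts:
                    entries.append(
                        SimulatedLibraryEntry(
                            entry_id=f"{cid}|{rec.record_id or ri}|k{k}|{adduct.label}",
                            compound_id=cid,
                            source_record_id=rec.record_id or str(ri),
                            degree=k,
                            adduct=adduct,
                            expected_precursor_mz=expected_precursor_mz(
                                product_mass, adduct
                            ),
                            reference_mz=rec.mz,
                            reference_intensity=rec.intensity,
                        )
                    )
    return entries


def write_library(entries: Sequence[SimulatedLibraryEntry], path: str | Path) -> None:
    """Persist as MSP with Comment fields carrying identity for exact reload."""
    records = [
        ReferenceRecord(
            name=e.entry_id,
            mz=e.reference_mz,
            intensity=e.reference_intensity,
            record_id=e.source_record_id,
            precursor_mz=e.expected_precursor_mz,
            adduct=e.adduct.label,
            metadata={
                "comment": (
                    f"compound_id={e.compound_id}; degree={e.degree}; "
                    f"adduct={e.adduct.label}; charge={e.adduct.charge}; "
                    f"adduct_delta={e.adduct.mass_delta:.5f}"
                )
            },
        )
        for e in entries
    ]
    write_msp(records, path)


def read_library(path: str | Path) -> list[SimulatedLibraryEntry]:
    entries = []
    for rec in read_msp(path):
        fields = dict(
            part.strip().split("=", 1)
            for part in rec.metadata.get("comment", "").split(";")
            if "=" in part
        )
        entries.append(
            SimulatedLibraryEntry(
                entry_id=rec.name,
                compound_id=fields["compound_id"],
                source_record_id=rec.record_id,
                degree=int(fields["degree"]),
                adduct=Adduct(
                    fields["adduct"],
                    int(fields.get("charge", 1)),
                    float(fields.get("adduct_delta", 1.00728)),
                ),
                expected_precursor_mz=rec.precursor_mz,
                reference_mz=rec.mz,
                reference_intensity=rec.intensity,
            )
        )
    return entries
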
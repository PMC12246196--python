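"""Readers and writers for the MS and table formats the pipeline touches.

mzML and MGF parsing delegate to pyteomics; the NIST-style MSP dialect used
for reference libraries and a JSON-lines fixture format (one scan per line,
lossless) are implemented here. Retention times are minutes everywhere after
ingestion, m/z is kept at full double precision in memory, and all peak
lists are sorted ascending by m/z.
"""

from __future__ import annotations

import base64
import json
import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakSpectrum",
    "RawRun",
    "ReferenceRecord",
    "read_mzml",
    "write_mzml",
    "read_msp",
    "write_msp",
    "read_mgf",
    "write_mgf",
    "read_jsonl",
    "write_jsonl",
    "read_table",
    "write_table",
    "SUBSTRATE_COLUMNS",
    "MANIFEST_COLUMNS",
]


class Peak(NamedTuple):
    mz: float
    intensity: float


def _as_sorted_arrays(
    mz: Sequence[float], intensity: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have equal length")
    if mz.size and np.any(mz <= 0):
        raise ValueError("all m/z values must be > 0")
    if intensity.size and np.any(intensity < 0):
        raise ValueError("intensities must be >= 0")
    order = np.argsort(mz, kind="stable")
    return mz[order], intensity[order]


@dataclass
class PeakSpectrum:
    """One scan: a centroided peak list plus acquisition metadata.

    ``level`` 1 scans carry no precursor; level 2 scans must. Retention time
    is in minutes.
    """

    mz: np.ndarray
    intensity: np.ndarray
    level: int = 2
    precursor_mz: float | None = None
    charge: int | None = None
    retention_time: float = 0.0
    scan_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.mz, self.intensity = _as_sorted_arrays(self.mz, self.intensity)
        if self.level == 2 and self.precursor_mz is None:
            raise ValueError(f"MS2 scan {self.scan_id!r} lacks precursor_mz")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class RawRun:
    """A chromatogram: time-ordered scans plus run-level metadata."""

    run_id: str
    scans: list[PeakSpectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.retention_time)

    def ms1(self) -> list[PeakSpectrum]:
        return [s for s in self.scans if s.level == 1]

    def ms2(self) -> list[PeakSpectrum]:
        return [s for s in self.scans if s.level == 2]


@dataclass
class ReferenceRecord:
    """One library spectrum (e.g. a MoNA aglycone reference)."""

    name: str
    mz: np.ndarray
    intensity: np.ndarray
    record_id: str = ""
    precursor_mz: float | None = None
    adduct: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz, self.intensity = _as_sorted_arrays(self.mz, self.intensity)
        if self.mz.size == 0:
            raise ValueError(f"reference record {self.name!r} has no peaks")


# ---------------------------------------------------------------------------
# mzML


_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv(elem, accession: str):
    """First cvParam with the given accession under ``elem`` (direct children)."""
    for cv in elem.iterfind(f"{_NS}cvParam"):
        if cv.get("accession") == accession:
            return cv
    return None


def _decode_array(array_elem, idx: int) -> np.ndarray:
    import zlib

    dtype = None
    compressed = False
    for cv in array_elem.iterfind(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000574":
            compressed = True
    binary = array_elem.find(f"{_NS}binary")
    if binary is None or dtype is None:
        raise ValueError(f"malformed binaryDataArray at spectrum index {idx}")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> RawRun:
    """Read a centroid-mode mzML file into a :class:`RawRun`.

    Handles 32/64-bit float arrays with or without zlib compression.
    Profile-mode spectra trigger a warning and are passed through unchanged
    (the pipeline treats every peak as a centroid).
    """
    path = Path(path)
    scans: list[PeakSpectrum] = []
    try:
        context = etree.iterparse(str(path), events=("end",), tag=f"{_NS}spectrum")
        for idx, (_, spec) in enumerate(context):
            if _cv(spec, "MS:1000128") is not None:
                warnings.warn(
                    f"profile-mode spectrum {spec.get('id', idx)!r} in {path.name}; "
                    "treating peaks as centroids"
                )
            level_cv = _cv(spec, "MS:1000511")
            level = int(level_cv.get("value")) if level_cv is not None else 1

            rt = 0.0
            scan_elem = spec.find(f"{_NS}scanList/{_NS}scan")
            if scan_elem is not None:
                rt_cv = _cv(scan_elem, "MS:1000016")
                if rt_cv is not None:
                    rt = float(rt_cv.get("value"))
                    if rt_cv.get("unitName") in ("second", "s"):
                        rt /= 60.0

            precursor = None
            charge = None
            if level >= 2:
                ion = spec.find(
                    f"{_NS}precursorList/{_NS}precursor/"
                    f"{_NS}selectedIonList/{_NS}selectedIon"
                )
                if ion is None:
                    raise ValueError(
                        f"malformed precursor block at scan index {idx} in {path}"
                    )
                precursor = float(_cv(ion, "MS:1000744").get("value"))
                charge_cv = _cv(ion, "MS:1000041")
                if charge_cv is not None:
                    charge = int(charge_cv.get("value"))

            mz_arr = intensity_arr = None
            for array_elem in spec.iterfind(
                f"{_NS}binaryDataArrayList/{_NS}binaryDataArray"
            ):
                data = _decode_array(array_elem, idx)
                if _cv(array_elem, "MS:1000514") is not None:
                    mz_arr = data
                elif _cv(array_elem, "MS:1000515") is not None:
                    intensity_arr = data
            if mz_arr is None or intensity_arr is None:
                raise ValueError(f"spectrum index {idx} in {path} lacks peak arrays")

            scans.append(
                PeakSpectrum(
                    mz=mz_arr,
                    intensity=intensity_arr,
                    level=level,
                    precursor_mz=precursor,
                    charge=charge,
                    retention_time=rt,
                    scan_id=str(spec.get("id", f"scan={idx}")),
                    run_id=path.stem,
                )
            )
            spec.clear()
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed mzML in {path} near scan index {len(scans)}: {exc}"
        ) from exc
    return RawRun(run_id=path.stem, scans=scans)


def _b64_doubles(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{values.size}d", *map(float, values))
    ).decode("ascii")


def write_mzml(run: RawRun, path: str | Path) -> None:
    """Write a minimal plain mzML file (64-bit float arrays, no compression)."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <cvList count="1">',
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "  </cvList>",
        f'  <run id="{escape(run.run_id)}">',
        f'    <spectrumList count="{len(run.scans)}">',
    ]
    for i, scan in enumerate(run.scans):
        sid = escape(scan.scan_id or f"scan={i + 1}")
        mz_b64 = _b64_doubles(scan.mz)
        int_b64 = _b64_doubles(scan.intensity)
        lines += [
            f'      <spectrum index="{i}" id="{sid}" defaultArrayLength="{len(scan)}">',
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan.level}"/>',
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
            '        <scanList count="1">',
            "          <scan>",
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.retention_time:.6f}" unitAccession="UO:0000031" unitName="minute"/>',
            "          </scan>",
            "        </scanList>",
        ]
        if scan.level >= 2:
            charge = (
                f'                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{scan.charge}"/>'
                if scan.charge
                else ""
            )
            lines += [
                '        <precursorList count="1">',
                "          <precursor>",
                '            <selectedIonList count="1">',
                "              <selectedIon>",
                f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan.precursor_mz:.6f}"/>',
                *( [charge] if charge else [] ),
                "              </selectedIon>",
                "            </selectedIonList>",
                "          </precursor>",
                "        </precursorList>",
            ]
        for accession, name, b64 in (
            ("MS:1000514", "m/z array", mz_b64),
            ("MS:1000515", "intensity array", int_b64),
        ):
            lines += [
                '        <binaryDataArrayList count="2">'
                if accession == "MS:1000514"
                else "",
                f'          <binaryDataArray encodedLength="{len(b64)}">',
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
                f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>',
                f"            <binary>{b64}</binary>",
                "          </binaryDataArray>",
            ]
        lines += [
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(l for l in lines if l != ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# MSP (NIST text dialect)


def _parse_msp_block(block_lines: list[str], origin: str) -> ReferenceRecord:
    meta: dict = {}
    peaks: list[tuple[float, float]] = []
    n_declared = None
    for line in block_lines:
        if ":" in line and not line[0].isdigit():
            key, _, value = line.partition(":")
            key = key.strip().lower()
            value = value.strip()
            if key == "num peaks":
                n_declared = int(value)
            else:
                meta[key] = value
        else:
            parts = line.replace(";", " ").split()
            if len(parts) >= 2:
                peaks.append((float(parts[0]), float(parts[1])))
    if n_declared is None:
        raise ValueError(f"record {origin}: missing 'Num Peaks'")
    if n_declared != len(peaks):
        raise ValueError(
            f"record {origin}: Num Peaks={n_declared} but {len(peaks)} peak lines"
        )
    if not peaks:
        raise ValueError(f"record {origin}: zero peaks")
    precursor = None
    for key in ("precursormz", "precursor_mz", "precursor m/z"):
        if key in meta:
            precursor = float(meta.pop(key))
            break
    name = meta.pop("name", origin)
    return ReferenceRecord(
        name=name,
        mz=[p[0] for p in peaks],
        intensity=[p[1] for p in peaks],
        record_id=meta.pop("db#", meta.pop("id", origin)),
        precursor_mz=precursor,
        adduct=meta.pop("precursor_type", meta.pop("adduct", None)),
        metadata=meta,
    )


def read_msp(path: str | Path) -> list[ReferenceRecord]:
    """Parse an MSP library. Malformed records are skipped with a log entry."""
    text = Path(path).read_text(encoding="utf-8")
    records: list[ReferenceRecord] = []
    block: list[str] = []
    blocks: list[list[str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            if block:
                blocks.append(block)
                block = []
        else:
            block.append(line)
    if block:
        blocks.append(block)
    for i, blk in enumerate(blocks):
        try:
            records.append(_parse_msp_block(blk, origin=f"{Path(path).name}#{i}"))
        except (ValueError, IndexError) as exc:
            logger.warning("skipping MSP record %d in %s: %s", i, path, exc)
    return records


def write_msp(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    lines: list[str] = []
    for rec in records:
        lines.append(f"Name: {rec.name}")
        if rec.record_id:
            lines.append(f"DB#: {rec.record_id}")
        if rec.precursor_mz is not None:
            lines.append(f"PrecursorMZ: {rec.precursor_mz:.6f}")
        if rec.adduct:
            lines.append(f"Precursor_type: {rec.adduct}")
        for key, value in rec.metadata.items():
            lines.append(f"{key.capitalize()}: {value}")
        lines.append(f"Num Peaks: {len(rec.mz)}")
        for m, i in zip(rec.mz, rec.intensity):
            lines.append(f"{m:.6f} {i:.6g}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path) -> list[PeakSpectrum]:
    """Read MS2-only MGF blocks. PEPMASS is required on every block."""
    spectra: list[PeakSpectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for idx, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"MGF block {idx} in {path} lacks PEPMASS")
            rt_s = params.get("rtinseconds")
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            spectra.append(
                PeakSpectrum(
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    level=2,
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    retention_time=float(rt_s) / 60.0 if rt_s is not None else 0.0,
                    scan_id=str(params.get("title", f"index={idx}")),
                    run_id=Path(path).stem,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[PeakSpectrum], path: str | Path) -> None:
    entries = []
    for spec in spectra:
        params: dict = {
            "title": spec.scan_id,
            "pepmass": spec.precursor_mz,
            "rtinseconds": spec.retention_time * 60.0,
        }
        if spec.charge:
            params["charge"] = spec.charge
        entries.append(
            {
                "m/z array": spec.mz,
                "intensity array": spec.intensity,
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# JSON-lines fixture format (lossless, no MS tooling required)


def write_jsonl(run: RawRun, path: str | Path) -> None:
    """One header line then one scan per line; lossless double precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            json.dumps({"run_id": run.run_id, "metadata": run.metadata}) + "\n"
        )
        for scan in run.scans:
            fh.write(
                json.dumps(
                    {
                        "scan_id": scan.scan_id,
                        "level": scan.level,
                        "retention_time": scan.retention_time,
                        "precursor_mz": scan.precursor_mz,
                        "charge": scan.charge,
                        "mz": scan.mz.tolist(),
                        "intensity": scan.intensity.tolist(),
                    }
                )
                + "\n"
            )


def read_jsonl(path: str | Path) -> RawRun:
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        scans = []
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            scans.append(
                PeakSpectrum(
                    mz=d["mz"],
                    intensity=d["intensity"],
                    level=d["level"],
                    precursor_mz=d["precursor_mz"],
                    charge=d.get("charge"),
                    retention_time=d["retention_time"],
                    scan_id=d["scan_id"],
                    run_id=header["run_id"],
                )
            )
    return RawRun(run_id=header["run_id"], scans=scans, metadata=header["metadata"])


def read_run(path: str | Path) -> RawRun:
    """Dispatch on extension: .mzML or .jsonl."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    if path.suffix.lower() in (".jsonl", ".json"):
        return read_jsonl(path)
    raise ValueError(f"unrecognised run format: {path.suffix}")


# ---------------------------------------------------------------------------
# Tables

SUBSTRATE_COLUMNS = ["compound_id", "name", "neutral_mass"]
MANIFEST_COLUMNS = ["run_id", "enzyme", "mix", "is_control"]


def read_table(
    path: str | Path, required: Sequence[str] = (), known: Sequence[str] = ()
) -> pd.DataFrame:
    """Read a TSV/CSV manifest or substrate/product table with header checks."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    if known:
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            warnings.warn(f"{path.name}: ignoring unknown columns {unknown}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
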
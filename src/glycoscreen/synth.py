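"""Ground-truthed synthetic screens for end-to-end pipeline validation.

Generates what the wet assay would deliver: a substrate table with
well-separated monoisotopic masses, an aglycone MS/MS reference library,
and per-pool LC-MS/MS runs in which chosen glycosylation products are
spiked as Gaussian MS1 elution peaks at the expected adduct m/z plus one
near-apex MS2 scan whose fragments mirror the aglycone spectrum under
small m/z and intensity jitter, together with low-level noise peaks and
decoy MS2 scans (valid glycoside precursor, fragments borrowed from a
different compound). Every spike is recorded with its analytic Gaussian
peak area, so recall, false-call rate, control subtraction and peak-area
recovery can be measured exactly.

Defaults emulate the screening conditions: 40-compound pools, fragment m/z
jitter (5 mDa) sitting between the 20 mDa preprocessing bin width and the
0.15 Da match tolerance, 10% multiplicative intensity noise, noise peaks
capped at 5% of the base fragment, and 7 MS1 scans across an elution peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemcore import (
    Adduct,
    CompoundRecord,
    DEFAULT_SHIFT,
    FEATURE_ADDUCTS,
    GlycoShift,
    Pool,
    expected_precursor_mz,
    glycoside_neutral_mass,
)
from .msio import PeakSpectrum, RawRun, ReferenceRecord

__all__ = [
    "SynthConfig",
    "SpikeSpec",
    "GroundTruth",
    "make_aglycone_library",
    "make_screen_run",
    "make_control_run",
    "choose_spikes",
]

_ADDUCT_BY_LABEL = {a.label: a for a in FEATURE_ADDUCTS}


@dataclass
class SynthConfig:
    """Study-condition knobs for the generator; ``seed`` fixes everything."""

    seed: int = 0
    n_compounds: int = 40
    mass_range: tuple[float, float] = (150.0, 800.0)
    fragments_per_compound: tuple[int, int] = (5, 20)
    true_product_fraction: float = 0.3
    mz_jitter_sd: float = 0.005
    intensity_jitter_cv: float = 0.10
    n_noise_peaks: int = 10
    decoy_fraction: float = 0.25
    scans_per_peak: int = 7
    rt_sigma: float = 0.08  # chromatographic peak sigma, minutes
    rt_spacing: float = 0.4  # apex-to-apex spacing between spikes, minutes
    precursor_jitter_sd: float = 0.0005  # Da, recorded MS2 precursor
    ms1_mz_jitter_sd: float = 0.001  # Da, MS1 centroid position

    def __post_init__(self) -> None:
        if self.mz_jitter_sd < 0 or self.intensity_jitter_cv < 0:
            raise ValueError("jitter parameters must be >= 0")
        if self.scans_per_peak < 2:
            raise ValueError("scans_per_peak must be >= 2")


@dataclass(frozen=True)
class SpikeSpec:
    """One product to plant in a run: which glycoside, where, how tall."""

    compound_id: str
    degree: int
    adduct_label: str = "[M+H]+"
    height: float = 1e6  # apex MS1 intensity, arbitrary units


@dataclass
class GroundTruth:
    """What was actually planted: spikes with analytic areas, plus decoys."""

    spikes: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)


def make_aglycone_library(
    config: SynthConfig,
) -> tuple[list[CompoundRecord], list[ReferenceRecord]]:
    """Random substrate table + one [M+H]+ reference spectrum per compound.

    Masses are pairwise separated by >= 0.02 Da; fragments are uniform below
    the precursor minus 2 Da with >= 0.5 Da spacing and log-uniform
    intensities in [0.02, 1], so they survive the 1% intensity floor.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mass_range
    masses = np.sort(rng.uniform(lo, hi, size=config.n_compounds))
    for i in range(1, masses.size):
        masses[i] = max(masses[i], masses[i - 1] + 0.02)
    if masses[-1] > hi + 1.0:
        raise ValueError("mass_range too narrow for n_compounds at 0.02 Da spacing")

    compounds: list[CompoundRecord] = []
    records: list[ReferenceRecord] = []
    f_lo, f_hi = config.fragments_per_compound
    for i, mass in enumerate(masses):
        cid = f"S{i + 1:03d}"
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                name=f"synthcompound {i + 1}",
                neutral_mass=float(mass),
                superclass=f"class{(i % 4) + 1}",
            )
        )
        n_frag = int(rng.integers(f_lo, f_hi + 1))
        frag_mz = np.sort(rng.uniform(50.0, mass - 2.0, size=n_frag))
        for j in range(1, frag_mz.size):
            frag_mz[j] = max(frag_mz[j], frag_mz[j - 1] + 0.5)
        frag_int = np.exp(rng.uniform(math.log(0.02), 0.0, size=n_frag))
        records.append(
            ReferenceRecord(
                name=f"synthcompound {i + 1}",
                mz=frag_mz,
                intensity=frag_int,
                record_id=f"REF{i + 1:03d}",
                precursor_mz=float(mass) + 1.00728,
                adduct="[M+H]+",
            )
        )
    return compounds, records


def choose_spikes(
    pool: Pool,
    rng: np.random.Generator,
    fraction: float,
    degrees: Sequence[int] = (1, 2),
    adduct_labels: Sequence[str] = ("[M+H]+", "[M+Na]+"),
) -> list[SpikeSpec]:
    """Sample a fraction of the pool's (compound, degree, adduct) slots."""
    slots = [
        (cid, k, a) for cid in pool.members for k in degrees for a in adduct_labels
    ]
    n = max(1, round(fraction * len(slots)))
    picks = rng.choice(len(slots), size=n, replace=False)
    return [
        SpikeSpec(*slots[i], height=float(rng.uniform(5e5, 5e6)))
        for i in sorted(picks)
    ]


def _expected_mz(
    comp: CompoundRecord, degree: int, adduct: Adduct, shift: GlycoShift
) -> float:
    return expected_precursor_mz(
        glycoside_neutral_mass(comp.neutral_mass, degree, shift), adduct
    )


def _jittered_fragments(
    ref: ReferenceRecord, rng: np.random.Generator, config: SynthConfig, base: float
) -> tuple[np.ndarray, np.ndarray]:
    mz = ref.mz + rng.normal(0.0, config.mz_jitter_sd, size=ref.mz.size)
    scale = np.clip(
        1.0 + rng.normal(0.0, config.intensity_jitter_cv, size=ref.mz.size), 0.05, None
    )
    return np.maximum(mz, 1.0), ref.intensity * scale * base


def make_screen_run(
    pool: Pool,
    compounds: Mapping[str, CompoundRecord],
    references: Mapping[str, ReferenceRecord],
    spikes: Sequence[SpikeSpec],
    config: SynthConfig,
    run_id: str = "run1",
    enzyme: str = "E1",
    is_control: bool = False,
    n_decoys: int | None = None,
    seed: int | None = None,
    shift: GlycoShift = DEFAULT_SHIFT,
) -> tuple[RawRun, GroundTruth]:
    """Build one chromatogram with the given spikes plus decoy MS2 scans.

    MS1 scans lie on a shared time grid whose spacing gives
    ``scans_per_peak`` samples across each +-4 sigma elution peak; every
    spiked product contributes its Gaussian-evaluated centroid to each MS1
    scan it overlaps. The analytic area height * sigma * sqrt(2*pi) is the
    ground-truth AUC. Decoy targets are drawn from (compound, degree,
    adduct) slots that were not spiked.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    member_set = set(pool.members)
    for spike in spikes:
        if spike.compound_id not in member_set:
            raise ValueError(
                f"spike {spike.compound_id!r} is not a member of pool {pool.pool_id}"
            )

    sigma = config.rt_sigma
    apexes = {
        spike: 1.0 + i * config.rt_spacing for i, spike in enumerate(spikes)
    }
    spike_mz = {
        spike: _expected_mz(
            compounds[spike.compound_id],
            spike.degree,
            _ADDUCT_BY_LABEL[spike.adduct_label],
            shift,
        )
        for spike in spikes
    }

    truth = GroundTruth()
    scans: list[PeakSpectrum] = []

    # --- shared MS1 grid ------------------------------------------------
    if spikes:
        spacing = 8.0 * sigma / (config.scans_per_peak - 1)
        t_end = max(apexes.values()) + 4.0 * sigma
        grid = np.arange(1.0 - 4.0 * sigma, t_end + spacing / 2, spacing)
        for si, t in enumerate(grid):
            mzs: list[float] = []
            ints: list[float] = []
            for spike in spikes:
                signal = spike.height * math.exp(
                    -((t - apexes[spike]) ** 2) / (2 * sigma**2)
                )
                if signal < spike.height * 1e-5:
                    continue
                jitter = float(
                    np.clip(rng.normal(0.0, config.ms1_mz_jitter_sd), -0.004, 0.004)
                )
                mzs.append(spike_mz[spike] + jitter)
                ints.append(signal)
            scans.append(
                PeakSpectrum(
                    mz=np.array(mzs),
                    intensity=np.array(ints),
                    level=1,
                    retention_time=float(t),
                    scan_id=f"ms1_{si}",
                    run_id=run_id,
                )
            )

    # --- MS2 scans at the apexes ----------------------------------------
    for mi, spike in enumerate(spikes):
        ref = references[spike.compound_id]
        frag_mz, frag_int = _jittered_fragments(ref, rng, config, spike.height)
        noise_mz = rng.uniform(50.0, spike_mz[spike] - 2.0, size=config.n_noise_peaks)
        noise_int = rng.uniform(0.0, 0.05, size=config.n_noise_peaks) * (
            frag_int.max() if frag_int.size else spike.height
        )
        precursor = spike_mz[spike] + float(
            np.clip(rng.normal(0.0, config.precursor_jitter_sd), -0.002, 0.002)
        )
        rt = apexes[spike] + 0.02
        scans.append(
            PeakSpectrum(
                mz=np.concatenate([frag_mz, noise_mz]),
                intensity=np.concatenate([frag_int, noise_int]),
                level=2,
                precursor_mz=precursor,
                charge=_ADDUCT_BY_LABEL[spike.adduct_label].charge,
                retention_time=rt,
                scan_id=f"ms2_{mi}",
                run_id=run_id,
            )
        )
        truth.spikes.append(
            {
                "run_id": run_id,
                "enzyme": enzyme,
                "compound_id": spike.compound_id,
                "degree": spike.degree,
                "adduct": spike.adduct_label,
                "rt": rt,
                "true_auc": spike.height * sigma * math.sqrt(2 * math.pi),
            }
        )

    # --- decoys ----------------------------------------------------------
    spiked_slots = {(s.compound_id, s.degree, s.adduct_label) for s in spikes}
    open_slots = [
        (cid, k, a.label)
        for cid in pool.members
        for k in (1, 2)
        for a in FEATURE_ADDUCTS
        if (cid, k, a.label) not in spiked_slots
    ]
    if n_decoys is None:
        n_decoys = round(config.decoy_fraction * max(len(spikes), 1))
    n_decoys = min(n_decoys, len(open_slots))
    member_list = list(pool.members)
    if n_decoys:
        picks = rng.choice(len(open_slots), size=n_decoys, replace=False)
        t_base = (max(apexes.values()) if apexes else 1.0) + 1.0
        for di, pi in enumerate(sorted(picks)):
            cid, k, label = open_slots[pi]
            target_mz = _expected_mz(
                compounds[cid], k, _ADDUCT_BY_LABEL[label], shift
            )
            # fragments borrowed from a different compound
            others = [m for m in member_list if m != cid] or [cid]
            donor = references[others[int(rng.integers(len(others)))]]
            frag_mz, frag_int = _jittered_fragments(donor, rng, config, 1e5)
            keep = frag_mz < target_mz - 2.0
            if not keep.any():
                continue
            scans.append(
                PeakSpectrum(
                    mz=frag_mz[keep],
                    intensity=frag_int[keep],
                    level=2,
                    precursor_mz=target_mz
                    + float(np.clip(rng.normal(0, 0.0005), -0.002, 0.002)),
                    charge=_ADDUCT_BY_LABEL[label].charge,
                    retention_time=t_base + 0.1 * di,
                    scan_id=f"decoy_{di}",
                    run_id=run_id,
                )
            )
            truth.decoys.append(
                {
                    "run_id": run_id,
                    "compound_id": cid,
                    "degree": k,
                    "adduct": label,
                    "scan_id": f"decoy_{di}",
                }
            )

    run = RawRun(
        run_id=run_id,
        scans=scans,
        metadata={
            "enzyme": enzyme,
            "mix": pool.pool_id,
            "is_control": is_control,
        },
    )
    return run, truth


def make_demo_screen(
    config: SynthConfig,
    n_enzymes: int = 2,
    background_per_pool: int = 1,
    capacity: int = 40,
):
    """A complete small screen: substrates, reference library, pools, runs.

    For every pool, one control (enzyme-free) run with ``background_per_pool``
    background products and one run per enzyme with spikes drawn at
    ``true_product_fraction``; background products are also spiked into each
    sample run so control subtraction has something to remove. Returns a dict
    with substrates, references, library entries, pools, runs, manifest rows
    and merged ground truth.
    """
    from .chemcore import PoolingConfig, pool_compounds
    from .glycolib import curate_aglycone_library, simulate_library

    compounds, records = make_aglycone_library(config)
    by_id = {c.compound_id: c for c in compounds}
    ref_by_id = {
        c.compound_id: rec for c, rec in zip(compounds, records)
    }
    pools = pool_compounds(compounds, PoolingConfig(capacity=capacity))
    aglycone_map, coverage = curate_aglycone_library(records, compounds)
    library = simulate_library(aglycone_map, compounds)

    rng = np.random.default_rng(config.seed + 1)
    runs: list[RawRun] = []
    manifest_rows: list[dict] = []
    truth = GroundTruth()
    for pool in pools:
        background = (
            choose_spikes(
                pool, rng,
                fraction=background_per_pool / len(pool.members),
                degrees=(1,), adduct_labels=("[M+H]+",),
            )[:background_per_pool]
            if background_per_pool
            else []
        )
        control_id = f"{pool.pool_id}_control"
        control, ctruth = make_control_run(
            pool, by_id, ref_by_id, background, config,
            run_id=control_id, seed=int(rng.integers(2**31 - 1)),
        )
        runs.append(control)
        truth.spikes.extend(ctruth.spikes)
        manifest_rows.append(
            {"run_id": control_id, "enzyme": "GFP", "mix": pool.pool_id,
             "is_control": True}
        )
        for e in range(1, n_enzymes + 1):
            enzyme = f"E{e}"
            run_id = f"{pool.pool_id}_{enzyme}"
            spikes = choose_spikes(pool, rng, config.true_product_fraction)
            spikes = list(spikes) + list(background)
            run, rtruth = make_screen_run(
                pool, by_id, ref_by_id, spikes, config,
                run_id=run_id, enzyme=enzyme,
                seed=int(rng.integers(2**31 - 1)),
            )
            runs.append(run)
            truth.spikes.extend(rtruth.spikes)
            truth.decoys.extend(rtruth.decoys)
            manifest_rows.append(
                {"run_id": run_id, "enzyme": enzyme, "mix": pool.pool_id,
                 "is_control": False}
            )
    return {
        "compounds": compounds,
        "records": records,
        "pools": pools,
        "library": library,
        "coverage": coverage,
        "runs": runs,
        "manifest_rows": manifest_rows,
        "truth": truth,
    }


def make_control_run(
    pool: Pool,
    compounds: Mapping[str, CompoundRecord],
    references: Mapping[str, ReferenceRecord],
    background: Sequence[SpikeSpec],
    config: SynthConfig,
    run_id: str = "control1",
    seed: int | None = None,
) -> tuple[RawRun, GroundTruth]:
    """An enzyme-free lysate run: background products + noise, control flag set."""
    return make_screen_run(
        pool,
        compounds,
        references,
        background,
        config,
        run_id=run_id,
        enzyme="GFP",
        is_control=True,
        n_decoys=0,
        seed=seed,
    )
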
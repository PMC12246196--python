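"""Monoisotopic mass arithmetic, adducts, glycoside shifts and pool design.

Everything downstream of the wet assay starts here: a glycosyltransferase
transfers a hexose from UDP-glucose onto an acceptor, shifting the product's
neutral monoisotopic mass by a fixed increment per sugar. Knowing the
acceptor masses in a reaction mix therefore fixes the complete set of
precursor m/z values at which products can appear, which is what makes
substrate multiplexing workable: pools are designed so that no two members
share a molecular weight, every expected product ion goes on the instrument
inclusion list, and the screen's size is plain arithmetic over enzymes,
substrates and pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROTON_MASS",
    "HEXOSE_SHIFT",
    "CompoundRecord",
    "Adduct",
    "GlycoShift",
    "Pool",
    "PoolingConfig",
    "PoolingInfeasibleError",
    "FEATURE_ADDUCTS",
    "IDENTIFICATION_ADDUCTS",
    "glycoside_neutral_mass",
    "expected_precursor_mz",
    "ppm_window",
    "pool_compounds",
    "make_inclusion_list",
    "reaction_grid",
]

#: Monoisotopic mass of a proton (Da).
PROTON_MASS = 1.00728

#: Mass added per glucosyl unit (dehydrated hexose, C6H10O5), Da.
#: The screening convention rounds to 162.0533; elemental summation gives
#: 162.05282. The ~0.5 mDa difference is far below the 50 ppm candidate
#: window at typical product masses and the constant is configurable.
HEXOSE_SHIFT = 162.0533


@dataclass(frozen=True)
class CompoundRecord:
    """A sugar-acceptor candidate from the substrate library."""

    compound_id: str
    name: str
    neutral_mass: float  # monoisotopic, Da
    formula: str | None = None
    structure: str | None = None  # SMILES or other line notation
    superclass: str | None = None

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError(
                f"neutral_mass must be > 0, got {self.neutral_mass!r} "
                f"for {self.compound_id!r}"
            )


@dataclass(frozen=True)
class Adduct:
    """An ESI adduct: label, charge and the mass added before division by z."""

    label: str
    charge: int
    mass_delta: float  # Da added to the neutral mass

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


#: Adducts used when filtering MS2 features by precursor m/z (3 mDa window).
FEATURE_ADDUCTS: tuple[Adduct, ...] = (
    Adduct("[M+H]+", 1, 1.00728),
    Adduct("[M+Na]+", 1, 22.98922),
    Adduct("[M+NH4]+", 1, 18.03383),
    Adduct("[M-H2O+H]+", 1, -17.00329),
)

#: Adducts considered when assigning candidates to features (50 ppm window).
IDENTIFICATION_ADDUCTS: tuple[Adduct, ...] = (
    Adduct("[M+H]+", 1, 1.00728),
    Adduct("[M+Na]+", 1, 22.98922),
    Adduct("[M+2H]2+", 2, 2.01456),
    Adduct("[M+NH4]+", 1, 18.03383),
    Adduct("[M+ACN+H]+", 1, 42.03383),
)


@dataclass(frozen=True)
class GlycoShift:
    """Neutral mass increments for glycosylation degrees 0..2."""

    unit_delta: float = HEXOSE_SHIFT
    max_degree: int = 2

    def delta(self, degree: int) -> float:
        if not (0 <= degree <= self.max_degree):
            raise ValueError(
                f"unsupported glycosylation degree {degree}; "
                f"supported: 0..{self.max_degree}"
            )
        return degree * self.unit_delta


DEFAULT_SHIFT = GlycoShift()


@dataclass
class PoolingConfig:
    """Pool capacity and the minimum within-pool mass separation (Da).

    ``max_pools`` bounds how many extra pools may be opened beyond
    ceil(n / capacity) to resolve mass collisions (each extra pool costs one
    LC-MS run per enzyme); None allows as many as there are compounds, in
    which case singleton pools make any input feasible.
    """

    capacity: int = 40
    min_separation: float = 0.01
    max_pools: int | None = None

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.max_pools is not None and self.max_pools < 1:
            raise ValueError("max_pools must be >= 1")


@dataclass
class Pool:
    """A multiplexed substrate set with pairwise mass-separated members."""

    pool_id: str
    members: list[str]
    capacity: int
    min_separation: float


class PoolingInfeasibleError(ValueError):
    """Raised when no assignment satisfies capacity + separation constraints."""


def glycoside_neutral_mass(
    neutral_mass: float, degree: int, shift: GlycoShift = DEFAULT_SHIFT
) -> float:
    """Neutral monoisotopic mass of the k-fold glycosylated product."""
    if not neutral_mass > 0:
        raise ValueError(f"neutral_mass must be > 0, got {neutral_mass}")
    return neutral_mass + shift.delta(degree)


def expected_precursor_mz(neutral_mass: float, adduct: Adduct) -> float:
    """m/z of the adducted ion: (M + mass_delta) / z."""
    if not neutral_mass > 0:
        raise ValueError(f"neutral_mass must be > 0, got {neutral_mass}")
    return (neutral_mass + adduct.mass_delta) / adduct.charge


def ppm_window(mz: float, ppm: float) -> tuple[float, float]:
    """Symmetric relative window (lo, hi) around ``mz``."""
    if mz <= 0:
        raise ValueError("mz must be > 0")
    if ppm < 0:
        raise ValueError("ppm must be >= 0")
    half = mz * ppm * 1e-6
    return mz - half, mz + half


def _pool_ok(masses: Sequence[float], min_separation: float) -> bool:
    ordered = sorted(masses)
    return all(
        b - a >= min_separation for a, b in zip(ordered, ordered[1:])
    )


def _try_assign(
    compounds: list[CompoundRecord], n_pools: int, config: PoolingConfig
) -> list[list[CompoundRecord]] | None:
    """Round-robin deal over mass-sorted compounds, then swap-repair.

    Dealing rank i to pool i % n_pools puts consecutive masses in different
    pools, so within-pool gaps are ~n_pools times the typical inter-compound
    gap by construction; the repair loop handles residual collisions.
    """
    ordered = sorted(compounds, key=lambda c: (c.neutral_mass, c.compound_id))
    pools: list[list[CompoundRecord]] = [[] for _ in range(n_pools)]
    for i, comp in enumerate(ordered):
        pools[i % n_pools].append(comp)

    def violators(pool: list[CompoundRecord]) -> list[int]:
        """Indices of members too close to a neighbour (mass order)."""
        idx = sorted(range(len(pool)), key=lambda j: pool[j].neutral_mass)
        bad: set[int] = set()
        for a, b in zip(idx, idx[1:]):
            if pool[b].neutral_mass - pool[a].neutral_mass < config.min_separation:
                bad.add(b)
        return sorted(bad)

    for _ in range(4 * len(compounds) + 8):
        moved = False
        for pi, pool in enumerate(pools):
            for vi in violators(pool):
                comp = pool[vi]
                # prefer a plain move into a pool with spare capacity
                placed = False
                for qi, other in enumerate(pools):
                    if qi == pi:
                        continue
                    if len(other) < config.capacity and _pool_ok(
                        [c.neutral_mass for c in other] + [comp.neutral_mass],
                        config.min_separation,
                    ):
                        other.append(pool.pop(vi))
                        placed = moved = True
                        break
                if placed:
                    break
                # otherwise swap with a member of another pool
                for qi, other in enumerate(pools):
                    if qi == pi:
                        continue
                    for wj, other_comp in enumerate(other):
                        new_p = [
                            c.neutral_mass for k, c in enumerate(pool) if k != vi
                        ] + [other_comp.neutral_mass]
                        new_q = [
                            c.neutral_mass for k, c in enumerate(other) if k != wj
                        ] + [comp.neutral_mass]
                        if _pool_ok(new_p, config.min_separation) and _pool_ok(
                            new_q, config.min_separation
                        ):
                            pool[vi], other[wj] = other[wj], pool[vi]
                            placed = moved = True
                            break
                    if placed:
                        break
                if placed:
                    break
            if moved:
                break
        if not moved:
            break

    if all(not violators(p) for p in pools):
        return pools
    return None


def pool_compounds(
    compounds: Sequence[CompoundRecord], config: PoolingConfig | None = None
) -> list[Pool]:
    """Partition compounds into mass-separated pools of bounded size.

    Starts from ceil(n / capacity) pools and adds pools only if the
    separation constraint cannot be repaired, so the pool count is minimal
    for well-separated libraries. Deterministic for a given input.
    """
    config = config or PoolingConfig()
    if len(compounds) == 0:
        raise ValueError("need at least one compound to pool")
    compounds = list(compounds)
    n_min = math.ceil(len(compounds) / config.capacity)
    n_max = len(compounds) if config.max_pools is None else min(
        config.max_pools, len(compounds)
    )
    for n_pools in range(n_min, n_max + 1):
        assignment = _try_assign(compounds, n_pools, config)
        if assignment is not None:
            return [
                Pool(
                    pool_id=f"mix{i + 1}",
                    members=[c.compound_id for c in pool],
                    capacity=config.capacity,
                    min_separation=config.min_separation,
                )
                for i, pool in enumerate(assignment)
                if pool
            ]
    colliding = _collision_report(compounds, config.min_separation)
    raise PoolingInfeasibleError(
        "no pool assignment satisfies capacity "
        f"{config.capacity} and min_separation {config.min_separation}; "
        f"colliding masses: {colliding}"
    )


def _collision_report(
    compounds: Sequence[CompoundRecord], min_separation: float
) -> list[tuple[str, float]]:
    ordered = sorted(compounds, key=lambda c: c.neutral_mass)
    out = []
    for a, b in zip(ordered, ordered[1:]):
        if b.neutral_mass - a.neutral_mass < min_separation:
            out.append((a.compound_id, a.neutral_mass))
            out.append((b.compound_id, b.neutral_mass))
    return sorted(set(out), key=lambda t: t[1])


def make_inclusion_list(
    pool: Pool,
    compounds: Mapping[str, CompoundRecord],
    degrees: Iterable[int] = (1, 2),
    adducts: Sequence[Adduct] = FEATURE_ADDUCTS,
    shift: GlycoShift = DEFAULT_SHIFT,
) -> list[tuple[str, int, str, float]]:
    """Expected product ions for one pool: (compound_id, degree, adduct, m/z).

    One entry per (member, degree, adduct) combination, sorted by m/z; this
    is the per-mix list the instrument prioritises for MS2 acquisition.
    """
    entries: list[tuple[str, int, str, float]] = []
    for cid in pool.members:
        if cid not in compounds:
            raise KeyError(f"pool member {cid!r} not in compound table")
        comp = compounds[cid]
        for k in degrees:
            product_mass = glycoside_neutral_mass(comp.neutral_mass, k, shift)
            for adduct in adducts:
                entries.append(
                    (cid, k, adduct.label, expected_precursor_mz(product_mass, adduct))
                )
    entries.sort(key=lambda e: e[3])
    return entries


def reaction_grid(
    n_enzymes: int, n_substrates: int, pools: Sequence[Pool] | int
) -> tuple[int, int]:
    """Screen size: (enzyme x substrate reactions, enzyme x pool LC-MS runs)."""
    if n_enzymes < 0 or n_substrates < 0:
        raise ValueError("counts must be >= 0")
    n_pools = pools if isinstance(pools, int) else len(pools)
    return n_enzymes * n_substrates, n_enzymes * n_pools
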
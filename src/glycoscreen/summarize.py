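"""Screen-level summaries of a product-call table.

Counts are taken over distinct productive (enzyme, substrate) pairs — a
substrate is "accepted" when at least one enzyme produced at least one call
on it at any degree or adduct, and an enzyme's promiscuity is the number of
distinct substrates it glycosylated. Superclass productivity expresses, per
natural-product superclass, the percentage of all possible enzyme x
substrate reactions in that class that yielded a product. Novelty is scored
against a user-provided presence table (compound -> glucoside already known
in a chemical database) rather than any live query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "ScreenSummary",
    "NoveltyResult",
    "summarize_screen",
    "annotate_novelty",
    "read_product_table",
]

#: Column names the pipeline's own product tables use.
PRODUCT_COLUMNS = ["enzyme", "compound_id", "degree"]


@dataclass
class ScreenSummary:
    per_enzyme_substrate_counts: dict[str, int]
    per_substrate_enzyme_counts: dict[str, int]
    n_products_total: int
    n_products_single: int
    n_products_double: int
    n_substrates_accepted: int
    superclass_productivity: dict[str, float]  # percent
    n_superclass_na: int = 0

    def to_dict(self) -> dict:
        return {
            "n_products_total": self.n_products_total,
            "n_products_single": self.n_products_single,
            "n_products_double": self.n_products_double,
            "n_substrates_accepted": self.n_substrates_accepted,
            "per_enzyme_substrate_counts": self.per_enzyme_substrate_counts,
            "per_substrate_enzyme_counts": self.per_substrate_enzyme_counts,
            "superclass_productivity_pct": self.superclass_productivity,
            "n_superclass_na": self.n_superclass_na,
        }


def read_product_table(
    path_or_df, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Load a product table, renaming columns via ``column_map`` if given.

    ``column_map`` maps source column names to the pipeline's names
    (enzyme, compound_id, degree), which lets externally deposited product
    tables with their own layouts feed the same summaries.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        from .msio import read_table

        df = read_table(path_or_df, required=())
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in PRODUCT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"product table missing columns {missing}")
    return df


def summarize_screen(
    product_table: pd.DataFrame,
    substrate_table: pd.DataFrame,
    n_enzymes: int,
) -> ScreenSummary:
    """Fig.-2-style totals from product calls and the substrate library.

    The product table is deduplicated to (enzyme, compound_id, degree) rows
    before counting, so multiple adducts or retention-time isomers of the
    same product never inflate counts.
    """
    products = product_table[PRODUCT_COLUMNS].drop_duplicates()
    known = set(substrate_table["compound_id"])
    unknown = sorted(set(products["compound_id"]) - known)
    if unknown:
        raise ValueError(f"product rows reference unknown compounds: {unknown}")

    pairs = products[["enzyme", "compound_id"]].drop_duplicates()
    per_enzyme = pairs.groupby("enzyme").size().to_dict()
    per_substrate = {cid: 0 for cid in substrate_table["compound_id"]}
    per_substrate.update(pairs.groupby("compound_id").size().to_dict())

    n_single = int((products["degree"] == 1).sum())
    n_double = int((products["degree"] == 2).sum())

    superclass_pct: dict[str, float] = {}
    n_na = 0
    if "superclass" in substrate_table.columns:
        sclass = substrate_table.set_index("compound_id")["superclass"]
        pair_class = pairs["compound_id"].map(sclass)
        for cls, members in substrate_table.groupby(
            substrate_table["superclass"].fillna("NA")
        ):
            n_sub = len(members)
            n_productive = int((pair_class.fillna("NA") == cls).sum())
            pct = 100.0 * n_productive / (n_enzymes * n_sub) if n_enzymes else 0.0
            if cls == "NA":
                n_na = n_sub
            superclass_pct[str(cls)] = pct

    return ScreenSummary(
        per_enzyme_substrate_counts={k: int(v) for k, v in per_enzyme.items()},
        per_substrate_enzyme_counts={k: int(v) for k, v in per_substrate.items()},
        n_products_total=len(products),
        n_products_single=n_single,
        n_products_double=n_double,
        n_substrates_accepted=int(sum(v > 0 for v in per_substrate.values())),
        superclass_productivity=superclass_pct,
        n_superclass_na=n_na,
    )


@dataclass
class NoveltyResult:
    novelty_fraction: float | None  # percent; None when undefined
    n_novel: int
    n_known: int
    n_unknown: int  # compounds missing from the presence table


def annotate_novelty(
    product_table: pd.DataFrame, presence: Mapping[str, bool]
) -> NoveltyResult:
    """Fraction of called (compound, degree) products absent from a database.

    ``presence[cid]`` is True when a glucoside of the compound is already
    recorded. Products of compounds missing from the table are counted as
    unknown and excluded from the denominator.
    """
    products = product_table[["compound_id", "degree"]].drop_duplicates()
    n_novel = n_known = n_unknown = 0
    for cid in products["compound_id"]:
        if cid not in presence:
            n_unknown += 1
        elif presence[cid]:
            n_known += 1
        else:
            n_novel += 1
    denom = n_novel + n_known
    fraction = 100.0 * n_novel / denom if denom else None
    return NoveltyResult(fraction, n_novel, n_known, n_unknown)


def pubchem_query_term(name: str) -> str:
    """The search-term construction used for glucoside presence lookups."""
    return f"{name} *glucoside"
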
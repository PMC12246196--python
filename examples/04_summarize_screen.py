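"""Screen-level summaries: enzyme promiscuity, substrate acceptance,
superclass productivity and database novelty.

Counts are over distinct productive (enzyme, substrate) pairs; superclass
productivity is the percentage of possible enzyme x substrate reactions in
a class that yielded product.
"""

import pandas as pd

from glycoscreen.summarize import annotate_novelty, summarize_screen

substrates = pd.DataFrame(
    {
        "compound_id": ["S1", "S2", "S3", "S4"],
        "name": ["a", "b", "c", "d"],
        "neutral_mass": [250.0, 300.0, 350.0, 400.0],
        "superclass": ["Flavonoids", "Flavonoids", "Coumarins", "Terpenoids"],
    }
)
products = pd.DataFrame(
    [
        ("E1", "S1", 1), ("E1", "S1", 2), ("E1", "S2", 1),
        ("E2", "S1", 1), ("E2", "S3", 1),
    ],
    columns=["enzyme", "compound_id", "degree"],
)

s = summarize_screen(products, substrates, n_enzymes=2)
print(f"products: {s.n_products_total} "
      f"({s.n_products_single} single + {s.n_products_double} double)")
print(f"substrates accepted by >= 1 enzyme: {s.n_substrates_accepted} / 4")
print(f"per-enzyme substrate counts: {s.per_enzyme_substrate_counts}")
print("superclass productivity (% of possible reactions):")
for cls, pct in sorted(s.superclass_productivity.items(), key=lambda kv: -kv[1]):
    print(f"  {cls:<12} {pct:5.1f}%")

novelty = annotate_novelty(products, {"S1": True, "S2": False, "S3": False})
print(f"novel products (no known glucoside in the presence table): "
      f"{novelty.novelty_fraction:.0f}% of {novelty.n_novel + novelty.n_known}")
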
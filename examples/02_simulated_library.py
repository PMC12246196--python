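"""Simulate a glycoside MS/MS reference library from aglycone spectra.

A glycoside fragments mostly into its aglycone's ions, so a glycoside
library can be simulated by shifting only the expected precursor m/z
(+162.0533 Da per hexose) while keeping the aglycone fragment pattern.
"""

from glycoscreen.chemcore import CompoundRecord
from glycoscreen.glycolib import curate_aglycone_library, simulate_library
from glycoscreen.msio import ReferenceRecord

substrates = [CompoundRecord("F", "formononetin", 268.0736)]
records = [
    ReferenceRecord(
        name="Formononetin",
        mz=[118.041, 132.057, 197.060, 213.055, 237.055, 253.050],
        intensity=[0.08, 0.12, 0.25, 0.40, 0.30, 1.00],
        record_id="MoNA-like-1",
        precursor_mz=269.0808,  # [M+H]+ of the aglycone
    )
]

aglycone_map, coverage = curate_aglycone_library(records, substrates)
entries = simulate_library(aglycone_map, substrates)

print(f"{len(records)} aglycone spectrum x 2 degrees x 5 adducts "
      f"= {len(entries)} simulated glycoside references")
for e in sorted(entries, key=lambda e: e.expected_precursor_mz)[:4]:
    print(f"  {e.compound_id} k={e.degree} {e.adduct.label:<11} "
          f"expect precursor m/z {e.expected_precursor_mz:.4f}")
# e.g. k=1 [M+H]+ is 268.0736 + 162.0533 + 1.00728 = 431.1342: the mass
# where formononetin glucoside appears, fragmenting like formononetin.
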
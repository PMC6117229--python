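"""Exact vs MS-Ready searching on the nicotine-family library.

The library holds 8 substances built around the nicotine skeleton: three
stereo-forms, two constitutional isomers of C10H14N2, and three
multi-component nicotine salts. An exact formula search only matches
substances whose overall formula is C10H14N2 (5 of them); the MS-Ready
search follows component links and finds all 8, and the nicotine
component itself sits in 6.
"""

from msready import (
    StandardizationConfig,
    build_fixture,
    exact_formula_search,
    inchikey,
    mass_search,
    msready_formula_search,
)
from msready.registry import Registry

registry = Registry()
registry.ingest_substances(build_fixture("nicotine_family").substances)
registry.process_all(StandardizationConfig())

exact = exact_formula_search(registry, "C10H14N2")
msready = msready_formula_search(registry, "C10H14N2")
print(f"exact formula search C10H14N2:    {len({h.substance_id for h in exact})} substances")
print(f"MS-Ready formula search C10H14N2: {len({h.substance_id for h in msready})} substances")

nicotine = registry.chemical_by_inchikey(inchikey("CN1CCCC1c1cccnc1"))
links = registry.substances_for_chemical(nicotine.cid)
print(f"substances containing the nicotine component: {len(links)}")
for sub in links:
    print(f"  {sub.source_id}  {sub.name}  (data sources: {sub.data_sources})")

hits = mass_search(registry, 162.1157, ppm=5)
print(f"mass search 162.1157 +/- 5 ppm: {len(hits)} (component, substance) pairs")
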
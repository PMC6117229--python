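"""Exporting search hits as a MetFrag-ready candidate file.

A fragmenter needs the structure that is actually observed (the MS-Ready
component) but should report the registered substance — salt, mixture or
free base — it belongs to. The export therefore carries structural fields
from the component (DTXCID-style columns) and identity fields from the
substance, plus any numeric metadata selected for scoring.
"""

from msready import StandardizationConfig, build_fixture, msready_formula_search
from msready.metfrag import export_metfrag
from msready.registry import Registry

registry = Registry()
registry.ingest_substances(build_fixture("triazines").substances)
registry.process_all(StandardizationConfig())

hits = msready_formula_search(registry, "C9H16ClN5") + msready_formula_search(
    registry, "C7H12ClN5"
)
text = export_metfrag(
    hits, registry, metadata_fields=["data_sources", "pubmed_refs"]
)
lines = text.splitlines()
print(f"{len(lines) - 1} candidate rows; header:")
print(lines[0])
print("first row:")
print(lines[1])
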
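# msready

**MS-Ready structure preparation, substance mapping and suspect-screening
search for non-targeted high-resolution mass spectrometry.**

In non-targeted and suspect-screening analysis (NTA/SSA), an HRMS
instrument observes a *single, desalted, neutral* molecular species: a
pseudomolecular ion such as [M+H]⁺ whose neutral monoisotopic mass and
molecular formula are what the analyst can actually search. Chemical
registries, however, store substances as they are sold and regulated —
hydrochloride salts, 3:2 fumarate solvates, potassium sulfonates, mixtures
— whose overall formula and mass will never match the observed feature.
A naive "exact" database search therefore silently misses every salt and
mixture form of the compound that is really in the sample, along with the
usage, toxicity and literature metadata attached to those substances.

`msready` addresses this for analysts and cheminformaticians who maintain
their own suspect lists. It converts substance records into **MS-Ready
structures** — desalted, neutralized, stereochemistry-free,
tautomer-canonical single components — while keeping bidirectional
substance ↔ component links, so one formula or mass query retrieves every
registered form of a chemical:

1. **Standardization pipeline** (`msready.standardizer`): consistency
   checking → mixture separation and inorganic removal → counterion
   exclusion-list desalting → ordered tautomer/mesomer transforms →
   neutralization (with permanent-charge flagging) and stereo removal →
   aromatization → InChIKey deduplication. A `qsarready` mode applies the
   larger exclusion list and additionally discards mixtures and
   organometallics, the form needed for descriptor calculation.
2. **Registry** (`msready.registry`): SQLite-backed substance (`SID…`) and
   chemical (`CID…`) tables joined by a typed relationship mapping table
   (`has_structure`, `component_of`, `msready_of`), with SDF/TSV export.
3. **Search** (`msready.search`): exact vs MS-Ready formula search,
   monoisotopic-mass search with ppm or absolute windows, and batch files
   mixing formulas and masses. A charged query like the PFOS sulfonate
   `C8F17O3S-` is neutralized by ±H per unit charge before matching.
4. **MetFrag export** (`msready.metfrag`): the 14-column candidate file in
   which structural fields describe the observable component and identity
   fields the mapped substance, plus optional numeric metadata columns.
5. **Scoring** (`msready.scoring`): the additive scheme
   `score = Σᵢ wᵢ·tᵢ` over a fragmenter term, a spectral-similarity term
   (both ∈ [0,1], supplied by external tools) and per-category metadata
   terms scaled to [0,1] by the column maximum (missing → 0); with five
   metadata categories at unit weights the maximum is 7. Candidates
   sharing an InChIKey first block can be grouped under their best member.

Mass arithmetic uses most-abundant-isotope masses with electron-mass
corrections: `m/z([M+H]⁺) = M + m_p`, `m/z(M⁺) = M − m_e`.

## Worked example

```bash
python examples/03_search.py
```

```
exact formula search C10H14N2:    5 substances
MS-Ready formula search C10H14N2: 8 substances
substances containing the nicotine component: 6
  NIC001  (S)-Nicotine  (data sources: 3880)
  NIC003  Nicotine (unspecified stereo)  (data sources: 540)
  NIC006  Nicotine hydrochloride  (data sources: 210)
  NIC008  Nicotine sulfate (2:1)  (data sources: 160)
  NIC002  (R)-Nicotine  (data sources: 120)
  NIC007  Nicotine salicylate  (data sources: 95)
mass search 162.1157 +/- 5 ppm: 8 (component, substance) pairs
```

The bundled nicotine-family library registers 8 substances. Searching the
nicotine formula C10H14N2 *exactly* matches only the five substances whose
overall formula is C10H14N2 (three stereo-forms and two constitutional
isomers); the *MS-Ready* search follows component links and also returns
the hydrochloride, salicylate and sulfate — the forms actually found in
commerce — ranked by data-source count. Six of the eight substances
contain the nicotine component itself.

The other scripts in `examples/` demonstrate formula/adduct arithmetic
(`01`), the standardization pipeline on nicarbazin, raloxifene·HCl and
PFOS-K (`02`), MetFrag candidate export (`04`) and metadata scoring
(`05`). A thin CLI mirrors the library:

```bash
msready fixtures --name triazines --out demo/
msready build-db demo/triazines.sdf --out demo/registry.db
msready search --db demo/registry.db --formula C9H16ClN5 \
    --export-metfrag demo/candidates.csv --metadata data_sources
```

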
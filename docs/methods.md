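# Methods

## The problem being modelled

High-resolution mass spectrometry observes a desalted, neutral, single
molecular species. Registries store substances — salts, solvates,
mixtures, charged dyes, organometallics. The package's job is the
bidirectional bridge: reduce each substance to the component structure(s)
an instrument could observe ("MS-Ready" forms), keep typed links from
every component back to every substance containing it, and search on the
component level while reporting on the substance level.

## Mass and formula arithmetic

Element masses are most-abundant-isotope exact masses (≥ 6 decimals) from
a current IUPAC-derived table bundled as `data/element_masses.tsv`
(~45 elements; unknown symbols are a parse error, not silently zero).
Monoisotopic mass of a (possibly multi-part) formula is
`Σ_parts (Σ count·m_isotope − q_part·m_e)`; the electron mass
(5.48579909×10⁻⁴ Da) is included for charged species, so an intrinsic
cation's m/z is slightly below its summed atomic masses. `[M+H]⁺`/`[M−H]⁻`
add/subtract one proton mass `m_p = m_H − m_e = 1.007276 Da`. Printed m/z
values in the field are typically given to 4 decimals and may be rounded
or truncated; the package computes at full double precision, displays at
4 decimals, and documents a ±1 mDa convention gap for fragment ions
(e.g. the butyl cation computes to 57.06988 and is commonly printed
57.0698). Multiply charged adducts and isotope-pattern simulation are out
of scope.

Formula text is parsed with Hill-order canonical display (C, H, then
alphabetical; without carbon fully alphabetical), dot-separated parts, and
trailing charge signs. Charge dialects: repeated signs (`--`), sign-digit
(`-2`), and caret (`^2-`). A bare digit before a single sign (`O2-`) is
read as an element count plus one charge, because `C2H3O2-` (acetate)
must parse with two oxygens; this is the one deliberate restriction on
"magnitude-before-sign" notation, chosen over making common anion
formulas ambiguous.

## The standardization pipeline

Steps, in order, per substance record:

1. **Consistency** — RDKit parse + sanitization (valence check, aromaticity
   perception). Hypervalent drawings RDKit normalizes on input (e.g.
   `N(=O)=O` nitro) are accepted. Failures yield `status=error` with the
   source identifier; batch processing continues.
2. **Split & classify** — connected components, ordered by heavy-atom count
   descending then canonical SMILES (reproducible output order). Classes:
   *organic* (≥1 carbon not in a CO/CO₂/carbonate/cyanide-like pattern,
   no metal–carbon bond), *organometallic* (≥1 covalent metal–carbon
   bond; retained in `msready` mode, dropped in `qsarready`), *inorganic*
   (dropped), *excluded* (on the counterion list). The metal set covers
   alkali/alkaline-earth/transition/lanthanide/actinide/post-transition
   metals; B, Si, Ge, As, Sb, Te count as non-metals, matching common
   QSAR curation practice. An explicit bond in the connection table is
   what makes a metal association covalent; disconnected charged
   fragments are ionic salt partners and are handled by classification
   and exclusion instead.
3. **Exclusion-list desalting** — membership is tested on the InChIKey of
   the *neutralized, stereochemistry-free* form, so benzoate and benzoic
   acid entries unify, and fires only for records with ≥ 2 components: a
   substance that *is* acetic acid stays searchable. The bundled MS-Ready
   list has 32 records (mineral acids/ions, water, common solvents); the
   bundled QSAR-Ready list is a superset (51 records) adding the organic
   acid counterions (acetate, fumarate, citrate, tosylate, …) that
   MS-Ready deliberately retains as observable secondary components. Both
   bundled lists are synthetic stand-ins curated for this package; a
   user-supplied exclusion SDF (`LABEL` or title field per record)
   replaces them verbatim. Because exclusion keys are stereo-free,
   fumarate and maleate collapse to one entry; the loader keeps the first
   label. One consequence worth noting: a fumarate salt in `qsarready`
   mode is desalted to its free base (salt removal precedes the mixture
   check), not discarded as a mixture — only records still holding two or
   more non-excluded components are discarded there.
4. **Tautomer/mesomer normalization** — an ordered, data-driven rule file
   (`data/transforms.txt`: nitro and azide mesomers, keto–enol,
   enamine–imine, ynol–ketene) applied as reaction SMARTS to a fixpoint
   with a 20-iteration cap, followed by RDKit's canonical-tautomer
   selection as a deterministic tie-break. Every rule must conserve the
   molecular formula — a product with a different element count is
   rejected — so mesomer fixes move formal charges only and tautomer
   fixes move hydrogens only. Non-convergence returns the last form
   flagged `max-iterations`.
5. **Neutralization & stereo removal** — protonatable anions (O⁻, S⁻, N⁻,
   C⁻, P⁻, Se⁻) gain H and cations with H lose H until net charge 0 where
   possible. Atoms bonded to an oppositely charged neighbour (nitro,
   azide, other ylides from step 4) are left as drawn. Permanently
   charged species — quaternary ammonium, stabilized carbenium, bare
   metal cations — keep their charge and are flagged `permanent_charge`.
   Stereo descriptors (tetrahedral and double-bond) are removed;
   conformers are dropped too, since the InChI engine would otherwise
   re-perceive stereochemistry from 2D coordinates of SDF inputs.
   Isotopic labels are *retained*: they change the monoisotopic mass,
   which is the quantity being searched.
6. **Finalize** — aromatization by the toolkit's default model, canonical
   aromatic SMILES, Hill formula, InChIKey and monoisotopic mass attached;
   SDF output adds explicit hydrogens.
7. **Dedup** — within-substance components unified by full InChIKey (the
   3:2 fumarate solvate yields two components, not five).

MS-Ready output is a fixpoint of the pipeline: re-standardizing a
component reproduces its own InChIKey (property-tested on randomized
SMILES renderings of every bundled library).

## Registry and search semantics

Substances get zero-padded sequential `SID…` surrogates, unique
structures `CID…`, unified by standard InChIKey at load. The substance's
*overall* formula is the merged Hill formula of the full original
structure (nicarbazin: C19H18N6O6); the dot-separated per-part formula is
kept alongside and used in export columns. Exact search compares the
merged overall formula (and rejects charged queries); MS-Ready search
neutralizes the query by ±H per unit charge, matches MS-Ready component
formulas, and follows `component_of` links to substances. Mass search
uses a ±5 ppm default window (the conventional fragmenter setting), with
an absolute-Da override, and records the signed ppm deviation per hit.
Results rank by substance data-source count descending, ties by id.

## Scoring

Core terms (fragmenter, spectral similarity) are inputs read from
columns — in-silico fragmentation and spectral matching are external
tools — defaulting to 0 when absent. Metadata categories scale to [0,1]
by column maximum (default) or min–max (option); missing values score 0,
an all-missing category scores 0 everywhere, a constant non-zero category
scores 1 under divide-by-max. Negative raw values are rejected
(categories are counts, flags, percentages). Weights are linear
multipliers in [0,∞), default 1. Grouping partitions by InChIKey first
block (connectivity skeleton, so all salt forms of one compound share a
group); the representative is the highest combined score, ties to the
lexicographically smaller identifier, and all member identifiers remain
visible. Grouping merges metadata-distinct entries, so it is optional.

## The example libraries

`msready.fixtures` embeds curated literature SMILES; generation is fully
deterministic (no randomness). The nicotine family is *engineered to the
stated counts* — 3 stereo-forms + 2 constitutional isomers (anabasine,
metanicotine) + 3 nicotine salts give MS-Ready 8 / exact 5 / component-in-6
— without claiming to mirror any particular registry's identities. The
metadata table values (data sources, PubMed counts, list flags, % active)
are plausible magnitudes chosen once for the ranking narratives, not
measurements. What passing tests show is that the *mechanics* — mixture
separation, linkage retention, count arithmetic, ranking — are correct;
they say nothing about coverage or curation quality of any real database,
nor about fragmenter or spectral-match accuracy, which this package does
not compute.

## Numerical and scale choices

Problem sizes are desk-scale by design: libraries of 1–8 substances,
registries of tens of rows, 200-structure idempotence sweeps and
500-formula mass-oracle sweeps in the test suite; the acceptance script
uses a 50-structure idempotence spot check. SQLite keeps the registry a
single file with no server. Formula comparison is string equality on
canonical Hill text; mass equality in tests uses 1×10⁻⁴ Da. Component
ordering, CSV quoting (RFC-4180, LF endings) and SDF property order are
fixed so exports are byte-stable.

## Known limitations

- Tautomer canonicalization matches RDKit's model, not any specific
  legacy toolchain; different engines choose different canonical forms
  (both are formula-preserving, so search behaviour is unaffected).
- The carve-out pattern list for "inorganic carbon" (CO, CO₂, carbonate,
  cyanide-like) is finite; exotic inorganic carbon species may classify
  as organic.
- Polymer records, 3D conformer handling and multiply charged adducts are
  out of scope; charged-query neutralization assumes protic charge sites.
- The bundled exclusion lists are reasonable defaults, not a curated
  registry artifact; production use should supply an authoritative list.
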
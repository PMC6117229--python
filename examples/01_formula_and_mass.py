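"""Formula parsing, monoisotopic masses and adduct m/z.

The triazine herbicides terbutylazine (C9H16ClN5) and its degradate
desethylterbutylazine (C7H12ClN5) are classic suspect-screening targets;
their neutral monoisotopic masses are what an analyst computes from an
observed [M+H]+ feature before searching a structure database.
"""

from msready import AdductSpec, adduct_mz, monoisotopic_mass, parse_formula

for formula in ("C9H16ClN5", "C7H12ClN5"):
    mass = monoisotopic_mass(formula)
    mh = adduct_mz(formula, AdductSpec("M+H", 1))
    print(f"{formula}: neutral monoisotopic mass {mass:.4f} Da, [M+H]+ {mh:.4f}")

# A butyl fragment ion seen in MS/MS is an intrinsic cation: its m/z is the
# summed atomic masses minus one electron mass.
print(f"C4H9+ fragment m/z: {adduct_mz('C4H9', AdductSpec('M', 1)):.4f}")

# Salt formulas keep their dot-separated parts and per-part charges.
salt = parse_formula("C31H42N3+.C2H3O2-")
print(f"salt formula {salt.display}: net charge {salt.charge}, "
      f"mass {monoisotopic_mass(salt):.4f} Da")
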
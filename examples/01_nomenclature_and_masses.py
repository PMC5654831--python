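"""Parse lipid shorthand names, classify acyl chains, compute masses.

Run:  python examples/01_nomenclature_and_masses.py
"""

from shotgunlipids import classify_acyl, count_pufa_chains, parse_shorthand
from shotgunlipids.nomenclature import FattyAcyl

for name in ["PC 16:0/22:6", "TAG 54:5", "SM 18:0", "PE-O 16:0/20:4"]:
    species = parse_shorthand(name)
    print(f"{name:16s} class={species.lipid_class.name:5s} "
          f"level={species.level:9s} formula={species.composition.hill_formula:16s} "
          f"M={species.neutral_mass:9.4f}  [M+H]+/[M+NH4]+ m/z={species.mz():9.4f}")

# Chain classification: PUFA means >= 2 double bonds; the omega family
# comes from a configurable lookup since shorthand carries no double-bond
# positions.
for chain in [FattyAcyl(22, 6), FattyAcyl(20, 4), FattyAcyl(18, 1)]:
    out = classify_acyl(chain)
    print(f"{str(chain):6s} PUFA={out.is_pufa!s:5s} family={out.omega_family}")

# Double-PUFA phospholipids (a PUFA at both sn positions) are the one
# metric with a strain-divergent diet response.
for name in ["PC 16:0/22:6", "PC 18:2/22:6", "PC 16:0/18:1"]:
    print(f"{name:14s} PUFA chains: {count_pufa_chains(parse_shorthand(name))}")
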
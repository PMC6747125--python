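"""Convert between dissociation constants and binding free energies.

dG = RT ln Kd relates the two scales; the ordinal range classes bin Kd
into the five categories used to summarise predictions.
"""

from wntcrd import classify_affinity, delta_g_from_kd, kd_from_delta_g

for kd in (3.1, 15.7, 102.5, 500.0):
    dg = delta_g_from_kd(kd)
    print(f"Kd = {kd:7.1f} nM  ->  dG = {dg:7.2f} kcal/mol  "
          f"range {classify_affinity(kd).symbol}")

print()
for dg in (-11.66, -10.87, -9.47):
    print(f"dG = {dg:.2f} kcal/mol  ->  Kd = {kd_from_delta_g(dg):6.1f} nM")

print("\nLower Kd means tighter binding, hence a more negative dG; the "
      "range symbols bin Kd at 10/40/100/400 nM.")
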
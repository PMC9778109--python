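"""Branching ratios in a photochemical reaction network.

After the photochemical steps, a radical intermediate sits at a junction of
competing channels: a productive hydride transfer, a dead-end hydride
branch, quenching by a nearby thiolate, and reactions with molecular
oxygen.  Each externally supplied barrier enters only through a rate law --
Eyring for thermal steps, the tunneling distance ruler for electron
transfers -- and the relative rates decide the fate of the intermediate.

This script loads the packaged mechanism network and prints the branching
analysis at the key intermediate, including the channels excluded on spin
grounds and the suppression of the superoxide-forming route.
"""

from etpath import branch_ratio, eyring_rate, mechanism_network

net = mechanism_network()

print(f"productive/dead-end hydride ratio: "
      f"{eyring_rate(11.3) / eyring_rate(26.6):.1e}")

res = branch_ratio(net, "C18H-PChlide.")
print(f"\nbranching at C18H-PChlide. ({res.temperature} K)")
print("(O2 channels assume saturating oxygen; anaerobically the hydride "
      "step takes the full flux):")
for name, frac in sorted(res.fractions.items(), key=lambda kv: -kv[1]):
    print(f"  {name:<18} rate {res.rates[name]:>9.2e} s^-1  fraction {frac:.3g}")
for name, why in res.excluded.items():
    print(f"  {name:<18} excluded: {why}")

edges = {e.name: e for e in net.edges}
sup = edges["O2_quench_PChlide-"].rate(298.15) / edges["O2_quench_C18"].rate(298.15)
print(f"\nO2 attack on the anion radical vs the protonated radical: "
      f"{sup:.1e}x faster")
print("=> the 9.2 kcal/mol barrier protects the committed intermediate "
      "from superoxide formation")
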
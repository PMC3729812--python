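"""Simulate a two-population panel and recover its drift parameter.

Builds a Balding–Nichols panel (two populations of 50 diploids, drift
F = 0.1, 20,000 SNPs), runs the per-site weighted F_ST scan between them and
combines the per-site mean squares into the multi-locus estimate.
"""

from selnet import PopulationSpec, multilocus_fst, pairwise_scan, simulate_panel

pops = [
    PopulationSpec("POP1", "West", 50, divergence_F=0.1),
    PopulationSpec("POP2", "East", 50, divergence_F=0.1),
]
panel = simulate_panel(pops, n_snps=20_000, seed=1)
scan = pairwise_scan(panel, {"POP1"}, {"POP2"})
est, se = multilocus_fst(scan)

n_qual = int(scan["qualifying"].sum())
print(f"sites scanned:        {len(scan)}")
print(f"qualifying (F_ST>0):  {n_qual}")
print(f"monomorphic:          {scan.attrs['n_monomorphic']}")
print(f"multi-locus F_ST:     {est:.4f} +/- {se:.4f}")
print()
print("The multi-locus estimate should sit within a couple of standard")
print("errors of the simulated drift parameter F = 0.1: allele-frequency")
print("differentiation measured from genotypes recovers the divergence that")
print("was put into the simulation.")
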
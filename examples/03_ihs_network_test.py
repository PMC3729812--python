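"""Network randomization test on an iHS-like score track.

Simulates a normalized-score track with +2 offsets planted in the twenty
candidate regions (a strong network-wide sweep signal), then asks how often
a random, 2-Mb-spaced network of the same size attains an equal or higher
mean of per-region maximum |score|.
"""

from selnet import Region, SweepSpec, randomization_p, simulate_ihs_track

chrom_lengths = {c: 30_000_000 for c in ("1", "2", "3", "4")}
candidates, sweeps = [], []
for c in chrom_lengths:
    for k in range(5):
        start = 3_000_000 + k * 5_000_000
        region = Region(c, start, start + 50_000)
        candidates.append(region)
        sweeps.append(SweepSpec(region, "ihs_shift", 2.0))

track = simulate_ihs_track(chrom_lengths, density=500, sweeps=sweeps, seed=4)
result = randomization_p(candidates, track, n_random=10_000, seed=5)

print(f"track sites:            {len(track)}")
print(f"candidate regions:      {result.n_regions}")
print(f"mean of region maxima:  {result.network_mean:.3f}")
print(f"randomization p-value:  {result.p_value:.4f}  ({result.n_random} random networks)")
print()
print("Under neutrality the mean of per-region max |iHS| for ~25-site windows")
print("sits near 2.2; the +2 offset pushes the candidate mean far above the")
print("random-network distribution, so the p-value should be at or near 0.")
print("Rerun with sweeps=[] to see a null p-value uniform on (0, 1).")
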
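"""Score microsatellite instability from paired tumor-normal repeat-length
histograms and classify the sample at the 3.5 cut-off.

Prints the number of evaluated and unstable sites, the MSI score, and the
MSI-H/MSS classification.
"""

from uromics import SimulationConfig, gen_msi_sites, msi_score
from uromics.msi import test_site

config = SimulationConfig(seed=5, msi_n_sites=300, msi_unstable_fraction=0.01)
sites, truth = gen_msi_sites(config)

for site in sites:
    test_site(site, min_depth=20, alpha=0.01)

result = msi_score(sites)
print(f"planted unstable sites: {sum(truth.values())}/{len(sites)}")
print(f"evaluated: {result.n_evaluated}, called unstable: {result.n_unstable}")
print(f"MSI score: {result.score:.2f}  ->  {result.classification}")
print("(score = % of evaluated sites whose tumor length distribution differs")
print(" from the matched normal; > 3.5 would classify the sample MSI-high)")
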
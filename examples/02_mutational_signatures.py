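"""Build 96-context mutation catalogs from a cohort with known signature
mixtures, extract signatures by KL-NMF, and match them to the reference
catalog by cosine similarity.

Prints the chosen rank, each extracted signature's best reference match with
its cosine, and the correlation between true and estimated exposures.
"""

import numpy as np

from uromics import (
    SimulationConfig,
    build_catalog,
    extract_signatures,
    gen_mutations,
    gen_reference,
    match_to_reference,
    synthetic_reference_catalog,
)

config = SimulationConfig(seed=3, contig_length=60_000, n_mutations_per_sample=500)
reference = gen_reference(config)
catalog_ref = synthetic_reference_catalog()

# heterogeneous APOBEC-like vs CpG-deamination exposures across 40 samples
rng = np.random.default_rng(0)
mixes = [
    dict(zip(["APOBEC_CT", "CPG_CT"], map(float, rng.dirichlet([1, 1]))))
    for _ in range(40)
]
variants, true_exposures = gen_mutations(
    config, reference, catalog_ref, n_samples=40, per_sample_mix=mixes
)

catalog = build_catalog(variants, {reference[0]: reference[1]})
model = extract_signatures(catalog, k="auto", n_restarts=5, max_iter=400, seed=0)
model, linkage, labels = match_to_reference(model, catalog_ref)

print(f"chosen rank: {model.k}")
for name, (ref_name, cosine) in model.best_match.items():
    print(f"  {name} -> {ref_name} (cosine {cosine:.3f})")

for name, (ref_name, _) in model.best_match.items():
    if ref_name in true_exposures.columns:
        corr = np.corrcoef(
            model.exposures.loc[name], true_exposures[ref_name]
        )[0, 1]
        print(f"  exposure correlation with true {ref_name}: {corr:.3f}")
print("(cosine near 1 means the extracted 96-channel profile reproduces the")
print(" generating signature; exposure correlation near 1 means per-sample")
print(" attributions are quantitatively recovered)")
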
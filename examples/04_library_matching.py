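"""Library matching: identify molecules from noisy replicate spectra.

An augmented library holds one spectrum per molecule; noisy replicate
measurements are used as queries, candidates are pre-filtered to a
+-5 Da window around the base peak and ranked by Stein dot product.
"""

import fragspec as fs

data = fs.make_dataset(n=50, max_heavy_atoms=7, seed=3)
library = fs.AugmentedLibrary()
for i, (mol, spec, _) in enumerate(data):
    library.add(f"mol{i:03d}", spec, "predicted")

noise = fs.ReplicateNoise(jitter=0.15, dropout=0.05, seed=0)
ranks = []
for i, (mol, spec, _) in enumerate(data):
    [query] = fs.make_replicates(spec, fs.ReplicateNoise(0.15, 0.05, seed=i), 1)
    ranks.append(fs.rank_query(query, f"mol{i:03d}", library))

for k in (1, 5, 10):
    recall = fs.recall_at_k(ranks, k)
    print(f"recall@{k:2d} = {recall:5.1%}   (error rate {1 - recall:5.1%})")
mean, std = fs.bootstrap_error(ranks, k=1, draws=100, fraction=0.2, seed=0)
print(f"bootstrap error rate @1 over 20% draws: {mean:.3f} +- {std:.3f}")
print("\nrecall@K is the fraction of noisy queries whose true molecule")
print("ranks in the top K of the SDP-sorted candidate list.")
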
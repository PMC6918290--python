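"""Simulate a two-batch LC-MS cohort with known drift and batch effects.

Builds the acquisition worklist (conditioning QCs, a pooled QC every 5
samples, solvent blanks) and a feature table with planted smooth
intra-batch drift, per-feature batch factors, noise, detection-limit
dropout and cross-batch replicate pairs.
"""

from driftqc import SyntheticSpec, generate_dataset, generate_worklist

spec = SyntheticSpec(
    n_features=100,
    n_experimental_per_batch=82,
    n_replicate_pairs=7,
    n_low_is_samples=20,
    noise_cv=0.10,
    seed=1,
)

worklist = generate_worklist(spec)
roles = [w.role for w in worklist]
print(f"worklist: {len(worklist)} injections over {spec.n_batches} batches")
for role in ("NO_INJECTION", "BLANK", "QC", "EXPERIMENTAL"):
    print(f"  {role:13s} {roles.count(role)}")

table, truth = generate_dataset(spec)
print(f"\nfeature table: {table.n_samples} samples x {table.n_features} features")
print(f"  internal-standard channels: {len(table.is_feature_ids())}")
print(f"  missing cells: {int(table.values.isna().sum().sum())}")
print(f"  replicate pairs (measured in both batches): {truth.replicate_pairs}")
print(f"  planted low-IS samples: {len(truth.low_is_samples)}")
b2 = truth.beta["batch_2"]
print(f"  batch-2 response factors: median {b2.median():.3f}, "
      f"range {b2.min():.2f}-{b2.max():.2f}")
# The batch factor is the multiplicative response shift a feature suffers
# when the instrument is cleaned and recalibrated between batches.
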
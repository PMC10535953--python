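"""Applicability domain from attribute statistical defects, plus prediction.

An attribute's statistical defect d_k measures how unevenly it is
distributed across the active training, passive training and calibration
subsets; a compound's defect D_j sums d_k over its non-blocked attribute
occurrences.  A compound is in the domain iff D_j < 2 * mean(D_j).
"""

from mcqsar import GeneratorConfig, TargetFunction, generate_dataset, predict, split_dataset, train

sd = generate_dataset(GeneratorConfig(n_compounds=120, seed=7, noise_relative=0.1))
ds = sd.dataset
ds.apply_split(split_dataset([c.compound_id for c in ds], seed=11))
run = train(ds, T=1, n_epochs=15, tf=TargetFunction(kind="tf1"),
            run_seeds=(1,), split_seed=11)[0]

n_in = sum(1 for a in run.domain if a.in_domain)
print(f"{n_in}/{len(run.domain)} dataset compounds fall inside the domain "
      f"(threshold 2*D_mean = {2 * run.model.d_mean:.4f})")

queries = [
    "CCOC(=O)CC",        # similar chemistry to the training molecules
    "c1ccncc1CCN",       # pyridine + amine, still in vocabulary
    "BrBr",              # no token in common with training: out of vocabulary
]
print("\nSMILES                predicted   in-domain  Dj")
for s in queries:
    p = predict(run.model, s)
    print(f"{s:20s}  {p.value:9.3f}   {str(p.in_domain):9s}  {p.defect:.4f}"
          + ("  (no known attribute carries weight)" if p.out_of_vocabulary else ""))
print("\nPredictions for out-of-vocabulary compounds collapse to the intercept")
print("and are flagged: the model has no information about their features.")
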
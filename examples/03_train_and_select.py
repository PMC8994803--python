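"""Train the binary TPO-inhibition classifier on a synthetic library.

Generates a 300-compound library with planted structure-activity signal,
featurizes it with the concatenated atom-pair-count + substructure-key
fingerprint, grid-searches the five base learners under PCA, builds the
hard/soft voting ensembles, and prints the CV and test macro-F1 per model.
Takes roughly 15 seconds.
"""

import warnings

warnings.filterwarnings("ignore")

import tposcreen as tp

spec = tp.SyntheticSpec(n_compounds=300, seed=0)
activity, truth = tp.generate_library(spec)

recipe = tp.FeatureRecipe(library=tp.SmartsLibrary.default())
features = recipe.featurize(list(activity["id"]), list(activity["smiles"]))
labels = dict(zip(truth["id"], truth["binary"]))

experiment = tp.run_experiment(
    features, labels, "binary",
    grids=tp.REDUCED_GRIDS, reducers=("pca",), seed=0,
)
print(experiment.results_table().to_string(index=False))
best = experiment.best
print(f"\nselected model: {best.combo_id}  cv={best.cv_score:.3f}  test={best.test_score:.3f}")
print(f"specificity (inactive class recall): {tp.specificity_inactive(best.confusion):.3f}")
# The planted aromatic-amine signal makes the binary task learnable: most
# models land around test macro-F1 0.8-0.9 even at this small library size.
# With a single feature set the CV score alone picks the winner, so the
# selected model can have a middling test score -- CV selects, the test set
# only reports.
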
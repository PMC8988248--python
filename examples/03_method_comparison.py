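"""Multi-method comparison with train:test ratio sweep and paired t-tests.

Reproduces the study's comparison protocol at reduced scale: the data are
shuffled into four equal subsets, the last is a fixed test set, and the
first one / two / three serve as training sets (ratios 1:1, 2:1, 3:1).
Pairwise significance comes from paired two-tailed t-tests over a common
10-fold cross-validation of the training portion.  Baselines (KNN, SVM,
logistic regression) share the deep variant's preprocessing.
"""

from drrbm import (
    DeepTrainConfig,
    RBMTrainConfig,
    RunConfig,
    SyntheticConfig,
    report_text,
    run_pipeline,
)

cfg = RunConfig(
    seed=0,
    variant="ADRSVM",
    baselines=["knn", "svm", "logistic"],
    pca_components=20,
    cv_folds=10,
    synthetic=SyntheticConfig(n_samples=400, n_features=40, latent_dim=8, seed=0),
    train=DeepTrainConfig(
        pretrain=RBMTrainConfig(learning_rate=0.05, epochs=3),
        finetune_epochs=80,
        batch_size=50,
        seed=0,
    ),
)

report = run_pipeline(cfg)
print(report_text(report))
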
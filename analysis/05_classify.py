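"""Train and evaluate the SVM and Bi-GRU classifiers.

Reads the feature tables written by 04_extract_features.py, makes a
stratified 80/20 split, standardizes on the training rows, trains the
cubic-polynomial SVM (NREM preset gamma=2.15/C=1, wake preset
gamma=13.2/C=2) and the 3-layer Bi-GRU (hidden 89 for NREM, 59 for
wake), and writes per-model metrics and ROC points under results/.

Usage: python analysis/05_classify.py [--seed N] [--grouping segment|subject]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sleepmci.classify import (SvmConfig, evaluate, split_data, train_bigru,
                               train_svm, wake_svm_config)
from sleepmci.features import (NREM_FEATURES, WAKE_FEATURES, FeatureTable,
                               standardize)
from sleepmci.gru import GruConfig, wake_config

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--grouping", default="segment",
                    choices=["segment", "subject"])
parser.add_argument("--max-epochs", type=int, default=200)
args = parser.parse_args()

out = Path("results")
results = {}
for state, fname, cols in (("NREM", "features_nrem.tsv", NREM_FEATURES),
                           ("W", "features_wake.tsv", WAKE_FEATURES)):
    path = out / fname
    if not path.exists():
        raise SystemExit("run analysis/04_extract_features.py first")
    df = pd.read_csv(path, sep="\t")
    table = FeatureTable(values=df[cols],
                         meta=df[["subject", "group", "state", "start_s"]],
                         state=state)
    train_idx, test_idx = split_data(table, 0.8, args.seed, args.grouping)
    std = standardize(table, train_idx)
    Xtr, ytr = std.X[train_idx], std.y[train_idx]
    Xte, yte = std.X[test_idx], std.y[test_idx]

    svm_cfg = SvmConfig() if state == "NREM" else wake_svm_config()
    svm, svm_cv = train_svm(Xtr, ytr, svm_cfg, seed=args.seed)
    svm_rep = evaluate(svm.score01(Xte), yte)

    gru_cfg = (GruConfig(max_epochs=args.max_epochs) if state == "NREM"
               else wake_config(max_epochs=args.max_epochs))
    gru, info = train_bigru(Xtr, ytr, gru_cfg, seed=args.seed)
    gru_rep = evaluate(gru.predict_scores(Xte), yte)

    results[state] = {"svm": svm_rep.as_dict(), "bigru": gru_rep.as_dict(),
                      "svm_cv_accuracy": svm_cv,
                      "bigru_best_epoch": info["best_epoch"],
                      "n_train": len(train_idx), "n_test": len(test_idx)}
    for name, rep in (("SVM", svm_rep), ("Bi-GRU", gru_rep)):
        print(f"{state:4s} {name:6s}: accuracy {rep.accuracy:.2f}% "
              f"sensitivity {rep.sensitivity:.2f}% "
              f"specificity {rep.specificity:.2f}% F1 {rep.f1:.2f}% "
              f"AUC {rep.auc:.3f}")
    pd.DataFrame({"fpr": svm_rep.roc_fpr, "tpr": svm_rep.roc_tpr}).to_csv(
        out / f"roc_svm_{state.lower()}.csv", index=False)
    pd.DataFrame({"fpr": gru_rep.roc_fpr, "tpr": gru_rep.roc_tpr}).to_csv(
        out / f"roc_bigru_{state.lower()}.csv", index=False)

(out / "classification_report.json").write_text(json.dumps(results, indent=2))
print(f"metrics -> {out / 'classification_report.json'}")
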
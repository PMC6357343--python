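{
  "comment": "Published SVM validation confusion matrices for the 41-probe HCC biomarker panel (positive class = HCC), with the printed metric values (percent) and AUCs.",
  "training": {
    "confusion": {"tp": 7, "fp": 0, "fn": 1, "tn": 8},
    "printed": {"sensitivity": 87.5, "specificity": 100.0, "precision": 100.0, "accuracy": 93.8, "auc": 1.0}
  },
  "testing": {
    "confusion": {"tp": 7, "fp": 0, "fn": 1, "tn": 8},
    "printed": {"sensitivity": 87.5, "specificity": 100.0, "precision": 100.0, "accuracy": 93.8, "auc": 0.984}
  },
  "rna_testing": {
    "confusion": {"tp": 15, "fp": 3, "fn": 6, "tn": 18},
    "printed": {"sensitivity": 71.4, "specificity": 85.7, "precision": 83.3, "accuracy": 78.6, "auc": 0.824}
  }
}
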
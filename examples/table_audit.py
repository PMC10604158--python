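"""Audit the published metric rows for internal consistency.

Given only the printed accuracy and F1 of a classifier evaluated on 20
diabetic / 50 non-diabetic samples, there is (for these rows) exactly one
integer confusion matrix that reproduces both numbers.  Solving for it and
recomputing MCC and Cohen's kappa checks whether the remaining printed
metrics are arithmetically consistent with the first two.
"""

from isletdx import metrics, solve_confusion

ROWS = [
    ("no selection, RBF-kernel SVM", 0.90, 0.844444),
    ("EHO selection, RBF-kernel SVM", 0.957142, 0.926829),
    ("dragonfly selection, RBF-kernel SVM", 0.942857, 0.904761),
]

for name, acc, f1 in ROWS:
    cm = solve_confusion(20, 50, acc, f1)
    m = metrics(cm)
    print(f"{name}:")
    print(f"  confusion matrix  tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")
    print(f"  MCC={m.mcc:.4f}  kappa={m.kappa:.4f}  FM={m.fm:.4f} "
          f" error rate={m.error_rate:.4f}")
# Each MCC/kappa printed here should equal the corresponding published
# value at its four-decimal truncation; a mismatch would mean the printed
# row is internally inconsistent.
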
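"""Recompute a full metric table from raw confusion-matrix counts.

Given only the four counts per classifier (positive class = show-up), the
metric stack reproduces every summary value: CA, support-weighted
precision/recall/F1, MCC and the column-normalised alpha/beta rates that the
pricing model consumes.
"""

from noshowpricing import ConfusionMatrix, classification_accuracy, column_rates, f1, mcc, precision, recall

COUNTS = {
    "RF": ConfusionMatrix(tp=116, tn=90, fp=3, fn=5),
    "GB": ConfusionMatrix(tp=117, tn=90, fp=3, fn=4),
    "AB": ConfusionMatrix(tp=114, tn=87, fp=6, fn=7),
}

print(f"{'alg':<4}{'CA':>7}{'F1':>7}{'Prec':>7}{'Rec':>7}{'MCC':>7}{'alpha%':>8}{'beta%':>8}")
for alg, cm in COUNTS.items():
    rates = column_rates(cm)
    print(
        f"{alg:<4}{classification_accuracy(cm):>7.3f}{f1(cm).weighted:>7.3f}"
        f"{precision(cm).weighted:>7.3f}{recall(cm).weighted:>7.3f}{mcc(cm):>7.3f}"
        f"{100 * rates.alpha:>8.1f}{100 * rates.beta:>8.1f}"
    )

print("\nalpha = P(actual no-show | predicted no-show); beta = P(actual show-up |")
print("predicted show-up). beta is the show-up rate the penalty-fee model uses.")
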
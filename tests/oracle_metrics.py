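"""Brute-force scoring oracle, independent of the package's metric code.

Everything here is computed by explicit per-item tallying so it can serve
as the reference against which the library's vectorized/sklearn-backed
metrics are checked.
"""


def tally(y_true, y_pred, cls):
    """True/false positives and false negatives of one class, by counting."""
    tp = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == cls and t == cls:
            tp += 1
        elif p == cls and t != cls:
            fp += 1
        elif p != cls and t == cls:
            fn += 1
    return tp, fp, fn


def precision_recall_f1_tally(y_true, y_pred, cls):
    tp, fp, fn = tally(y_true, y_pred, cls)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2.0 / (1.0 / precision + 1.0 / recall)
        if precision > 0 and recall > 0
        else 0.0
    )
    return precision, recall, f1


def weighted_f1_tally(y_true, y_pred):
    """Support-weighted per-class F1: sum_i F1_i * n_i / total."""
    classes = sorted(set(y_true))
    total = len(y_true)
    acc = 0.0
    for cls in classes:
        _, _, f1 = precision_recall_f1_tally(y_true, y_pred, cls)
        support = sum(1 for t in y_true if t == cls)
        acc += f1 * support
    return acc / total


def confusion_tally(y_true, y_pred, class_order):
    index = {c: i for i, c in enumerate(class_order)}
    matrix = [[0] * len(class_order) for _ in class_order]
    for t, p in zip(y_true, y_pred):
        matrix[index[t]][index[p]] += 1
    return matrix
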
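"""Published confusion-panel rows used as metric worked examples.

Each row carries the four one-vs-rest counts and the seven printed rate
columns (sensitivity, FPR, ACC, specificity, PPV, NPV, FDR — the
printed MCC column follows no standard formula and is not reproduced).
``consistent=False`` marks the one row whose printed rates contradict
its own counts; it is excluded from exact-reproduction checks but its
printed values still participate in the printed-column aggregates.
"""


def row(tp, fp, tn, fn, sens, fpr, acc, spec, ppv, npv, fdr, consistent=True):
    return {
        "counts": (tp, fp, tn, fn),
        "printed": {"sensitivity": sens, "fpr": fpr, "acc": acc,
                    "specificity": spec, "ppv": ppv, "npv": npv, "fdr": fdr},
        "consistent": consistent,
    }


# Proposed method, five panels (a)-(e), three images each.
TABLE2 = {
    "a": [row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(0, 1, 4, 0, 0, 20.0, 80, 80, 0, 100, 100),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0)],
    "b": [row(1, 1, 3, 0, 100, 25.0, 80, 75, 50, 100, 50),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0)],
    "c": [row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(0, 1, 4, 0, 100, 0.0, 100, 100, 100, 100, 0, consistent=False)],
    "d": [row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 1, 3, 0, 100, 25.0, 80, 75, 50, 100, 50),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0)],
    "e": [row(0, 1, 4, 0, 0, 20.0, 80, 80, 0, 100, 100),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0)],
}

# First comparison method.
TABLE3 = {
    "a": [row(0, 1, 3, 1, 0, 25.0, 60, 75, 0, 75, 100),
          row(1, 2, 2, 0, 100, 50.0, 60, 50, 33, 100, 67),
          row(0, 1, 2, 2, 0, 33.3, 40, 67, 0, 50, 100)],
    "b": [row(1, 1, 1, 2, 33, 50.0, 40, 50, 50, 33, 50),
          row(0, 2, 3, 0, 0, 40.0, 60, 60, 0, 100, 100),
          row(1, 2, 1, 1, 50, 66.7, 40, 33, 33, 50, 67)],
    "c": [row(0, 3, 2, 0, 0, 60.0, 40, 40, 0, 100, 100),
          row(1, 2, 1, 2, 33, 66.7, 33, 33, 33, 33, 67),
          row(1, 4, 0, 0, 100, 100.0, 20, 0, 20, 0, 80)],
    "d": [row(0, 3, 2, 0, 0, 60.0, 40, 40, 0, 100, 100),
          row(0, 3, 2, 0, 0, 60.0, 40, 40, 0, 100, 100),
          row(1, 3, 1, 0, 100, 75.0, 40, 25, 25, 100, 75)],
    "e": [row(1, 2, 1, 1, 50, 66.7, 40, 33, 33, 50, 67),
          row(0, 3, 1, 1, 0, 75.0, 20, 25, 0, 50, 100),
          row(0, 2, 3, 0, 0, 40.0, 60, 60, 0, 100, 100)],
}

# Second comparison method.
TABLE4 = {
    "a": [row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(0, 1, 4, 0, 0, 20.0, 80, 80, 0, 100, 100)],
    "b": [row(1, 1, 3, 0, 100, 25.0, 80, 75, 50, 100, 50),
          row(1, 0, 3, 1, 50, 0.0, 80, 100, 100, 75, 0),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0)],
    "c": [row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 1, 3, 0, 100, 25.0, 80, 75, 50, 100, 50),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0)],
    "d": [row(1, 1, 3, 0, 100, 25.0, 80, 75, 50, 100, 50),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 1, 3, 0, 100, 25.0, 80, 75, 50, 100, 50)],
    "e": [row(1, 0, 3, 1, 50, 0.0, 80, 100, 100, 75, 0),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0),
          row(1, 0, 4, 0, 100, 0.0, 100, 100, 100, 100, 0)],
}

ALL_TABLES = {"proposed": TABLE2, "comparison_a": TABLE3, "comparison_b": TABLE4}


def iter_rows(table):
    for panel, rows in table.items():
        for i, r in enumerate(rows):
            yield panel, i, r
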
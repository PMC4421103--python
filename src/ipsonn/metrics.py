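"""Confusion bookkeeping and the eight panel statistics.

One-vs-rest counts per tissue class feed eight derived statistics, all
expressed as percentages: sensitivity, false-positive rate, accuracy,
specificity, positive/negative predictive value, false discovery rate
and the Matthews correlation coefficient.  Any 0/0 rate is reported as
0 and flagged degenerate.  Display rounding follows the panel
convention: integers everywhere except FPR and MCC at one decimal;
full precision is kept internally.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

#: Panel column order (fixed).
PANEL_COLUMNS = (
    "Images", "TP", "FP", "TN", "FN",
    "Sensitivity", "FPR", "ACC", "Specificity", "PPV", "NPV", "FDR", "MCC",
)

RATE_FIELDS = ("sensitivity", "fpr", "acc", "specificity", "ppv", "npv", "fdr", "mcc")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero toward +inf (0.5 -> 1), as panels print."""
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionStats:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    fpr: float
    acc: float
    specificity: float
    ppv: float
    npv: float
    fdr: float
    mcc: float
    degenerate: tuple = field(default=())

    def rounded(self) -> dict:
        """Display-precision values: integers, FPR/MCC one decimal."""
        out = {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}
        for name, col in zip(RATE_FIELDS, PANEL_COLUMNS[5:]):
            val = getattr(self, name)
            if col in ("FPR", "MCC"):
                out[col] = round_half_up(val, 1)
            else:
                out[col] = int(round_half_up(val))
        return out


def confusion(y_true: Sequence, y_pred: Sequence, positive_class) -> tuple:
    """One-vs-rest counts (TP, FP, TN, FN) for the named class."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    known = set(y_true) | set(y_pred)
    if positive_class not in known:
        raise ValueError(f"unknown class {positive_class!r}")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive_class:
            tp += t == positive_class
            fp += t != positive_class
        else:
            fn += t == positive_class
            tn += t != positive_class
    return tp, fp, tn, fn


def _rate(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return 100.0 * num / den


def derive_stats(tp: int, fp: int, tn: int, fn: int) -> ConfusionStats:
    """The eight statistics from raw counts (percent scale).

    0/0 rates are reported as 0 with the field name recorded in
    ``degenerate``; all-zero counts flag everything.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    flags: list = []
    total = tp + fp + tn + fn
    sens = _rate(tp, tp + fn, flags, "sensitivity")
    fpr = _rate(fp, fp + tn, flags, "fpr")
    acc = _rate(tp + tn, total, flags, "acc")
    spec = _rate(tn, tn + fp, flags, "specificity")
    ppv = _rate(tp, tp + fp, flags, "ppv")
    npv = _rate(tn, tn + fn, flags, "npv")
    fdr = _rate(fp, fp + tp, flags, "fdr")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = 100.0 * (tp * tn - fp * fn) / math.sqrt(denom)
    return ConfusionStats(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, fpr=fpr, acc=acc, specificity=spec,
        ppv=ppv, npv=npv, fdr=fdr, mcc=mcc,
        degenerate=tuple(flags),
    )


def aggregate(stats_list: Sequence, fld: str) -> int:
    """Mean of a rate field across rows, rounded half-up to integer percent.

    Accepts ConfusionStats objects or plain numbers.
    """
    if len(stats_list) == 0:
        raise ValueError("cannot aggregate an empty list")
    vals = [getattr(s, fld) if isinstance(s, ConfusionStats) else float(s)
            for s in stats_list]
    return int(round_half_up(float(np.mean(vals))))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


# ---------------------------------------------------------------------------
# panel rendering


def _format_value(col: str, val) -> str:
    if col in ("Images", "TP", "FP", "TN", "FN"):
        return str(int(val))
    if col in ("FPR", "MCC"):
        return f"{val:.1f}"
    return str(int(val))


def render_panels(per_tissue_stats: Dict[str, List[ConfusionStats]]) -> str:
    """CSV panels, one per tissue, in the standard report layout.

    Each panel starts with ``# <tissue>`` followed by the fixed header
    and one row per image (display rounding applied).
    """
    if not per_tissue_stats:
        raise ValueError("need at least one tissue")
    buf = io.StringIO()
    for tissue, rows in per_tissue_stats.items():
        buf.write(f"# {tissue}\n")
        buf.write(",".join(PANEL_COLUMNS) + "\n")
        for i, st in enumerate(rows, start=1):
            r = st.rounded()
            vals = [str(i)] + [_format_value(c, r[c]) for c in PANEL_COLUMNS[1:]]
            buf.write(",".join(vals) + "\n")
    return buf.getvalue()


def parse_panels(text: str) -> Dict[str, List[ConfusionStats]]:
    """Inverse of :func:`render_panels`; statistics are recomputed from
    the counts, so render -> parse round-trips stats derived here."""
    out: Dict[str, List[ConfusionStats]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# "):
            current = line[2:]
            out[current] = []
        elif line.startswith("Images"):
            if tuple(line.split(",")) != PANEL_COLUMNS:
                raise ValueError("unexpected panel header")
        else:
            parts = line.split(",")
            tp, fp, tn, fn = (int(v) for v in parts[1:5])
            out[current].append(derive_stats(tp, fp, tn, fn))
    return out
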